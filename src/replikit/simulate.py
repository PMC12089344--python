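"""Stochastic forward simulation of DNA replication.

Every 1-kb site is a potential origin whose firing time is drawn from
Exp(f_j). A fired origin launches a leftward- and a rightward-moving fork;
forks replicate one site per step and die when they reach a site that is
already replicated (fork merging) or a chromosome end. An origin that is
passively replicated before its drawn firing time never fires.

Two fork-motion modes are supported:

- ``deterministic``: each 1-kb step takes exactly 1/v min, so the
  replication time of site j is exactly min_i (A_i + |i-j|/v). This mode
  is computed directly by a two-pass lower-envelope sweep and serves as
  the analytic oracle.
- ``erlang``: each 1-kb step takes an independent Exp(v) time, so a
  k-site traversal is Erlang(k, v) with mean k/v — the process-algebra
  semantics of the original stochastic model. Simulated event-driven
  with a priority queue.

Ensembles aggregate mean timing, replication fork directionality
(RFD, in [-1, 1]), inter-origin distances (IOD), replicon lengths and
active-fork counts over time.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .grid import FiringRateProfile, GenomeGrid, ModelConfig, TimingProfile

__all__ = [
    "LABEL_ORIGIN",
    "LABEL_LEFT_FORK",
    "LABEL_RIGHT_FORK",
    "ReplicationRecord",
    "SimulationSummary",
    "sample_firing_times",
    "min_formula_times",
    "simulate_once",
    "simulate_ensemble",
]

LABEL_ORIGIN = 0
LABEL_LEFT_FORK = 1  # replicated by a leftward-moving fork (origin to the right)
LABEL_RIGHT_FORK = 2  # replicated by a rightward-moving fork (origin to the left)


@dataclass
class ReplicationRecord:
    """One replication cycle: per-site times, event labels, fired origins."""

    replication_time: np.ndarray  # minutes, flat over the grid
    replicated_by: np.ndarray  # int8 labels, LABEL_* constants
    fired_origins: list[tuple[int, float]]  # (flat site index, firing time)
    replicon_extent: dict[int, int]  # fired origin -> sites replicated (incl. itself)
    fork_intervals: list[tuple[float, float]]  # (birth, death) times of each fork
    grid: GenomeGrid | None = None


@dataclass
class SimulationSummary:
    """Ensemble aggregate over n_simulations replication cycles."""

    mean_timing: TimingProfile
    rfd: np.ndarray  # (#rightward - #leftward) / n_simulations, in [-1, 1]
    direction_fractions: np.ndarray  # (n_sites, 3): origin/left/right fractions
    iod_samples: np.ndarray  # kb, distances between consecutive fired origins
    replicon_lengths: np.ndarray  # kb
    active_fork_counts: np.ndarray  # forks alive per 1-min bin
    n_simulations: int


def sample_firing_times(rates: FiringRateProfile, seed: int) -> np.ndarray:
    """Draw independent Exp(f_j) origin firing times, one per site."""
    rng = np.random.default_rng(seed)
    return rng.exponential(1.0 / rates.rates)


def min_formula_times(
    firing_times: np.ndarray, v: float, grid: GenomeGrid | None = None
) -> np.ndarray:
    """Replication times T_j = min_i (A_i + |i-j|/v) under constant fork speed.

    Computed in O(n) per chromosome by a two-pass lower-envelope sweep.
    Because the per-site fork delay is the constant 1/v, the left pass is
    the min-plus scan min_{i<=j}(A_i - i/v) + j/v (and symmetrically for
    the right pass), so both passes vectorise as running minima. Accepts a
    2-D array of shape (replicates, sites) and sweeps each row, enabling
    the Monte-Carlo oracle over many sampled firing-time vectors at once.
    Infinite entries mark origins that never fire.
    """
    A = np.asarray(firing_times, dtype=float)
    step = 1.0 / v

    def _sweep(a: np.ndarray) -> np.ndarray:
        if not np.all(np.any(np.isfinite(a), axis=-1)):
            raise ValueError("no finite firing time on chromosome")
        pos = np.arange(a.shape[-1]) * step
        left = np.minimum.accumulate(a - pos, axis=-1) + pos
        rev = (a + pos)[..., ::-1]
        right = np.minimum.accumulate(rev, axis=-1)[..., ::-1] - pos
        return np.minimum(left, right)

    if grid is None or A.ndim == 2:
        return _sweep(A)
    out = np.empty_like(A)
    for _, sl in grid.iter_chromosomes():
        out[sl] = _sweep(A[sl])
    return out


def _labels_deterministic(A: np.ndarray, T: np.ndarray, v: float) -> np.ndarray:
    """Event labels for constant-speed motion given firing and replication times.

    A fork arriving exactly when the site would fire wins (the origin is
    passively replicated); between two forks arriving together the
    rightward-moving one wins.
    """
    n = A.size
    step = 1.0 / v
    labels = np.empty(n, dtype=np.int8)
    for j in range(n):
        from_left = T[j - 1] + step if j > 0 else np.inf
        from_right = T[j + 1] + step if j < n - 1 else np.inf
        best_fork = min(from_left, from_right)
        if best_fork <= A[j]:
            labels[j] = LABEL_RIGHT_FORK if from_left <= from_right else LABEL_LEFT_FORK
        else:
            labels[j] = LABEL_ORIGIN
    return labels


def _record_deterministic(
    A: np.ndarray, v: float
) -> tuple[np.ndarray, np.ndarray, list, dict, list]:
    T = min_formula_times(A, v)
    labels = _labels_deterministic(A, T, v)
    n = A.size
    fired = [(j, float(A[j])) for j in range(n) if labels[j] == LABEL_ORIGIN]
    # trace each fork-replicated site back to its source origin
    source = np.full(n, -1, dtype=np.int64)
    for j in range(n):
        if labels[j] == LABEL_ORIGIN:
            source[j] = j
        elif labels[j] == LABEL_RIGHT_FORK:
            source[j] = source[j - 1]
    for j in range(n - 2, -1, -1):
        if labels[j] == LABEL_LEFT_FORK:
            source[j] = source[j + 1]
    extents: dict[int, int] = {j: 0 for j, _ in fired}
    for j in range(n):
        extents[int(source[j])] += 1
    forks: list[tuple[float, float]] = []
    for o, t0 in fired:
        for lab in (LABEL_LEFT_FORK, LABEL_RIGHT_FORK):
            served = np.nonzero((source == o) & (labels == lab))[0]
            death = float(T[served].max()) if served.size else t0
            forks.append((t0, death))
    return T, labels, fired, extents, forks


def _record_erlang(
    A: np.ndarray, v: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list, dict, list]:
    n = A.size
    T = np.full(n, np.nan)
    labels = np.full(n, -1, dtype=np.int8)
    done = np.zeros(n, dtype=bool)
    fired: list[tuple[int, float]] = []
    extents: dict[int, int] = {}
    forks: list[tuple[float, float]] = []
    # events: (time, kind, seq, site, direction, origin, birth)
    # kind 0 = fork arrival, 1 = origin firing — forks win exact-time ties
    heap: list[tuple] = [(float(A[j]), 1, j, j, 0, j, 0.0) for j in range(n)]
    heapq.heapify(heap)
    seq = n
    remaining = n
    while remaining:
        t, kind, _, site, direction, origin, birth = heapq.heappop(heap)
        if done[site]:
            if kind == 0:
                forks.append((birth, t))  # fork meets replicated DNA and retires
            continue
        done[site] = True
        remaining -= 1
        T[site] = t
        if kind == 1:
            labels[site] = LABEL_ORIGIN
            fired.append((site, t))
            extents[site] = 1
            for d in (-1, 1):
                nxt = site + d
                if 0 <= nxt < n:
                    heapq.heappush(
                        heap,
                        (t + rng.exponential(1.0 / v), 0, seq, nxt, d, site, t),
                    )
                    seq += 1
                else:
                    forks.append((t, t))
        else:
            labels[site] = LABEL_RIGHT_FORK if direction == 1 else LABEL_LEFT_FORK
            extents[origin] += 1
            nxt = site + direction
            if 0 <= nxt < n:
                heapq.heappush(
                    heap,
                    (t + rng.exponential(1.0 / v), 0, seq, nxt, direction, origin, birth),
                )
                seq += 1
            else:
                forks.append((birth, t))
    return T, labels, fired, extents, forks


def simulate_once(
    rates: FiringRateProfile, config: ModelConfig, seed: int
) -> ReplicationRecord:
    """Simulate one replication cycle over the whole grid.

    In ``deterministic`` mode the record's times equal
    :func:`min_formula_times` on the sampled firing times exactly.
    """
    rates.validate(config.rate_floor, config.rate_cap)
    grid = rates.grid
    A = sample_firing_times(rates, seed)
    rng = np.random.default_rng((seed, 1))  # fork-step stream, separate from firing
    times = np.empty(grid.total_sites)
    labels = np.empty(grid.total_sites, dtype=np.int8)
    fired_all: list[tuple[int, float]] = []
    extents_all: dict[int, int] = {}
    forks_all: list[tuple[float, float]] = []
    for _, sl in grid.iter_chromosomes():
        if config.fork_motion_mode == "deterministic":
            T, lab, fired, ext, forks = _record_deterministic(
                A[sl], config.fork_speed_v
            )
        else:
            T, lab, fired, ext, forks = _record_erlang(
                A[sl], config.fork_speed_v, rng
            )
        times[sl] = T
        labels[sl] = lab
        off = sl.start
        fired_all.extend((j + off, t) for j, t in fired)
        extents_all.update({j + off: c for j, c in ext.items()})
        forks_all.extend(forks)
    return ReplicationRecord(
        replication_time=times,
        replicated_by=labels,
        fired_origins=fired_all,
        replicon_extent=extents_all,
        fork_intervals=forks_all,
        grid=grid,
    )


def simulate_ensemble(
    rates: FiringRateProfile, config: ModelConfig
) -> SimulationSummary:
    """Run n_simulations replication cycles (seeds base_seed + index) and
    aggregate timing, RFD, IOD, replicon-length and active-fork summaries.

    RFD at a site is (#rightward - #leftward) / n_simulations; runs in which
    the site fired as an origin contribute 0 to either direction.
    """
    if config.n_simulations < 1:
        raise ValueError("n_simulations must be >= 1")
    grid = rates.grid
    n = grid.total_sites
    time_sum = np.zeros(n)
    counts = np.zeros((n, 3), dtype=np.int64)  # origin / left / right
    iods: list[float] = []
    replicons: list[float] = []
    fork_intervals: list[tuple[float, float]] = []
    offsets = grid.offsets
    for i in range(config.n_simulations):
        rec = simulate_once(rates, config, config.base_seed + i)
        time_sum += rec.replication_time
        for lab in (LABEL_ORIGIN, LABEL_LEFT_FORK, LABEL_RIGHT_FORK):
            counts[rec.replicated_by == lab, lab] += 1
        fired = np.array(sorted(j for j, _ in rec.fired_origins), dtype=np.int64)
        for ci in range(len(grid.chromosomes)):
            on_chrom = fired[(fired >= offsets[ci]) & (fired < offsets[ci + 1])]
            if on_chrom.size > 1:
                iods.extend(np.diff(on_chrom).astype(float))
        replicons.extend(float(c) for c in rec.replicon_extent.values())
        fork_intervals.extend(rec.fork_intervals)

    nsim = config.n_simulations
    mean_timing = TimingProfile(time_sum / nsim, grid, provenance="simulated-mean")
    rfd = (counts[:, LABEL_RIGHT_FORK] - counts[:, LABEL_LEFT_FORK]) / nsim
    if fork_intervals:
        births = np.array([b for b, _ in fork_intervals])
        deaths = np.array([d for _, d in fork_intervals])
        nbins = int(np.floor(deaths.max())) + 1
        active = np.zeros(nbins, dtype=np.int64)
        # a fork counts in every 1-min bin its lifetime intersects
        lo = np.floor(births).astype(int)
        hi = np.floor(deaths).astype(int)
        for a, b in zip(lo, hi):
            active[a : b + 1] += 1
    else:
        active = np.zeros(0, dtype=np.int64)
    return SimulationSummary(
        mean_timing=mean_timing,
        rfd=rfd,
        direction_fractions=counts / nsim,
        iod_samples=np.asarray(iods, dtype=float),  # sites == kb at 1-kb resolution
        replicon_lengths=np.asarray(replicons, dtype=float),
        active_fork_counts=active,
        n_simulations=nsim,
    )
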