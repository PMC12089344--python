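"""Seeded synthetic-data generators.

These emulate the statistical structure the model assumes — sparse origins
with exponential firing on a 1-kb lattice, constant-speed forks — plus the
perturbations the model deliberately cannot fit: fork-stall delays that
violate the 1/v timing slope bound. Every generator is a pure function of
its spec and seed, so regenerating with the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import FiringRateProfile, GenomeGrid, ModelConfig, TimingProfile
from .io import RepliseqFractions, IntervalTrack
from .model import expected_timing_profile

import pandas as pd

__all__ = [
    "SyntheticSpec",
    "gen_firing_landscape",
    "gen_observed_timing",
    "gen_fraction_heatmap",
    "gen_interval_track",
]

STALL_RAMP_SITES = 10  # linear ramp at each stall edge, sites


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic replication landscape.

    stall_regions is a list of (start_site, end_site, delay_minutes)
    with inclusive site bounds; defaults emulate fragile-site-scale fork
    stalling (60-min delay over 150 kb). noise_sd is the per-site Gaussian
    timing noise in minutes.
    """

    n_sites: int = 5000
    origin_count: int = 20
    rate_range: tuple[float, float] = (1e-3, 1e-1)
    background_rate: float = 1e-10
    stall_regions: tuple[tuple[int, int, float], ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    chromosome: str = "chrS"

    def __post_init__(self) -> None:
        if self.origin_count > self.n_sites:
            raise ValueError("origin_count > n_sites")
        if self.rate_range[0] <= 0 or self.rate_range[1] < self.rate_range[0]:
            raise ValueError("bad rate_range")
        for s, e, d in self.stall_regions:
            if not (0 <= s <= e < self.n_sites):
                raise ValueError(f"stall region ({s}, {e}) outside grid")
            if d <= 0:
                raise ValueError("stall delays must be > 0")


def gen_firing_landscape(spec: SyntheticSpec) -> FiringRateProfile:
    """Sparse-origin rate landscape: origin_count sites drawn without
    replacement carry log-uniform rates in rate_range, the rest the
    background rate."""
    rng = np.random.default_rng(spec.seed)
    rates = np.full(spec.n_sites, spec.background_rate)
    if spec.origin_count:
        sites = rng.choice(spec.n_sites, size=spec.origin_count, replace=False)
        lo, hi = np.log(spec.rate_range[0]), np.log(spec.rate_range[1])
        rates[sites] = np.exp(rng.uniform(lo, hi, size=spec.origin_count))
    grid = GenomeGrid.from_sizes({spec.chromosome: spec.n_sites})
    return FiringRateProfile(rates, grid)


def _stall_delay_field(spec: SyntheticSpec) -> np.ndarray:
    """Additive delay per site: full delay inside each stall region, ramped
    linearly over STALL_RAMP_SITES at each edge."""
    delay = np.zeros(spec.n_sites)
    for s, e, d in spec.stall_regions:
        j = np.arange(s, e + 1)
        ramp_in = (j - s + 1) / STALL_RAMP_SITES
        ramp_out = (e - j + 1) / STALL_RAMP_SITES
        delay[s : e + 1] = np.maximum(
            delay[s : e + 1], d * np.minimum(1.0, np.minimum(ramp_in, ramp_out))
        )
    return delay


def gen_observed_timing(
    spec: SyntheticSpec,
    rates: FiringRateProfile,
    config: ModelConfig,
) -> tuple[TimingProfile, list[tuple[int, int]]]:
    """Forward-model timing plus stall delays and Gaussian noise.

    Returns the timing profile and the ground-truth stall intervals
    (inclusive site bounds) for detector evaluation. With no stalls and
    zero noise the output equals the closed-form expectation exactly.
    """
    base = expected_timing_profile(rates, config)
    t = base.times.copy()
    t += _stall_delay_field(spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng((spec.seed, 17))
        t += rng.normal(0.0, spec.noise_sd, size=t.size)
        t = np.maximum(t, 0.0)
    truth = [(s, e) for s, e, _ in spec.stall_regions]
    return TimingProfile(t, rates.grid, provenance="observed"), truth


def gen_fraction_heatmap(
    timing: TimingProfile,
    n_bins: int = 16,
    spread_minutes: float = 60.0,
    noise_sd_points: float = 0.0,
    seed: int = 0,
    span_minutes: float = 600.0,
) -> RepliseqFractions:
    """Cumulative Repli-seq-style fraction matrix from a timing profile.

    Each site's cumulative percent-replicated is a logistic centred at its
    replication time T_j with scale set by spread_minutes, sampled at
    n_bins midpoints spanning S phase, plus truncated Gaussian noise.
    The generating t_rep is the input timing itself.
    """
    if n_bins < 4:
        raise ValueError("need n_bins >= 4")
    edges = np.linspace(0.0, span_minutes, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    k = 4.0 / spread_minutes  # logistic slope: ~spread_minutes from 12% to 88%
    t0 = timing.times[:, None]
    frac = 100.0 / (1.0 + np.exp(-k * (mids[None, :] - t0)))
    if noise_sd_points > 0:
        rng = np.random.default_rng(seed)
        frac = frac + rng.normal(0.0, noise_sd_points, size=frac.shape)
    frac = np.clip(frac, 0.0, 100.0)
    return RepliseqFractions(mids, frac, timing.grid)


def gen_interval_track(
    n_intervals: int,
    length_range: tuple[int, int],
    class_labels: tuple[str, ...],
    seed: int,
    grid: GenomeGrid,
) -> IntervalTrack:
    """Seeded non-overlapping labelled intervals scattered over the grid."""
    if n_intervals < 0:
        raise ValueError("n_intervals must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in grid.chromosomes}
    attempts = 0
    while len(rows) < n_intervals and attempts < 100 * max(n_intervals, 1):
        attempts += 1
        ci = int(rng.integers(len(grid.chromosomes)))
        chrom = grid.chromosomes[ci]
        span_bp = grid.n_sites[ci] * 1000
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if length >= span_bp:
            continue
        start = int(rng.integers(0, span_bp - length))
        end = start + length
        if any(start < e and s < end for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        label = class_labels[int(rng.integers(len(class_labels)))]
        rows.append((chrom, start, end, f"iv{len(rows)}", label))
    if len(rows) < n_intervals:
        raise RuntimeError("could not place all intervals without overlap")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "class_label"])
    return IntervalTrack(df, vocabulary=tuple(sorted(set(class_labels))))
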