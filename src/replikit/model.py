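"""Closed-form expected replication timing.

Each 1-kb site j may fire as an origin after an Exp(f_j) waiting time;
forks then spread bidirectionally at constant speed v (kb/min). The time
T_j at which site j is replicated is the minimum over all origins i of
A_i + |i-j|/v. Its expectation has a closed form: partition the time axis
at the fork-arrival breakpoints k/v; on [k/v, (k+1)/v) the survival
probability is exp(-sum_{|i|<=k} f_{j+i} (t - |i|/v)), a single
exponential, so each segment integrates analytically. Writing
S_k = sum_{|i|<=k} (k-|i|) f_{j+i} and W_k = sum_{|i|<=k} f_{j+i}
(recurrences S_{k+1} = S_k + W_k, W via prefix sums), the expected time is

    E[T_j] = sum_k [exp(-S_k/v) - exp(-(S_k+W_k)/v)] / W_k

summed over k = 0..R, the radius of influence. A uniform-rate landscape
reduces this to a one-dimensional series with the asymptotic approximation
E[T] ~ (1/2) sqrt(pi/(f v)), whose inverse provides the initial rate
estimate used by the fitting algorithm.
"""

from __future__ import annotations

import math

import numpy as np

from .grid import FiringRateProfile, GenomeGrid, ModelConfig, TimingProfile

__all__ = [
    "expected_timing_profile",
    "expected_timing_uniform",
    "expected_timing_uniform_finite",
    "approx_expected_timing",
    "invert_timing_uniform",
]

_MIN_CHROM_SITES = 3


def _expected_times_chrom(
    f: np.ndarray, v: float, radius: int, tail_tol: float
) -> np.ndarray:
    """Expected replication time per site of one chromosome.

    Windows are clamped at chromosome ends (missing flank contributes
    rate 0). After the k-sum stops — early-stop tolerance reached, the
    window frozen at the full chromosome span, or k = radius — the
    geometric remainder of the frozen-window survival, exp(-S/v)/W, is
    added in closed form so no tail mass is dropped.
    """
    n = f.size
    if n < _MIN_CHROM_SITES:
        raise ValueError(f"chromosome needs >= {_MIN_CHROM_SITES} sites, got {n}")
    if np.any(f <= 0) or np.any(~np.isfinite(f)):
        raise ValueError("firing rates must be finite and > 0")

    prefix = np.concatenate(([0.0], np.cumsum(f)))
    idx = np.arange(n)
    T = np.zeros(n)
    S = np.zeros(n)  # S_k accumulator
    W = np.zeros(n)
    # once k >= n-1 every window is clamped to the whole chromosome and W freezes
    k_freeze = min(radius, n - 1)
    for k in range(k_freeze + 1):
        lo = np.maximum(idx - k, 0)
        hi = np.minimum(idx + k + 1, n)
        W = prefix[hi] - prefix[lo]
        surv = np.exp(-S / v)
        x = W / v
        # term = surv * (1 - e^{-x}) / (x v); stable at small W via expm1
        g = np.empty_like(x)
        nz = x > 0
        g[nz] = -np.expm1(-x[nz]) / x[nz]
        g[~nz] = 1.0
        T += surv * g / v
        S += W
        if surv.max() < tail_tol:
            break
    # frozen-window geometric remainder: sum_{k'>k} terms = exp(-S_{k+1}/v)/W
    T += np.exp(-S / v) / W
    return T


def expected_timing_profile(
    rates: FiringRateProfile, config: ModelConfig
) -> TimingProfile:
    """Closed-form expected replication timing for a rate landscape.

    Deterministic; chromosomes are independent. The output obeys the
    fork-speed slope bound |T_{j+1} - T_j| <= 1/v within each chromosome.
    """
    rates.validate(config.rate_floor, config.rate_cap)
    out = np.empty(rates.grid.total_sites)
    for _, sl in rates.grid.iter_chromosomes():
        out[sl] = _expected_times_chrom(
            rates.rates[sl],
            config.fork_speed_v,
            config.radius_R,
            config.series_tail_tolerance,
        )
    return TimingProfile(out, rates.grid, provenance="predicted")


def expected_timing_uniform(
    f: float, v: float = 1.4, *, tail_tol: float = 1e-12
) -> float:
    """Expected replication time under a uniform firing rate, infinite genome.

    Evaluates (1/f) sum_k [e^{-f k^2/v} - e^{-f (k+1)^2/v}] / (2k+1),
    truncated once the leading exponential drops below ``tail_tol``.
    """
    if f <= 0:
        raise ValueError("f must be > 0")
    if v <= 0:
        raise ValueError("v must be > 0")
    x = f / v
    kmax = int(math.ceil(math.sqrt(max(-math.log(tail_tol), 1.0) / x))) + 1
    k = np.arange(kmax + 1, dtype=float)
    terms = (np.exp(-x * k**2) - np.exp(-x * (k + 1) ** 2)) / (2 * k + 1)
    return float(terms.sum() / f)


def _distance_multiset(n: int) -> np.ndarray:
    """Sorted origin distances (in sites) seen by one site among n sites.

    Sites are arranged symmetrically around the focal one (indices modulo
    n), so distances are 0, then 1..floor((n-1)/2) each twice, plus the
    antipode n/2 once when n is even — the source of the parity dependence
    of the finite-genome expectation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    half = (n - 1) // 2
    d = [0]
    for k in range(1, half + 1):
        d += [k, k]
    if n % 2 == 0:
        d.append(n // 2)
    return np.asarray(sorted(d), dtype=float)


def expected_timing_uniform_finite(f: float, n: int, v: float = 1.4) -> float:
    """Expected replication time among n uniform-rate potential origins.

    Integrates the survival product prod_i min{1, exp(-f (t - d_i/v))}
    exactly by partitioning the time axis at the fork-arrival breakpoints
    d_i/v, where each segment is a single exponential. Non-increasing in n
    and converges to :func:`expected_timing_uniform` as n grows.
    """
    if f <= 0:
        raise ValueError("f must be > 0")
    d = _distance_multiset(int(n))
    t_break = d / v
    m = np.arange(1, d.size + 1, dtype=float)  # active origin count per segment
    D = np.cumsum(t_break)  # sum of d_i/v over active origins
    # segment [t_m, t_{m+1}): integrand exp(-f (m t - D_{m-1}))
    t_hi = np.concatenate((t_break[1:], [np.inf]))
    a_lo = np.exp(-f * (m * t_break - D))
    with np.errstate(over="ignore"):
        a_hi = np.where(np.isinf(t_hi), 0.0, np.exp(-f * (m * t_hi - D)))
    return float(np.sum((a_lo - a_hi) / (f * m)))


def approx_expected_timing(f: float, v: float) -> float:
    """Asymptotic approximation E[T] ~ (1/2) sqrt(pi/(f v))."""
    if f <= 0 or v <= 0:
        raise ValueError("f and v must be > 0")
    return 0.5 * math.sqrt(math.pi / (f * v))


def invert_timing_uniform(T: float, v: float) -> float:
    """Firing-rate estimate from a replication time: f = pi/(4 v) T^-2.

    Exact inverse of :func:`approx_expected_timing`; used to initialise
    the fitting iteration.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    if v <= 0:
        raise ValueError("v must be > 0")
    return math.pi / (4.0 * v) * T**-2
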