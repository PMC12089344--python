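"""Model-data discrepancy analysis.

The fit error at a site is the squared difference between observed and
predicted replication time, in min². Contiguous stretches of high error
("misfit regions") flag loci where the constant-fork-speed assumption
breaks down — e.g. fork slowing or stalling — and are related to interval
annotations (fragile sites, genes) and other genomic signal tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import SITE_BP, GenomeGrid, TimingProfile
from .io import IntervalTrack

__all__ = [
    "DEFAULT_MISFIT_THRESHOLD",
    "HIGH_MISFIT_THRESHOLD",
    "DEFAULT_MERGE_RADIUS_KB",
    "ErrorProfile",
    "MisfitRegion",
    "error_profile",
    "normalize_error",
    "detect_misfit_regions",
    "misfit_site_mask",
    "overlap_fraction",
    "correlate_tracks",
    "apparent_speed_profile",
    "regions_to_bed",
]

DEFAULT_MISFIT_THRESHOLD = 10**2.8  # min², the local-maxima calling threshold
HIGH_MISFIT_THRESHOLD = 1e4  # min², the stricter coding/non-coding contrast preset
DEFAULT_MERGE_RADIUS_KB = 300


@dataclass
class ErrorProfile:
    """Per-site squared timing error (min²); NaN on masked sites."""

    squared_error: np.ndarray
    grid: GenomeGrid

    def __post_init__(self) -> None:
        arr = np.asarray(self.squared_error, dtype=float)
        if arr.shape != (self.grid.total_sites,):
            raise ValueError("error length does not match grid")
        valid = self.grid.valid_mask & np.isfinite(arr)
        if np.any(arr[valid] < 0):
            raise ValueError("squared error must be >= 0")
        self.squared_error = arr


@dataclass(frozen=True)
class MisfitRegion:
    """Contiguous run of sites above the misfit threshold (inclusive sites)."""

    chromosome: str
    start_site: int
    end_site: int
    peak_error: float

    def __post_init__(self) -> None:
        if self.start_site > self.end_site:
            raise ValueError("start_site > end_site")

    @property
    def length_kb(self) -> int:
        return self.end_site - self.start_site + 1

    @property
    def start_bp(self) -> int:
        return self.start_site * SITE_BP

    @property
    def end_bp(self) -> int:
        return (self.end_site + 1) * SITE_BP


def error_profile(observed: TimingProfile, predicted: TimingProfile) -> ErrorProfile:
    """Per-site squared difference (T - T~)²; masked where either input is."""
    if observed.grid.chromosomes != predicted.grid.chromosomes or tuple(
        observed.grid.n_sites
    ) != tuple(predicted.grid.n_sites):
        raise ValueError("profiles must share one grid layout")
    valid = (
        observed.grid.valid_mask
        & predicted.grid.valid_mask
        & np.isfinite(observed.times)
        & np.isfinite(predicted.times)
    )
    err = np.full(observed.grid.total_sites, np.nan)
    err[valid] = (observed.times[valid] - predicted.times[valid]) ** 2
    grid = GenomeGrid(observed.grid.chromosomes, observed.grid.n_sites, valid)
    return ErrorProfile(err, grid)


def normalize_error(error: ErrorProfile, scheme: str = "log10_minmax") -> np.ndarray:
    """Map errors to [0, 1] per chromosome: log10(e + 1), then min-max.

    A chromosome with constant error maps to 0 everywhere.
    """
    if scheme != "log10_minmax":
        raise ValueError(f"unknown scheme {scheme!r}")
    out = np.full(error.grid.total_sites, np.nan)
    for _, sl in error.grid.iter_chromosomes():
        e = error.squared_error[sl]
        m = error.grid.valid_mask[sl] & np.isfinite(e)
        if not m.any():
            continue
        le = np.log10(e[m] + 1.0)
        lo, hi = le.min(), le.max()
        sub = np.full(e.size, np.nan)
        sub[m] = 0.0 if hi == lo else (le - lo) / (hi - lo)
        out[sl] = sub
    return out


def detect_misfit_regions(
    error: ErrorProfile,
    threshold: float = DEFAULT_MISFIT_THRESHOLD,
    merge_radius: int = DEFAULT_MERGE_RADIUS_KB,
) -> list[MisfitRegion]:
    """Contiguous runs of error > threshold, merged when gaps <= merge_radius kb.

    Deterministic; regions are annotated with the peak error over the
    merged span's above-threshold sites.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    regions: list[MisfitRegion] = []
    for name, sl in error.grid.iter_chromosomes():
        e = error.squared_error[sl]
        hot = error.grid.valid_mask[sl] & np.isfinite(e) & (e > threshold)
        if not hot.any():
            continue
        idx = np.nonzero(hot)[0]
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        starts = np.concatenate(([idx[0]], idx[breaks + 1]))
        ends = np.concatenate((idx[breaks], [idx[-1]]))
        # merge runs whose separating gap is within the radius
        merged = [[int(starts[0]), int(ends[0])]]
        for s, t in zip(starts[1:], ends[1:]):
            if s - merged[-1][1] - 1 <= merge_radius:
                merged[-1][1] = int(t)
            else:
                merged.append([int(s), int(t)])
        for s, t in merged:
            peak = float(np.nanmax(np.where(hot[s : t + 1], e[s : t + 1], np.nan)))
            regions.append(MisfitRegion(name, s, t, peak))
    return regions


def misfit_site_mask(
    error: ErrorProfile, threshold: float = DEFAULT_MISFIT_THRESHOLD
) -> np.ndarray:
    """Boolean per-site mask of error > threshold (the 'misfit sites')."""
    e = error.squared_error
    return error.grid.valid_mask & np.isfinite(e) & (e > threshold)


def _class_site_masks(
    annotations: IntervalTrack, grid: GenomeGrid
) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(grid.total_sites, dtype=bool) for c in annotations.vocabulary}
    known = set(grid.chromosomes)
    for rec in annotations.intervals.itertuples(index=False):
        if rec.chrom not in known:
            continue
        sl = grid.chrom_slice(rec.chrom)
        n = sl.stop - sl.start
        j0 = max(rec.start // SITE_BP, 0)
        j1 = min((rec.end - 1) // SITE_BP, n - 1)
        if j1 >= j0:
            masks[rec.class_label][sl.start + j0 : sl.start + j1 + 1] = True
    return masks


def overlap_fraction(
    misfit: np.ndarray | list[MisfitRegion],
    annotations: IntervalTrack,
    grid: GenomeGrid,
    by_class: bool = True,
) -> pd.DataFrame:
    """Fraction of annotated sites that are misfit, per annotation class.

    misfit may be a per-site boolean mask or a list of regions (converted
    to the union of their sites). For each class the complement row
    reports the misfit fraction outside that class's intervals, for
    enrichment comparison.
    """
    if isinstance(misfit, list):
        mask = np.zeros(grid.total_sites, dtype=bool)
        for r in misfit:
            sl = grid.chrom_slice(r.chromosome)
            mask[sl.start + r.start_site : sl.start + r.end_site + 1] = True
    else:
        mask = np.asarray(misfit, dtype=bool)
    valid = grid.valid_mask
    mask = mask & valid
    class_masks = _class_site_masks(annotations, grid)
    if not by_class:
        union = np.zeros(grid.total_sites, dtype=bool)
        for m in class_masks.values():
            union |= m
        class_masks = {"all": union}
    rows = []
    for label, cmask in sorted(class_masks.items()):
        inside = cmask & valid
        outside = ~cmask & valid
        n_in, n_out = int(inside.sum()), int(outside.sum())
        rows.append(
            {
                "class_label": label,
                "misfit_fraction": float(mask[inside].sum() / n_in) if n_in else np.nan,
                "complement_fraction": float(mask[outside].sum() / n_out)
                if n_out
                else np.nan,
                "sites_in_class": n_in,
                "misfit_sites_in_class": int(mask[inside].sum()),
            }
        )
    return pd.DataFrame(rows)


def correlate_tracks(
    a: np.ndarray, b: np.ndarray, method: str = "spearman"
) -> tuple[float, float]:
    """Correlation between two per-site tracks with pairwise-complete masking.

    Returns (coefficient, two-sided p-value); methods: spearman, pearson,
    kendall. Raw p-values, no multiplicity adjustment.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need >= 3 jointly valid sites")
    if method == "spearman":
        r = stats.spearmanr(a[ok], b[ok])
    elif method == "pearson":
        r = stats.pearsonr(a[ok], b[ok])
    elif method == "kendall":
        r = stats.kendalltau(a[ok], b[ok])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


def apparent_speed_profile(timing: TimingProfile) -> np.ndarray:
    """Apparent replication speed 1 kb / |T_{j+1} - T_j| per adjacent pair.

    Length total_sites - 1; NaN where either site is masked or across a
    chromosome boundary; +inf where adjacent times are equal. For
    model-predicted profiles every finite value is >= the fork speed v.
    """
    t = timing.times
    grid = timing.grid
    out = np.full(grid.total_sites - 1, np.nan)
    for _, sl in grid.iter_chromosomes():
        sub = t[sl]
        m = grid.valid_mask[sl] & np.isfinite(sub)
        if sub.size < 2:
            continue
        dt = np.abs(np.diff(sub))
        pair_ok = m[:-1] & m[1:]
        with np.errstate(divide="ignore"):
            sp = np.where(dt > 0, 1.0 / np.where(dt > 0, dt, 1.0), np.inf)
        seg = np.full(sub.size - 1, np.nan)
        seg[pair_ok] = sp[pair_ok]
        out[sl.start : sl.stop - 1] = seg
    return out


def regions_to_bed(regions: list[MisfitRegion], path) -> None:
    """Write misfit regions as BED with the peak error in the name column."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chromosome, r.start_site)):
            fh.write(
                f"{r.chromosome}\t{r.start_bp}\t{r.end_bp}\t{r.peak_error:.6g}\n"
            )
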