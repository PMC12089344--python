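"""Genomic track input/output and Repli-seq timing extraction.

Supported text formats:

- bedGraph (4 columns, 0-based half-open) for signal and timing tracks;
- BED3+ for interval annotations (fragile sites, genes);
- a tab-separated site-by-bin matrix for cumulative Repli-seq fractions,
  whose header row carries the S-phase bin midpoints in minutes.

Timing extraction follows standard Repli-seq practice: ENCODE-style
wavelet-smoothed signals (0-100, higher = earlier by default) are rescaled
by a factor of 6 onto a nominal 0-600 min S phase, while multi-fraction
cumulative matrices are reduced to the median replication time t_rep — the
instant at which the fitted sigmoid crosses 50% replication.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .grid import SITE_BP, GenomeGrid, TimingProfile

__all__ = [
    "SignalTrack",
    "IntervalTrack",
    "RepliseqFractions",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed_intervals",
    "write_bed_intervals",
    "encode_signal_to_timing",
    "bin_track_to_grid",
    "fit_sigmoid_trep",
    "trep_profile",
    "timing_to_track",
    "values_to_track",
    "read_fractions_tsv",
    "write_fractions_tsv",
]

_SKIP = re.compile(r"^(track|browser|#)")


@dataclass
class SignalTrack:
    """Sorted, non-overlapping (chrom, start, end, value) records."""

    intervals: pd.DataFrame  # columns chrom, start, end, value
    value_units: str = ""

    def __post_init__(self) -> None:
        cols = ["chrom", "start", "end", "value"]
        self.intervals = self.intervals[cols].reset_index(drop=True)

    def normalize(self) -> "SignalTrack":
        """Sort records; overlapping intervals resolve last-writer-wins."""
        df = self.intervals
        out_rows = []
        had_overlap = False
        for chrom, sub in df.groupby("chrom", sort=True):
            # later records overwrite earlier ones where they overlap
            prev_end = -1
            rows = []
            for rec in sub.itertuples(index=True):
                rows.append([rec.Index, rec.chrom, rec.start, rec.end, rec.value])
            rows.sort(key=lambda r: (r[2], r[0]))
            kept: list[list] = []
            for row in rows:
                while kept and row[2] < kept[-1][3]:
                    had_overlap = True
                    if row[0] > kept[-1][0]:  # newer record wins
                        if kept[-1][2] < row[2]:
                            kept[-1][3] = row[2]  # truncate older record
                        else:
                            kept.pop()
                    else:
                        row[2] = kept[-1][3]  # older record is newer: clip this one
                if row[2] < row[3]:
                    kept.append(row)
            out_rows.extend(kept)
        if had_overlap:
            warnings.warn("overlapping intervals resolved last-writer-wins")
        out = pd.DataFrame(
            [(r[1], r[2], r[3], r[4]) for r in out_rows],
            columns=["chrom", "start", "end", "value"],
        )
        return SignalTrack(out, self.value_units)


@dataclass
class IntervalTrack:
    """BED-style annotation intervals with a class label per record."""

    intervals: pd.DataFrame  # columns chrom, start, end, name, class_label
    vocabulary: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        cols = ["chrom", "start", "end", "name", "class_label"]
        df = self.intervals[cols].reset_index(drop=True)
        if not self.vocabulary:
            self.vocabulary = tuple(sorted(df["class_label"].unique()))
        bad = set(df["class_label"]) - set(self.vocabulary)
        if bad:
            raise ValueError(f"class labels outside vocabulary: {sorted(bad)}")
        self.intervals = df.sort_values(["chrom", "start"]).reset_index(drop=True)


@dataclass
class RepliseqFractions:
    """Cumulative percent-replicated per site across ordered S-phase bins."""

    bins: np.ndarray  # bin midpoints, minutes, increasing
    fractions: np.ndarray  # (n_sites, n_bins), values in [0, 100]
    grid: GenomeGrid | None = None

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.bins.ndim != 1 or np.any(np.diff(self.bins) <= 0):
            raise ValueError("bins must be strictly increasing midpoints")
        if self.fractions.ndim != 2 or self.fractions.shape[1] != self.bins.size:
            raise ValueError("fractions must be (n_sites, n_bins)")


def read_bedgraph(path, value_units: str = "") -> SignalTrack:
    """Parse a 4-column bedGraph; track/browser/# lines are skipped.

    Malformed coordinates or values raise ValueError naming the line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or _SKIP.match(line):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            try:
                value = float(parts[3])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value {parts[3]!r}") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start {start}")
            rows.append((chrom, start, end, value))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return SignalTrack(df, value_units).normalize()


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a sorted bedGraph with full float precision."""
    df = track.normalize().intervals
    with open(path, "w") as fh:
        for rec in df.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.value:.10g}\n")


def read_bed_intervals(path, class_map: dict[str, str] | None = None) -> IntervalTrack:
    """Parse BED3+ intervals; classes attach via regex patterns on the name.

    class_map maps regex pattern -> class label (first match wins); records
    matching no pattern — or all records when class_map is None — use the
    5th BED column if present, else the name itself, as class.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or _SKIP.match(line):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end or start < 0:
                raise ValueError(f"{path}:{lineno}: bad interval [{start}, {end})")
            name = parts[3] if len(parts) > 3 else "."
            label = None
            if class_map:
                for pattern, cls in class_map.items():
                    if re.search(pattern, name):
                        label = cls
                        break
            if label is None:
                label = parts[4] if len(parts) > 4 else name
            rows.append((chrom, start, end, name, label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "class_label"])
    return IntervalTrack(df)


def write_bed_intervals(track: IntervalTrack, path) -> None:
    with open(path, "w") as fh:
        for rec in track.intervals.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t{rec.class_label}\n"
            )


def _bin_to_grid(track: SignalTrack, grid: GenomeGrid):
    """Coverage-weighted per-site sums; returns (weighted sum, covered bp, max)."""
    n = grid.total_sites
    wsum = np.zeros(n)
    cov = np.zeros(n)
    vmax = np.full(n, -np.inf)
    known = set(grid.chromosomes)
    for rec in track.intervals.itertuples(index=False):
        if rec.chrom not in known:
            continue
        sl = grid.chrom_slice(rec.chrom)
        chrom_sites = sl.stop - sl.start
        j0 = max(rec.start // SITE_BP, 0)
        j1 = min((rec.end - 1) // SITE_BP, chrom_sites - 1)
        if j1 < j0:
            continue
        for j in range(j0, j1 + 1):
            lo = max(rec.start, j * SITE_BP)
            hi = min(rec.end, (j + 1) * SITE_BP)
            k = sl.start + j
            wsum[k] += rec.value * (hi - lo)
            cov[k] += hi - lo
            vmax[k] = max(vmax[k], rec.value)
    return wsum, cov, vmax


def bin_track_to_grid(
    track: SignalTrack, grid: GenomeGrid, aggregation: str = "mean"
) -> np.ndarray:
    """Aggregate an interval track onto the 1-kb grid.

    mean: coverage-weighted mean of overlapping values; sum: integral of
    the signal density over the site (value x overlapping kb); max:
    maximum overlapping value. Uncovered sites are NaN.
    """
    if aggregation not in ("mean", "sum", "max"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    wsum, cov, vmax = _bin_to_grid(track.normalize(), grid)
    out = np.full(grid.total_sites, np.nan)
    covered = cov > 0
    if aggregation == "mean":
        out[covered] = wsum[covered] / cov[covered]
    elif aggregation == "sum":
        out[covered] = wsum[covered] / SITE_BP
    else:
        out[covered] = vmax[covered]
    return out


def encode_signal_to_timing(
    track: SignalTrack,
    grid: GenomeGrid,
    *,
    high_signal_early: bool = True,
    scale: float = 6.0,
    tolerance: float = 1e-6,
) -> TimingProfile:
    """ENCODE-style wavelet signal (0-100) -> replication time in minutes.

    The signal is coverage-weighted onto the grid, then mapped as
    T = (100 - s) * scale when high signal means early replication (the
    default orientation), or T = s * scale otherwise; the default scale 6
    spans a nominal 0-600 min S phase. Sites without coverage are masked.
    """
    values = np.asarray(track.intervals["value"], dtype=float)
    if values.size and (values.min() < -tolerance or values.max() > 100 + tolerance):
        raise ValueError("signal values outside [0, 100]")
    s = bin_track_to_grid(track, grid, "mean")
    covered = ~np.isnan(s)
    s = np.clip(s, 0.0, 100.0)
    t = (100.0 - s) * scale if high_signal_early else s * scale
    t[~covered] = np.nan
    new_grid = GenomeGrid(grid.chromosomes, grid.n_sites, grid.valid_mask & covered)
    return TimingProfile(t, new_grid, provenance="observed")


def _logistic(t, t0, k):
    return 100.0 / (1.0 + np.exp(-k * (t - t0)))


def _interp_crossing(bins: np.ndarray, y: np.ndarray) -> float:
    """Linear interpolation of the first 50% crossing."""
    above = y >= 50.0
    if not above.any() or above.all():
        return float("nan")
    i = int(np.argmax(above))
    if i == 0:
        return float(bins[0])
    x0, x1, y0, y1 = bins[i - 1], bins[i], y[i - 1], y[i]
    if y1 == y0:
        return float(0.5 * (x0 + x1))
    return float(x0 + (50.0 - y0) * (x1 - x0) / (y1 - y0))


def fit_sigmoid_trep(fractions: RepliseqFractions, site: int) -> tuple[float, bool]:
    """Median replication time t_rep of one site from its cumulative curve.

    Fits F(t) = 100 / (1 + exp(-k (t - t0))) by least squares and returns
    (t0, fallback_flag); when the fit fails to converge, t_rep falls back
    to linear interpolation of the 50% crossing (flag True). Degenerate
    sites (all near 0 or all near 100) return NaN.
    """
    bins = fractions.bins
    if bins.size < 4:
        raise ValueError("need >= 4 bins for a sigmoidal fit")
    y = fractions.fractions[site]
    if np.all(y <= 1.0) or np.all(y >= 99.0):
        return float("nan"), False
    guess_t0 = _interp_crossing(bins, y)
    if np.isnan(guess_t0):
        guess_t0 = float(bins[bins.size // 2])
    span = float(bins[-1] - bins[0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _logistic,
                bins,
                y,
                p0=(guess_t0, 10.0 / span),
                bounds=((bins[0] - span, 1e-6), (bins[-1] + span, np.inf)),
                maxfev=2000,
            )
        return float(popt[0]), False
    except (RuntimeError, ValueError):
        return _interp_crossing(bins, y), True


def trep_profile(fractions: RepliseqFractions, grid: GenomeGrid) -> TimingProfile:
    """t_rep for every site of a fraction matrix, as a timing profile.

    Sites whose t_rep is undefined (degenerate curves) are masked.
    """
    n = fractions.fractions.shape[0]
    if n != grid.total_sites:
        raise ValueError("fraction matrix does not match grid")
    t = np.empty(n)
    for j in range(n):
        t[j], _ = fit_sigmoid_trep(fractions, j)
    ok = ~np.isnan(t)
    t[ok] = np.maximum(t[ok], 0.0)
    new_grid = GenomeGrid(grid.chromosomes, grid.n_sites, grid.valid_mask & ok)
    return TimingProfile(t, new_grid, provenance="observed")


def timing_to_track(profile: TimingProfile, units: str = "min") -> SignalTrack:
    return values_to_track(profile.times, profile.grid, units, profile.grid.valid_mask)


def values_to_track(
    values: np.ndarray,
    grid: GenomeGrid,
    units: str = "",
    mask: np.ndarray | None = None,
) -> SignalTrack:
    """Per-site values -> one bedGraph record per (valid, finite) site."""
    rows = []
    keep = np.isfinite(values)
    if mask is not None:
        keep &= mask
    for name, sl in grid.iter_chromosomes():
        vals = values[sl]
        for j in np.nonzero(keep[sl])[0]:
            rows.append((name, int(j) * SITE_BP, (int(j) + 1) * SITE_BP, vals[j]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return SignalTrack(df, units)


def track_to_timing(track: SignalTrack, grid: GenomeGrid) -> TimingProfile:
    """Read back a per-site timing bedGraph written by timing_to_track."""
    t = bin_track_to_grid(track, grid, "mean")
    covered = ~np.isnan(t)
    t[~covered] = np.nan
    new_grid = GenomeGrid(grid.chromosomes, grid.n_sites, grid.valid_mask & covered)
    return TimingProfile(t, new_grid, provenance="observed")


def write_fractions_tsv(fractions: RepliseqFractions, path) -> None:
    """Site-by-bin matrix; header row holds the bin midpoints in minutes."""
    header = "site\t" + "\t".join(f"{b:.10g}" for b in fractions.bins)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for j, row in enumerate(fractions.fractions):
            fh.write(str(j) + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def read_fractions_tsv(path, grid: GenomeGrid | None = None) -> RepliseqFractions:
    df = pd.read_csv(path, sep="\t")
    bins = np.array([float(c) for c in df.columns[1:]])
    return RepliseqFractions(bins, df.iloc[:, 1:].to_numpy(float), grid)
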