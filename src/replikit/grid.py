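"""Genome lattice and per-site profile containers.

The genome is discretised into 1-kb sites. All profiles (firing rates,
replication timing, errors) are flat numpy arrays over the concatenation of
all chromosomes, with a :class:`GenomeGrid` holding the chromosome layout
and a validity mask for sites with missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import yaml

SITE_BP = 1000  # genomic span of one lattice site, bp


@dataclass(frozen=True)
class GenomeGrid:
    """1-kb site lattice over one or more chromosomes.

    Site ``j`` of a chromosome covers ``[j*1000, (j+1)*1000)`` bp,
    0-based half-open. Profiles are stored as flat arrays over the
    concatenated chromosomes in declaration order.
    """

    chromosomes: tuple[str, ...]
    n_sites: tuple[int, ...]
    valid_mask: np.ndarray  # bool, length = sum(n_sites)

    def __post_init__(self) -> None:
        if len(self.chromosomes) != len(self.n_sites):
            raise ValueError("chromosomes and n_sites length mismatch")
        if len(self.chromosomes) == 0:
            raise ValueError("grid needs at least one chromosome")
        if any(n < 1 for n in self.n_sites):
            raise ValueError("every chromosome needs >= 1 site")
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        mask = np.asarray(self.valid_mask, dtype=bool)
        if mask.shape != (self.total_sites,):
            raise ValueError(
                f"valid_mask length {mask.shape} != total sites {self.total_sites}"
            )
        object.__setattr__(self, "valid_mask", mask)

    @classmethod
    def from_sizes(
        cls, sizes: Mapping[str, int], valid_mask: np.ndarray | None = None
    ) -> "GenomeGrid":
        names = tuple(sizes)
        counts = tuple(int(sizes[c]) for c in names)
        if valid_mask is None:
            valid_mask = np.ones(sum(counts), dtype=bool)
        return cls(names, counts, valid_mask)

    @property
    def total_sites(self) -> int:
        return int(sum(self.n_sites))

    @property
    def offsets(self) -> np.ndarray:
        """Start offset of each chromosome in the flat arrays (+ total at end)."""
        return np.concatenate(([0], np.cumsum(self.n_sites)))

    def chrom_slice(self, chromosome: str) -> slice:
        i = self.chromosomes.index(chromosome)
        off = self.offsets
        return slice(int(off[i]), int(off[i + 1]))

    def iter_chromosomes(self) -> Iterator[tuple[str, slice]]:
        off = self.offsets
        for i, name in enumerate(self.chromosomes):
            yield name, slice(int(off[i]), int(off[i + 1]))

    def site_to_coord(self, flat_index: int) -> tuple[str, int, int]:
        """Flat site index -> (chromosome, start bp, end bp), 0-based half-open."""
        off = self.offsets
        if not 0 <= flat_index < self.total_sites:
            raise IndexError(flat_index)
        ci = int(np.searchsorted(off, flat_index, side="right")) - 1
        j = flat_index - int(off[ci])
        return self.chromosomes[ci], j * SITE_BP, (j + 1) * SITE_BP

    def coord_to_site(self, chromosome: str, position_bp: int) -> int:
        """(chromosome, bp) -> flat site index of the covering site."""
        i = self.chromosomes.index(chromosome)
        j = position_bp // SITE_BP
        if not 0 <= j < self.n_sites[i]:
            raise IndexError(f"{chromosome}:{position_bp} outside grid")
        return int(self.offsets[i]) + int(j)


def _check_profile(values: np.ndarray, grid: GenomeGrid, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (grid.total_sites,):
        raise ValueError(f"{name} length {arr.shape} != grid sites {grid.total_sites}")
    return arr


@dataclass
class FiringRateProfile:
    """Per-site origin firing rates f_j, in events per minute."""

    rates: np.ndarray
    grid: GenomeGrid

    def __post_init__(self) -> None:
        self.rates = _check_profile(self.rates, self.grid, "rates")

    def validate(self, rate_floor: float, rate_cap: float) -> None:
        r = self.rates
        if np.any(~np.isfinite(r)) or np.any(r <= 0):
            raise ValueError("firing rates must be finite and > 0")
        if np.any(r < rate_floor) or np.any(r > rate_cap):
            raise ValueError("firing rates outside [rate_floor, rate_cap]")

    def copy(self) -> "FiringRateProfile":
        return FiringRateProfile(self.rates.copy(), self.grid)


@dataclass
class TimingProfile:
    """Per-site replication time T_j in minutes.

    ``provenance`` records where the profile came from: ``observed`` (data),
    ``predicted`` (closed-form expectation), or ``simulated-mean``
    (ensemble average). Masked sites may hold NaN.
    """

    times: np.ndarray
    grid: GenomeGrid
    provenance: str = "observed"

    def __post_init__(self) -> None:
        self.times = _check_profile(self.times, self.grid, "times")
        if self.provenance not in ("observed", "predicted", "simulated-mean"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        valid = self.grid.valid_mask
        t = self.times[valid]
        if t.size and (np.any(~np.isfinite(t)) or np.any(t < 0)):
            raise ValueError("times must be finite and >= 0 on valid sites")

    def copy(self) -> "TimingProfile":
        return TimingProfile(self.times.copy(), self.grid, self.provenance)


@dataclass(frozen=True)
class ModelConfig:
    """Global model parameters.

    fork_speed_v : kb/min, constant bidirectional fork speed.
    radius_R : sites (= kb), radius of influence of neighbouring origins.
    alpha : exponent of the multiplicative rate update.
    max_iterations : fitting iterations after initialisation.
    rate_floor, rate_cap : clip bounds for firing rates, min^-1.
    series_tail_tolerance : early-stop threshold on the survival factor
        exp(-S_k/v) in the timing series.
    early_stop_tol : optional relative-MSE-improvement threshold that stops
        fitting before max_iterations (None disables).
    n_simulations : ensemble size for stochastic simulation.
    base_seed : seed of simulation replicate 0 (replicate i uses base_seed+i).
    fork_motion_mode : 'erlang' (1-kb step times ~ Exp(v)) or
        'deterministic' (each step exactly 1/v min).
    """

    fork_speed_v: float = 1.4
    radius_R: int = 2000
    alpha: float = 2.0
    max_iterations: int = 20
    rate_floor: float = 1e-10
    rate_cap: float = 10.0
    series_tail_tolerance: float = 1e-12
    early_stop_tol: float | None = None
    n_simulations: int = 500
    base_seed: int = 0
    fork_motion_mode: str = "erlang"

    def __post_init__(self) -> None:
        if self.fork_speed_v <= 0:
            raise ValueError("fork_speed_v must be > 0")
        if self.radius_R < 1:
            raise ValueError("radius_R must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.rate_floor <= 0 or self.rate_cap <= self.rate_floor:
            raise ValueError("need 0 < rate_floor < rate_cap")
        if self.fork_motion_mode not in ("erlang", "deterministic"):
            raise ValueError(f"unknown fork_motion_mode {self.fork_motion_mode!r}")

    def with_overrides(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "fork_speed_v": self.fork_speed_v,
            "radius_R": self.radius_R,
            "alpha": self.alpha,
            "max_iterations": self.max_iterations,
            "rate_floor": self.rate_floor,
            "rate_cap": self.rate_cap,
            "series_tail_tolerance": self.series_tail_tolerance,
            "early_stop_tol": self.early_stop_tol,
            "n_simulations": self.n_simulations,
            "base_seed": self.base_seed,
            "fork_motion_mode": self.fork_motion_mode,
        }

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        unknown = set(data) - set(cls().to_dict())
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
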