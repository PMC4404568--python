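"""Shared domain types for LC-HRMS parameter optimization.

Conventions used throughout the package: retention time is in seconds,
m/z in Da, all intervals are closed, and peak ``intensity`` is the apex
height of the detected chromatographic peak (not the integrated area).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "SchemaError",
    "EmptyInputError",
    "ValidationError",
    "InfeasibleRangeError",
    "CentroidScan",
    "Run",
    "RunSet",
    "Peak",
    "PeakClassification",
    "FeatureGroup",
    "ParameterSpace",
    "select_center_run",
]


class FormatError(ValueError):
    """Raised when an input file is not in the expected format."""


class SchemaError(ValueError):
    """Raised when a tabular input lacks the required columns."""


class EmptyInputError(ValueError):
    """Raised when an input contains no usable data (e.g. zero MS1 scans)."""


class ValidationError(ValueError):
    """Raised when values violate a type invariant; message locates the value."""


class InfeasibleRangeError(ValueError):
    """Raised when a parameter-range adjustment cannot satisfy floors/orderings."""


@dataclass(frozen=True)
class CentroidScan:
    """One centroided MS1 scan: sticks of (m/z, intensity) at a retention time."""

    rt: float
    mz_values: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz_values, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "mz_values", mz)
        object.__setattr__(self, "intensities", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValidationError(
                f"scan at rt={self.rt}: m/z and intensity arrays must be 1-D and equal length"
            )
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise ValidationError(f"scan at rt={self.rt}: m/z values must be strictly increasing")
        if np.any(inten < 0):
            raise ValidationError(f"scan at rt={self.rt}: negative intensity")

    @property
    def n_centroids(self) -> int:
        return int(self.mz_values.size)


@dataclass
class Run:
    """One injection: centroided MS1 scans ordered by retention time."""

    run_id: str
    scans: list[CentroidScan]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValidationError(f"run {self.run_id!r}: scan retention times must be strictly increasing")

    @property
    def scan_times(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans], dtype=float)

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    def total_intensity(self) -> float:
        return float(sum(float(s.intensities.sum()) for s in self.scans))


@dataclass
class RunSet:
    """Ordered collection of runs: repeated injections of one pooled sample."""

    runs: list[Run]

    def __post_init__(self) -> None:
        ids = [r.run_id for r in self.runs]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate run ids in run set: {ids}")

    def __iter__(self):
        return iter(self.runs)

    def __len__(self) -> int:
        return len(self.runs)

    @property
    def run_ids(self) -> list[str]:
        return [r.run_id for r in self.runs]

    def get(self, run_id: str) -> Run:
        for r in self.runs:
            if r.run_id == run_id:
                return r
        raise KeyError(run_id)


@dataclass(frozen=True)
class Peak:
    """A detected chromatographic peak from one run.

    ``intensity`` is the apex height; ``rt`` the apex time in seconds.
    """

    run_id: str
    mz: float
    mzmin: float
    mzmax: float
    rt: float
    rtmin: float
    rtmax: float
    intensity: float

    def validate(self, where: str = "peak") -> None:
        if not (self.mzmin <= self.mz <= self.mzmax):
            raise ValidationError(f"{where}: mzmin <= mz <= mzmax violated ({self.mzmin}, {self.mz}, {self.mzmax})")
        if not (self.rtmin <= self.rt <= self.rtmax):
            raise ValidationError(f"{where}: rtmin <= rt <= rtmax violated ({self.rtmin}, {self.rt}, {self.rtmax})")
        if not self.intensity > 0:
            raise ValidationError(f"{where}: intensity must be > 0 (got {self.intensity})")

    @property
    def rt_width(self) -> float:
        return self.rtmax - self.rtmin


# Peak classification labels
RP = "RP"
LIP = "LIP"
UNRELIABLE = "UNRELIABLE"


@dataclass
class PeakClassification:
    """Per-peak labels from isotopologue detection and the low-intensity cut-off.

    ``labels[i]`` is one of RP / LIP / UNRELIABLE for the i-th peak of the list
    the classification was computed from.  ``partners`` maps the index of a
    ¹²C parent peak to the indices of its accepted ¹³C isotopologue peaks.
    """

    labels: np.ndarray
    partners: dict[int, list[int]] = field(default_factory=dict)
    lip_cutoff: float | None = None

    @property
    def n_peaks(self) -> int:
        return int(self.labels.size)

    @property
    def n_rp(self) -> int:
        return int(np.sum(self.labels == RP))

    @property
    def n_lip(self) -> int:
        return int(np.sum(self.labels == LIP))


@dataclass
class FeatureGroup:
    """Peaks from different runs grouped as one feature."""

    member_peaks: list[Peak]

    def __post_init__(self) -> None:
        if not self.member_peaks:
            raise ValidationError("feature group must contain at least one peak")

    @property
    def runs_represented(self) -> Counter:
        return Counter(p.run_id for p in self.member_peaks)

    @property
    def n_peaks(self) -> int:
        return len(self.member_peaks)

    @property
    def median_rt(self) -> float:
        return float(np.median([p.rt for p in self.member_peaks]))

    @property
    def mz_center(self) -> float:
        return float(np.median([p.mz for p in self.member_peaks]))

    @property
    def rts(self) -> np.ndarray:
        return np.array([p.rt for p in self.member_peaks], dtype=float)


@dataclass
class ParameterSpace:
    """Optimizable parameters (current low/high range) plus fixed parameters.

    ``constraints`` are pairwise orderings ``(a, b)`` meaning the value of
    parameter ``a`` must stay below the value of ``b``; ``floors`` are hard
    lower limits applied after any range adjustment.
    """

    optimized: dict[str, tuple[float, float]]
    fixed: dict[str, float] = field(default_factory=dict)
    constraints: list[tuple[str, str]] = field(default_factory=list)
    floors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.optimized.items():
            if not lo < hi:
                raise ValidationError(f"parameter {name!r}: low {lo} must be < high {hi}")
            floor = self.floors.get(name)
            if floor is not None and lo < floor:
                raise ValidationError(f"parameter {name!r}: low {lo} below floor {floor}")

    @property
    def names(self) -> list[str]:
        return list(self.optimized)

    @property
    def k(self) -> int:
        return len(self.optimized)

    def center(self, name: str) -> float:
        lo, hi = self.optimized[name]
        return 0.5 * (lo + hi)

    def half_width(self, name: str) -> float:
        lo, hi = self.optimized[name]
        return 0.5 * (hi - lo)

    def decode(self, coded: Sequence[float]) -> dict[str, float]:
        """Map a coded point in [-1, 1]^k to real parameter settings (fixed included)."""
        out = dict(self.fixed)
        for name, x in zip(self.names, coded):
            out[name] = self.center(name) + float(x) * self.half_width(name)
        return out

    def encode(self, settings: Mapping[str, float]) -> np.ndarray:
        return np.array(
            [(settings[n] - self.center(n)) / self.half_width(n) for n in self.names], dtype=float
        )


def select_center_run(runset: RunSet, peaklists: Mapping[str, Sequence[Peak]]) -> str:
    """Pick the run whose peaks have the highest mean intensity.

    This run serves as the alignment reference; ties go to the first run in
    the run set's input order, and runs without any picked peak are skipped.
    """
    best_id, best_mean = None, -np.inf
    any_peaks = False
    for run in runset:
        peaks = peaklists.get(run.run_id, ())
        if not peaks:
            continue
        any_peaks = True
        mean = float(np.mean([p.intensity for p in peaks]))
        if mean > best_mean:
            best_id, best_mean = run.run_id, mean
    if not any_peaks:
        raise EmptyInputError("cannot select a center run: every run has an empty peak list")
    return best_id
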