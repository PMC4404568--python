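"""Target values for the optimization: peak-picking score from natural ¹³C
isotopologues, retention-time correction score from within-group RT
coherence, and grouping score from pooled-sample group completeness.

The peak-picking score (PPS) rewards parameter settings under which many of
the detected peaks can be validated by a co-eluting ¹³C isotopologue:

    PPS = RP² / (all peaks − LIP)

where RP (reliable peaks) are peaks belonging to a detected isotopologue
pair and LIP (low-intensity peaks) are peaks whose best-case isotope signal
would fall below the instrument's sensitivity cut-off, so their lack of an
isotope partner is not evidence against them.  Squaring RP creates the
optimization force: raising RP and the total count by the same amount still
raises the score.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import LIP, RP, UNRELIABLE, FeatureGroup, Peak, PeakClassification

__all__ = [
    "IsotopeCriteria",
    "ScoreReport",
    "AlignScoreReport",
    "max_carbons",
    "find_isotopologues",
    "classify_lip",
    "compute_pps",
    "pps_from_counts",
    "compute_grts",
    "compute_arts",
    "compute_rcs",
    "classify_groups",
    "compute_gs",
    "compute_rgtv",
]

#: Exact masses (Da) of the hydrocarbon-chain building blocks used by maxC.
CH2_MASS = 14.015650
CH3_MASS = 15.023475
#: Mass difference between ¹³C and ¹²C, Da.
C13_C12_DELTA = 1.0033548
#: Natural abundance of ¹³C.
NATURAL_13C_ABUNDANCE = 0.01108


@dataclass(frozen=True)
class IsotopeCriteria:
    """Tolerances of the three isotopologue acceptance criteria.

    A candidate pair (parent p, isotope q) is accepted iff
      1. mass: q lies within ``mass_tol_ppm`` of p.mz + ``iso_mass_delta``;
      2. co-elution: the RT extents overlap and the apex distance is at most
         ``rt_window_frac`` of the parent's RT width;
      3. intensity: q's apex lies in [IA·I, maxC(p.mz)·IA·I], optionally
         widened by ``intensity_slack`` on each side.

    Charge 1 is assumed throughout.
    """

    iso_mass_delta: float = C13_C12_DELTA
    mass_tol_ppm: float = 10.0
    rt_window_frac: float = 0.5
    intensity_slack: float = 0.0
    ia: float = NATURAL_13C_ABUNDANCE
    lip_fraction: float = 0.03

    def __post_init__(self) -> None:
        if not (0.0 < self.ia < 1.0):
            raise ValueError(f"isotope abundance must be in (0, 1), got {self.ia}")
        if self.mass_tol_ppm <= 0 or self.rt_window_frac <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class ScoreReport:
    """Peak-picking score with its underlying counts."""

    n_peaks: int
    n_rp: int
    n_lip: int
    pps: float
    lip_cutoff: float | None = None
    per_run: dict = field(default_factory=dict)


@dataclass
class AlignScoreReport:
    """Retention-time correction and grouping scores for one experiment."""

    n_groups: int
    arts: float
    rcs: float
    n_reliable: int
    n_nonreliable: int
    gs: float
    grts: list[float] = field(default_factory=list)
    rgtv: float | None = None  # filled per DoE round (needs the round's peers)


def max_carbons(mz: float) -> int:
    """Maximum number of carbon atoms a singly-charged ion of this m/z could
    carry, assuming a hydrocarbon chain: floor((mz − 2·CH3)/CH2) + 2.

    Below the two-CH3 minimum (one ethane-like unit) the model does not
    apply and 0 is returned.
    """
    num = mz - 2.0 * CH3_MASS
    if num < -1e-9:
        return 0
    # tiny epsilon keeps exact-boundary masses (num == 0) from flooring to -1
    return int(math.floor(num / CH2_MASS + 1e-9)) + 2


def _peak_arrays(peaks: Sequence[Peak]):
    mz = np.array([p.mz for p in peaks], dtype=float)
    rt = np.array([p.rt for p in peaks], dtype=float)
    rtmin = np.array([p.rtmin for p in peaks], dtype=float)
    rtmax = np.array([p.rtmax for p in peaks], dtype=float)
    inten = np.array([p.intensity for p in peaks], dtype=float)
    return mz, rt, rtmin, rtmax, inten


def find_isotopologues(
    peaks: Sequence[Peak], criteria: IsotopeCriteria = IsotopeCriteria()
) -> PeakClassification:
    """Label peaks that belong to a ¹³C isotopologue pair as reliable (RP).

    Every (parent, candidate) pair passing all three criteria marks both
    members RP; ``partners`` records the accepted pairs by index into
    ``peaks``.  Peaks are expected to come from a single run.
    """
    n = len(peaks)
    labels = np.full(n, UNRELIABLE, dtype=object)
    partners: dict[int, list[int]] = {}
    if n == 0:
        return PeakClassification(labels=labels, partners=partners)

    mz, rt, rtmin, rtmax, inten = _peak_arrays(peaks)
    order = np.argsort(mz, kind="stable")
    mz_sorted = mz[order]

    for p in range(n):
        target = mz[p] + criteria.iso_mass_delta
        tol = criteria.mass_tol_ppm * mz[p] * 1e-6
        lo = int(np.searchsorted(mz_sorted, target - tol, side="left"))
        hi = int(np.searchsorted(mz_sorted, target + tol, side="right"))
        if lo >= hi:
            continue
        cand = order[lo:hi]
        cand = cand[cand != p]
        if cand.size == 0:
            continue
        # co-elution: RT extent overlap plus apex proximity relative to parent width
        overlap = (rtmin[cand] <= rtmax[p]) & (rtmax[cand] >= rtmin[p])
        width = rtmax[p] - rtmin[p]
        close = np.abs(rt[cand] - rt[p]) <= criteria.rt_window_frac * width
        # intensity window from 1 to maxC carbon atoms at natural abundance
        mc = max_carbons(mz[p])
        lo_int = criteria.ia * inten[p] / (1.0 + criteria.intensity_slack)
        hi_int = mc * criteria.ia * inten[p] * (1.0 + criteria.intensity_slack)
        in_window = (inten[cand] >= lo_int) & (inten[cand] <= hi_int)
        ok = cand[overlap & close & in_window]
        if ok.size:
            labels[p] = RP
            labels[ok] = RP
            partners.setdefault(p, []).extend(int(q) for q in ok)

    return PeakClassification(labels=labels, partners=partners)


def classify_lip(
    peaks: Sequence[Peak],
    classification: PeakClassification,
    criteria: IsotopeCriteria = IsotopeCriteria(),
) -> PeakClassification:
    """Mark non-RP peaks as LIP when even a maxC-carbon isotope signal would
    fall below the sensitivity cut-off.

    The cut-off is the mean of the lowest 3% of all peak intensities (at
    least one value).  The comparison is strict: a predicted isotope
    intensity exactly at the cut-off is *not* LIP.
    """
    n = len(peaks)
    if n == 0:
        return classification
    inten = np.array([p.intensity for p in peaks], dtype=float)
    n_low = max(1, math.ceil(criteria.lip_fraction * n))
    cutoff = float(np.sort(inten)[:n_low].mean())
    labels = classification.labels.copy()
    for i, p in enumerate(peaks):
        if labels[i] == RP:
            continue
        predicted = p.intensity * max_carbons(p.mz) * criteria.ia
        if predicted < cutoff:
            labels[i] = LIP
    return PeakClassification(labels=labels, partners=classification.partners, lip_cutoff=cutoff)


def pps_from_counts(n_rp: int, n_peaks: int, n_lip: int) -> float:
    """PPS = RP² / (all − LIP); zero when RP = 0 or the denominator is ≤ 0."""
    denom = n_peaks - n_lip
    if n_rp <= 0 or denom <= 0:
        return 0.0
    return float(n_rp) ** 2 / float(denom)


def compute_pps(classification: PeakClassification) -> ScoreReport:
    n, n_rp, n_lip = classification.n_peaks, classification.n_rp, classification.n_lip
    return ScoreReport(
        n_peaks=n,
        n_rp=n_rp,
        n_lip=n_lip,
        pps=pps_from_counts(n_rp, n, n_lip),
        lip_cutoff=classification.lip_cutoff,
    )


def compute_grts(group: FeatureGroup | Sequence[float]) -> float:
    """Group retention-time shift: mean |median(rts) − rt| over members."""
    rts = group.rts if isinstance(group, FeatureGroup) else np.asarray(group, dtype=float)
    if rts.size == 0:
        raise ValueError("GRTS of an empty group is undefined")
    return float(np.mean(np.abs(np.median(rts) - rts)))


def compute_arts(groups: Sequence[FeatureGroup]) -> float:
    """Average retention-time shift: mean GRTS over all groups."""
    if len(groups) == 0:
        raise ValueError("ARTS of zero groups is undefined")
    return float(np.mean([compute_grts(g) for g in groups]))


def compute_rcs(groups: Sequence[FeatureGroup]) -> float:
    """Retention-time correction score: 1/ARTS.

    Perfect alignment (ARTS = 0) returns ``inf`` as a sentinel; the DoE
    round's unity-based normalization maps it to the round's best value.
    Zero groups yield 0 with a warning (nothing to assess).
    """
    if len(groups) == 0:
        warnings.warn("RCS undefined for zero groups; reporting 0", stacklevel=2)
        return 0.0
    arts = compute_arts(groups)
    if arts == 0.0:
        return math.inf
    return 1.0 / arts


def classify_groups(groups: Sequence[FeatureGroup], n_runs: int) -> tuple[int, int]:
    """Count reliable vs non-reliable groups.

    A reliable group shows exactly one peak from each injection of the
    pooled sample; anything else (missing run, duplicate peaks in a run) is
    non-reliable.
    """
    n_rel = 0
    for g in groups:
        reps = g.runs_represented
        if len(reps) == n_runs and all(c == 1 for c in reps.values()):
            n_rel += 1
    return n_rel, len(groups) - n_rel


def compute_gs(n_reliable: int, n_nonreliable: int) -> float:
    """Grouping score: reliable² / non-reliable (denominator 1 when none)."""
    if n_reliable <= 0:
        return 0.0
    denom = n_nonreliable if n_nonreliable > 0 else 1
    return float(n_reliable) ** 2 / float(denom)


def _unity_norm(values: np.ndarray) -> np.ndarray:
    """Unity-based normalization within one DoE round; ``inf`` sentinels are
    first mapped to the round's largest finite value, and an all-equal round
    normalizes to 0.5 everywhere so the other score decides the ranking."""
    v = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(v)
    if not finite.all():
        if finite.any():
            v[~finite] = v[finite].max()
        else:
            v[:] = 0.0
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return np.full_like(v, 0.5)
    return (v - vmin) / (vmax - vmin)


def compute_rgtv(rcs_values: Sequence[float], gs_values: Sequence[float]) -> np.ndarray:
    """Per-experiment combined target value: norm(RCS) + norm(GS), where
    ``norm`` scales each score to [0, 1] across the experiments of one DoE."""
    rcs = np.asarray(rcs_values, dtype=float)
    gs = np.asarray(gs_values, dtype=float)
    if rcs.shape != gs.shape:
        raise ValueError(f"RCS and GS lists differ in length ({rcs.size} vs {gs.size})")
    if rcs.size < 2:
        raise ValueError("RGTV normalization needs at least two experiments per DoE")
    return _unity_norm(rcs) + _unity_norm(gs)
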