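"""Semi-sequential parameter optimization.

Peak-picking parameters are optimized first against the peak-picking score
(PPS), then retention-time correction and grouping parameters are optimized
simultaneously against the per-round normalized combined target (RGTV),
using the peak lists picked with the best settings of the first stage.
Each stage iterates DoE rounds while its score keeps strictly increasing
and returns the global best over all evaluated experiments.

RGTV is normalized within one round, so rounds of the second stage are
compared on the lexicographic (GS, RCS) pair of each round's best
experiment — a round improves if it improves GS, or ties GS and improves
RCS.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment import AlignParams, GroupParams, align_run, apply_warp, group_density, make_profiles, similarity_matrix
from .doe import DoEResult, run_doe_round
from .model import (
    EmptyInputError,
    ParameterSpace,
    Peak,
    RunSet,
    ValidationError,
    select_center_run,
)
from .picking import PickParams, pick_peaks
from .scoring import (
    AlignScoreReport,
    IsotopeCriteria,
    ScoreReport,
    classify_groups,
    classify_lip,
    compute_arts,
    compute_gs,
    compute_rgtv,
    find_isotopologues,
    pps_from_counts,
)

__all__ = [
    "OptimizationResult",
    "default_pick_space",
    "default_align_space",
    "score_picking",
    "score_align_group",
    "optimize_peak_picking",
    "optimize_align_group",
    "run_full_optimization",
]

logger = logging.getLogger("lcmsopt")

PICK_PARAM_NAMES = {"ppm", "min_peakwidth", "max_peakwidth", "mzdiff", "noise", "prefilter_k", "prefilter_I"}
ALIGN_PARAM_NAMES = {"profStep", "gapInit", "gapExtend"}
GROUP_PARAM_NAMES = {"bw", "mzwid", "minfrac"}


def default_pick_space() -> ParameterSpace:
    """Start ranges for the peak-picking stage, centered on common defaults
    for high-resolution centroid data (peakwidth 20-50 s, ppm 25)."""
    return ParameterSpace(
        optimized={
            "min_peakwidth": (12.0, 28.0),
            "max_peakwidth": (35.0, 65.0),
            "ppm": (10.0, 40.0),
        },
        fixed={"mzdiff": 0.005, "noise": 0.0, "prefilter_k": 3, "prefilter_I": 100.0},
        constraints=[("min_peakwidth", "max_peakwidth")],
        floors={"min_peakwidth": 0.5, "max_peakwidth": 1.0, "ppm": 0.1},
    )


def default_align_space() -> ParameterSpace:
    """Start ranges for the alignment/grouping stage.

    mzwid is fixed at 0.025 Da (the 0.25 default is far too wide for
    high-resolution data) and minfrac at 1.0: the pooled sample is injected
    repeatedly, so a trustworthy feature should appear in every injection.
    """
    return ParameterSpace(
        optimized={
            "gapInit": (0.0, 0.8),
            "gapExtend": (0.5, 2.5),
            "bw": (3.0, 15.0),
        },
        fixed={"profStep": 1.0, "mzwid": 0.025, "minfrac": 1.0},
        constraints=[],
        floors={"gapInit": 0.0, "gapExtend": 0.0, "bw": 0.25, "profStep": 0.05,
                "mzwid": 1e-4, "minfrac": 0.05},
    )


@dataclass
class OptimizationResult:
    rounds: list[DoEResult]
    best_settings: dict[str, float]
    best_score: float
    stop_reason: str  # no_improvement | max_rounds | range_infeasible | nothing_to_optimize
    best_raw: object = None

    def to_dict(self) -> dict:
        return {
            "rounds": [r.to_dict() for r in self.rounds],
            "best_settings": self.best_settings,
            "best_score": self.best_score,
            "stop_reason": self.stop_reason,
        }


def _pick_params_from(settings: Mapping[str, float]) -> PickParams:
    kw = {k: settings[k] for k in PICK_PARAM_NAMES if k in settings}
    if "prefilter_k" in kw:
        kw["prefilter_k"] = int(round(kw["prefilter_k"]))
    return PickParams(**kw)


def score_picking(
    runset: RunSet,
    settings: Mapping[str, float],
    criteria: IsotopeCriteria = IsotopeCriteria(),
    peaklists_out: dict | None = None,
) -> ScoreReport:
    """Pick every run with the given settings and compute one pooled PPS.

    Counts (RP, all peaks, LIP) are summed over the runs of the experiment
    and the score formula applied once, yielding a single scalar per
    experiment for the response surface.
    """
    params = _pick_params_from(settings)
    n_peaks = n_rp = n_lip = 0
    per_run = {}
    for run in runset:
        peaks = pick_peaks(run, params)
        cls = find_isotopologues(peaks, criteria)
        cls = classify_lip(peaks, cls, criteria)
        per_run[run.run_id] = {"n_peaks": cls.n_peaks, "n_rp": cls.n_rp, "n_lip": cls.n_lip}
        n_peaks += cls.n_peaks
        n_rp += cls.n_rp
        n_lip += cls.n_lip
        if peaklists_out is not None:
            peaklists_out[run.run_id] = peaks
    return ScoreReport(
        n_peaks=n_peaks,
        n_rp=n_rp,
        n_lip=n_lip,
        pps=pps_from_counts(n_rp, n_peaks, n_lip),
        per_run=per_run,
    )


class _AlignEvaluator:
    """Aligns, groups and scores one experiment's settings; caches the
    per-profStep profile matrices and scan-pair similarity matrices, which
    do not depend on the gap penalties or grouping parameters."""

    def __init__(self, runset: RunSet, peaklists: Mapping[str, Sequence[Peak]], center_id: str):
        self.runset = runset
        self.peaklists = {k: list(v) for k, v in peaklists.items()}
        self.center_id = center_id
        self._cache: dict[float, tuple] = {}

    def _profiles(self, prof_step: float):
        key = round(float(prof_step), 12)
        if key not in self._cache:
            profiles = make_profiles(list(self.runset), prof_step)
            by_id = {run.run_id: prof for run, prof in zip(self.runset, profiles)}
            center = by_id[self.center_id]
            sims = {
                rid: similarity_matrix(prof, center)
                for rid, prof in by_id.items()
                if rid != self.center_id
            }
            self._cache[key] = (by_id, sims)
        return self._cache[key]

    def __call__(self, settings: Mapping[str, float]) -> AlignScoreReport:
        align = AlignParams(
            profStep=float(settings["profStep"]),
            gapInit=float(settings["gapInit"]),
            gapExtend=float(settings["gapExtend"]),
        )
        group = GroupParams(
            bw=float(settings["bw"]),
            mzwid=float(settings["mzwid"]),
            minfrac=float(settings["minfrac"]),
        )
        align.validate()
        group.validate()
        by_id, sims = self._profiles(align.profStep)
        center = by_id[self.center_id]
        warped: dict[str, list[Peak]] = {}
        for rid, peaks in self.peaklists.items():
            if rid == self.center_id:
                warped[rid] = list(peaks)
            else:
                warp = align_run(by_id[rid], center, align, similarity=sims[rid])
                warped[rid] = apply_warp(peaks, warp)
        groups = group_density(warped, group, n_runs=len(self.runset))
        n_rel, n_nonrel = classify_groups(groups, n_runs=len(self.runset))
        if groups:
            arts = compute_arts(groups)
            rcs = float("inf") if arts == 0.0 else 1.0 / arts
        else:
            arts, rcs = float("nan"), 0.0
        return AlignScoreReport(
            n_groups=len(groups),
            arts=arts,
            rcs=rcs,
            n_reliable=n_rel,
            n_nonreliable=n_nonrel,
            gs=compute_gs(n_rel, n_nonrel),
        )


def _rgtv_transform(raw: list) -> list[float]:
    """Compute per-round RGTV from raw AlignScoreReports (None rows → NaN)."""
    idx = [i for i, r in enumerate(raw) if r is not None]
    scores = [np.nan] * len(raw)
    if len(idx) >= 2:
        rgtv = compute_rgtv([raw[i].rcs for i in idx], [raw[i].gs for i in idx])
        for i, v in zip(idx, rgtv):
            scores[i] = float(v)
            raw[i].rgtv = float(v)
    return scores


def optimize_peak_picking(
    runset: RunSet,
    space: ParameterSpace | None = None,
    criteria: IsotopeCriteria = IsotopeCriteria(),
    max_rounds: int = 10,
    n_workers: int = 1,
) -> OptimizationResult:
    """Optimize peak-picking parameters against the pooled PPS.

    Rounds continue while the best PPS strictly increases (up to
    ``max_rounds``); the returned settings are the global best over every
    evaluated experiment.  Infeasible decoded settings (min_peakwidth ≥
    max_peakwidth) score 0, penalizing that region of the surface.
    """
    if len(runset) == 0:
        raise EmptyInputError("run set is empty")
    space = default_pick_space() if space is None else space

    def evaluate(settings: Mapping[str, float]) -> ScoreReport:
        params = _pick_params_from(settings)
        if params.violations():
            return ScoreReport(n_peaks=0, n_rp=0, n_lip=0, pps=0.0)
        return score_picking(runset, settings, criteria)

    def transform(raw: list) -> list[float]:
        return [np.nan if r is None else r.pps for r in raw]

    rounds: list[DoEResult] = []
    best_score = -np.inf
    best_settings: dict[str, float] = space.decode(np.zeros(space.k))
    best_raw = None
    stop_reason = "max_rounds"
    for rnd in range(max_rounds):
        result = run_doe_round(space, evaluate, score_transform=transform, n_workers=n_workers)
        rounds.append(result)
        if rnd == 0 and all(r is None or r.n_peaks == 0 for r in result.raw_results):
            raise EmptyInputError(
                "no peaks detected in any experiment of the first round; "
                "check the start ranges and the noise floor"
            )
        i = result.best_row
        round_best = result.scores[i]
        logger.info("picking round %d: best PPS %.4g at %s", rnd + 1, round_best, result.design.settings[i])
        if round_best > best_score:
            best_score = round_best
            best_settings = dict(result.design.settings[i])
            best_raw = result.raw_results[i]
        else:
            stop_reason = "no_improvement"
            break
        if result.focus.next_space is None:
            stop_reason = "range_infeasible"
            break
        space = result.focus.next_space
    return OptimizationResult(
        rounds=rounds,
        best_settings=best_settings,
        best_score=float(best_score),
        stop_reason=stop_reason,
        best_raw=best_raw,
    )


def optimize_align_group(
    runset: RunSet,
    peaklists: Mapping[str, Sequence[Peak]],
    space: ParameterSpace | None = None,
    max_rounds: int = 10,
    n_workers: int = 1,
) -> OptimizationResult:
    """Optimize RT-correction and grouping parameters simultaneously.

    Peak picking is never re-run here (the semi-sequential split); the
    supplied peak lists come from the best picking settings.  Within a round
    experiments are ranked by RGTV; across rounds the best experiment's
    (GS, RCS) pair must improve lexicographically for the loop to continue.
    """
    if len(runset) < 2:
        raise EmptyInputError("alignment and grouping need at least two runs")
    space = default_align_space() if space is None else space
    if space.k == 0:
        raise ValidationError(
            "align/group optimization needs at least one optimized parameter: "
            "the per-round RGTV normalization requires two or more experiments"
        )
    center_id = select_center_run(runset, peaklists)
    evaluator = _AlignEvaluator(runset, peaklists, center_id)

    rounds: list[DoEResult] = []
    best_pair = (-np.inf, -np.inf)  # (GS, RCS) lexicographic
    best_settings = space.decode(np.zeros(space.k))
    best_raw = None
    stop_reason = "max_rounds"
    for rnd in range(max_rounds):
        result = run_doe_round(space, evaluator, score_transform=_rgtv_transform, n_workers=n_workers)
        rounds.append(result)
        if rnd == 0 and all(r is None or r.n_groups == 0 for r in result.raw_results):
            raise EmptyInputError("no feature groups formed in any experiment of the first round")
        # RGTV ranks the round; ties (common after the inf-RCS sentinel mapping)
        # fall back on the underlying (GS, RCS) pair
        valid = [j for j, r in enumerate(result.raw_results) if r is not None]
        i = max(valid, key=lambda j: (result.scores[j], result.raw_results[j].gs,
                                      result.raw_results[j].rcs, -j))
        rep = result.raw_results[i]
        pair = (rep.gs, rep.rcs)
        logger.info(
            "align/group round %d: best RGTV %.3f (GS %.4g, RCS %.4g) at %s",
            rnd + 1, result.scores[i], rep.gs, rep.rcs, result.design.settings[i],
        )
        if pair > best_pair:
            best_pair = pair
            best_settings = dict(result.design.settings[i])
            best_raw = rep
        else:
            stop_reason = "no_improvement"
            break
        if result.focus.next_space is None:
            stop_reason = "range_infeasible"
            break
        space = result.focus.next_space
    return OptimizationResult(
        rounds=rounds,
        best_settings=best_settings,
        best_score=float(best_pair[0]),
        stop_reason=stop_reason,
        best_raw=best_raw,
    )


def _space_from_dict(data: dict, default: ParameterSpace) -> ParameterSpace:
    """Build a parameter space from a config mapping, starting from the
    package default: ``optimized`` entries replace ranges (a two-element
    list) or, when given a scalar, move the parameter to ``fixed``."""
    optimized = dict(default.optimized)
    fixed = dict(default.fixed)
    for name, value in (data.get("optimized") or {}).items():
        if isinstance(value, (list, tuple)):
            optimized[name] = (float(value[0]), float(value[1]))
            fixed.pop(name, None)
        else:
            fixed[name] = float(value)
            optimized.pop(name, None)
    for name, value in (data.get("fixed") or {}).items():
        fixed[name] = float(value)
        optimized.pop(name, None)
    return ParameterSpace(
        optimized=optimized,
        fixed=fixed,
        constraints=[tuple(c) for c in data.get("constraints", default.constraints)],
        floors={**default.floors, **(data.get("floors") or {})},
    )


@dataclass
class OptimizeConfig:
    """Configuration of a full two-stage optimization."""

    pick_space: ParameterSpace = field(default_factory=default_pick_space)
    align_space: ParameterSpace = field(default_factory=default_align_space)
    criteria: IsotopeCriteria = field(default_factory=IsotopeCriteria)
    max_rounds_pick: int = 10
    max_rounds_align: int = 10
    n_workers: int = 1

    @classmethod
    def from_yaml(cls, path) -> "OptimizeConfig":
        """Load a config file.  Recognized keys: ``pick``/``align`` mappings
        with ``optimized`` (name -> [low, high] range, or a scalar to fix),
        ``fixed``, ``constraints``, ``floors``; ``criteria`` keyword
        arguments; ``max_rounds_pick``/``max_rounds_align``; ``n_workers``."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            pick_space=_space_from_dict(data.get("pick") or {}, default_pick_space()),
            align_space=_space_from_dict(data.get("align") or {}, default_align_space()),
            criteria=IsotopeCriteria(**(data.get("criteria") or {})),
            max_rounds_pick=int(data.get("max_rounds_pick", 10)),
            max_rounds_align=int(data.get("max_rounds_align", 10)),
            n_workers=int(data.get("n_workers", 1)),
        )


def _score_align_at(runset, peaklists, settings) -> AlignScoreReport:
    center_id = select_center_run(runset, peaklists)
    return _AlignEvaluator(runset, peaklists, center_id)(settings)


def score_align_group(runset, peaklists, settings: Mapping[str, float]) -> AlignScoreReport:
    """Align, group and score one settings combination (no optimization)."""
    return _score_align_at(runset, peaklists, settings)


def run_full_optimization(runset: RunSet, config: OptimizeConfig | None = None) -> dict:
    """Both optimization stages end to end, plus a default-vs-optimized
    score table (PPS, RCS/ARTS, reliable and non-reliable group counts)."""
    config = config or OptimizeConfig()

    default_pick = config.pick_space.decode(np.zeros(config.pick_space.k))
    default_align = config.align_space.decode(np.zeros(config.align_space.k))

    default_peaklists: dict[str, list[Peak]] = {}
    default_pick_report = score_picking(
        runset, default_pick, config.criteria, peaklists_out=default_peaklists
    )

    if config.pick_space.k == 0:
        pick_result = OptimizationResult(
            rounds=[], best_settings=default_pick,
            best_score=default_pick_report.pps, stop_reason="nothing_to_optimize",
        )
    else:
        pick_result = optimize_peak_picking(
            runset, config.pick_space, config.criteria,
            max_rounds=config.max_rounds_pick, n_workers=config.n_workers,
        )

    best_peaklists: dict[str, list[Peak]] = {}
    best_pick_report = score_picking(
        runset, pick_result.best_settings, config.criteria, peaklists_out=best_peaklists
    )

    default_align_report = _score_align_at(runset, best_peaklists, default_align)
    if config.align_space.k == 0:
        align_result = OptimizationResult(
            rounds=[], best_settings=default_align,
            best_score=default_align_report.gs, stop_reason="nothing_to_optimize",
            best_raw=default_align_report,
        )
    else:
        align_result = optimize_align_group(
            runset, best_peaklists, config.align_space,
            max_rounds=config.max_rounds_align, n_workers=config.n_workers,
        )
    best_align_report: AlignScoreReport = align_result.best_raw

    return {
        "picking": {
            "optimization": pick_result.to_dict(),
            "default_settings": default_pick,
            "optimized_settings": pick_result.best_settings,
            "default": {
                "pps": default_pick_report.pps,
                "n_peaks": default_pick_report.n_peaks,
                "n_rp": default_pick_report.n_rp,
                "n_lip": default_pick_report.n_lip,
            },
            "optimized": {
                "pps": best_pick_report.pps,
                "n_peaks": best_pick_report.n_peaks,
                "n_rp": best_pick_report.n_rp,
                "n_lip": best_pick_report.n_lip,
            },
        },
        "align_group": {
            "optimization": align_result.to_dict(),
            "default_settings": default_align,
            "optimized_settings": align_result.best_settings,
            "default": {
                "arts": default_align_report.arts,
                "rcs": default_align_report.rcs,
                "gs": default_align_report.gs,
                "n_reliable": default_align_report.n_reliable,
                "n_nonreliable": default_align_report.n_nonreliable,
                "n_groups": default_align_report.n_groups,
            },
            "optimized": {
                "arts": best_align_report.arts,
                "rcs": best_align_report.rcs,
                "gs": best_align_report.gs,
                "n_reliable": best_align_report.n_reliable,
                "n_nonreliable": best_align_report.n_nonreliable,
                "n_groups": best_align_report.n_groups,
            },
        },
    }
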