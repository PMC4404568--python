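"""Design-of-experiments engine: three-level designs, second-order response
surfaces, maximum location, and the maximum-focusing range adjustment.

Each optimization round evaluates the score at the points of a Box-Behnken
design (three-level incomplete factorial; for one or two parameters a full
three-level design, keeping the "three evenly spaced values per parameter"
property), fits a full quadratic in coded units, locates its maximizer over
the [-1, 1]^k cube, and re-centers the parameter ranges on it: a maximum on
a range bound zooms out (+20% width), a maximum within 25% of the center
zooms in (-10% at each bound), otherwise the width is kept.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .model import InfeasibleRangeError, ParameterSpace, ValidationError

__all__ = [
    "Design",
    "ResponseSurface",
    "FocusResult",
    "DoEResult",
    "build_design",
    "fit_response_surface",
    "locate_maximum",
    "adjust_ranges",
    "run_doe_round",
]


@dataclass
class Design:
    """One DoE round's design: coded points in {-1, 0, +1}^k plus decoded
    real-valued settings (fixed parameters included)."""

    names: list[str]
    coded: np.ndarray
    settings: list[dict[str, float]]
    n_center: int = 1

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def n_rows(self) -> int:
        return int(self.coded.shape[0])


@dataclass
class ResponseSurface:
    """Full quadratic y = b0 + Σ bi·xi + Σ bij·xi·xj + Σ bii·xi² in coded units."""

    k: int
    coefficients: np.ndarray  # [intercept, linear (k), interactions (k(k-1)/2), quadratic (k)]
    r_squared: float
    rank: int

    def predict(self, points: np.ndarray) -> np.ndarray:
        X = _model_matrix(np.atleast_2d(np.asarray(points, float)))
        return X @ self.coefficients


@dataclass
class FocusResult:
    best_coded: np.ndarray
    best_decoded: dict[str, float]
    actions: dict[str, str]  # zoom_in | zoom_out | keep
    next_space: ParameterSpace | None  # None when adjustment was infeasible


@dataclass
class DoEResult:
    """Everything one DoE round produced, serializable for audit."""

    design: Design
    raw_results: list
    scores: list[float]
    surface: ResponseSurface | None
    focus: FocusResult | None
    errors: dict[int, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def best_row(self) -> int:
        s = np.asarray(self.scores, float)
        s = np.where(np.isnan(s), -np.inf, s)
        return int(np.argmax(s))

    def to_dict(self) -> dict:
        return {
            "names": self.design.names,
            "coded_matrix": self.design.coded.tolist(),
            "settings": self.design.settings,
            "scores": [None if (s is None or np.isnan(s)) else float(s) for s in self.scores],
            "coefficients": None if self.surface is None else self.surface.coefficients.tolist(),
            "r_squared": None if self.surface is None else self.surface.r_squared,
            "best_coded": None if self.focus is None else self.focus.best_coded.tolist(),
            "best_decoded": None if self.focus is None else self.focus.best_decoded,
            "actions": None if self.focus is None else self.focus.actions,
            "errors": self.errors,
            "warnings": self.warnings,
        }


def build_design(space: ParameterSpace) -> Design:
    """Three-level design over the space's current ranges.

    k ≥ 3: Box-Behnken — every pair of parameters at the four (±1, ±1)
    combinations with the rest at 0, plus one center point.  k = 2: full
    3-level factorial (9 points).  k = 1: three-level sweep.
    """
    k = space.k
    if k == 0:
        raise ValidationError("parameter space has no optimized parameters")
    rows: list[np.ndarray] = []
    if k == 1:
        rows = [np.array([-1.0]), np.array([0.0]), np.array([1.0])]
    elif k == 2:
        rows = [np.array([a, b], float) for a in (-1, 0, 1) for b in (-1, 0, 1)]
    else:
        for i, j in itertools.combinations(range(k), 2):
            for si, sj in itertools.product((-1.0, 1.0), repeat=2):
                row = np.zeros(k)
                row[i], row[j] = si, sj
                rows.append(row)
        rows.append(np.zeros(k))
    coded = np.array(rows)
    # drop duplicate center rows from the factorial cases, keep exactly one
    settings = [space.decode(row) for row in coded]
    return Design(names=space.names, coded=coded, settings=settings, n_center=1)


def _model_matrix(coded: np.ndarray) -> np.ndarray:
    n, k = coded.shape
    cols = [np.ones(n)]
    cols.extend(coded[:, i] for i in range(k))
    cols.extend(coded[:, i] * coded[:, j] for i, j in itertools.combinations(range(k), 2))
    cols.extend(coded[:, i] ** 2 for i in range(k))
    return np.column_stack(cols)


def n_coefficients(k: int) -> int:
    return 1 + 2 * k + k * (k - 1) // 2


def fit_response_surface(design: Design, scores: Sequence[float]) -> ResponseSurface:
    """Least-squares fit of the full quadratic to the per-row scores.

    NaN scores are rejected (the caller excludes failed rows *before*
    fitting); a rank-deficient system falls back to the minimum-norm
    solution with a warning.
    """
    y = np.asarray(scores, dtype=float)
    if y.shape[0] != design.n_rows:
        raise ValidationError(f"got {y.shape[0]} scores for {design.n_rows} design rows")
    bad = np.where(np.isnan(y))[0]
    if bad.size:
        raise ValidationError(f"score is NaN for experiment row(s) {bad.tolist()}")
    X = _model_matrix(design.coded)
    ncoef = X.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < ncoef:
        warnings.warn(
            f"response surface is rank deficient (rank {rank} < {ncoef}); "
            "minimum-norm fit used",
            stacklevel=2,
        )
    resid = y - X @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ResponseSurface(k=design.k, coefficients=beta, r_squared=r2, rank=int(rank))


def _grid_step(k: int) -> float:
    if k <= 3:
        return 0.01
    if k == 4:
        return 0.05
    return 0.2


def locate_maximum(surface: ResponseSurface, k: int | None = None) -> np.ndarray:
    """Deterministic maximizer of the fitted quadratic over [-1, 1]^k.

    Dense grid search (step 0.01 for k ≤ 3, coarser for higher k) refined by
    bounded local ascent.  Ties prefer the exact center if tied, else the
    lexicographically smallest grid point.
    """
    k = surface.k if k is None else k
    step = _grid_step(k)
    axis = np.linspace(-1.0, 1.0, int(round(2.0 / step)) + 1)
    grids = np.meshgrid(*([axis] * k), indexing="ij")
    pts = np.column_stack([g.ravel() for g in grids])
    # chunked evaluation keeps the model matrix small for fine grids
    vals = np.empty(pts.shape[0])
    chunk = 262144
    for i in range(0, pts.shape[0], chunk):
        vals[i : i + chunk] = surface.predict(pts[i : i + chunk])
    vmax = vals.max()
    tol = 1e-9 * max(1.0, abs(vmax))
    tied = np.where(vals >= vmax - tol)[0]
    center_idx = None
    for idx in tied:
        if np.all(pts[idx] == 0.0):
            center_idx = idx
            break
    start = pts[center_idx if center_idx is not None else tied[0]]

    res = minimize(
        lambda x: -surface.predict(x[None, :])[0],
        start,
        method="L-BFGS-B",
        bounds=[(-1.0, 1.0)] * k,
    )
    if res.success and -res.fun > vmax + tol:
        return np.clip(res.x, -1.0, 1.0)
    return start.copy()


def adjust_ranges(
    space: ParameterSpace, best_decoded: dict[str, float], best_coded: np.ndarray
) -> tuple[ParameterSpace, dict[str, str]]:
    """Maximum-focusing range update: re-center every range on the located
    maximum; widen by 20% where the maximum sat on a bound, shrink by 10% at
    each bound where it sat within 25% of the center, keep the width
    otherwise.  Floors are enforced by clamping the lower bound."""
    new_opt: dict[str, tuple[float, float]] = {}
    actions: dict[str, str] = {}
    for name, x in zip(space.names, best_coded):
        lo, hi = space.optimized[name]
        width = hi - lo
        center = best_decoded[name]
        if abs(x) >= 1.0 - 1e-9:
            width *= 1.2
            actions[name] = "zoom_out"
        elif abs(x) < 0.25:
            width *= 0.8
            actions[name] = "zoom_in"
        else:
            actions[name] = "keep"
        new_lo, new_hi = center - width / 2.0, center + width / 2.0
        floor = space.floors.get(name)
        if floor is not None and new_lo < floor:
            new_lo = floor
        if new_hi <= new_lo:
            raise InfeasibleRangeError(
                f"parameter {name!r}: adjusted range [{new_lo}, {new_hi}] collapsed at its "
                f"floor; raise the range or lower the floor"
            )
        new_opt[name] = (new_lo, new_hi)

    def value_of(n: str) -> float:
        if n in new_opt:
            return 0.5 * (new_opt[n][0] + new_opt[n][1])
        return space.fixed[n]

    for a, b in space.constraints:
        if value_of(a) >= value_of(b):
            raise InfeasibleRangeError(
                f"ordering constraint {a!r} < {b!r} violated after range adjustment "
                f"({value_of(a)} >= {value_of(b)}); widen the ranges apart or fix one parameter"
            )
    return (
        ParameterSpace(
            optimized=new_opt,
            fixed=dict(space.fixed),
            constraints=list(space.constraints),
            floors=dict(space.floors),
        ),
        actions,
    )


def run_doe_round(
    space: ParameterSpace,
    evaluate: Callable[[dict[str, float]], float],
    score_transform: Callable[[list], list[float]] | None = None,
    n_workers: int = 1,
) -> DoEResult:
    """Evaluate one full design round and produce the next parameter space.

    ``evaluate`` must be a pure function of the settings; rows whose
    evaluator raises are excluded from the fit (with a warning) as long as
    at least as many rows as surface coefficients remain.
    ``score_transform`` may map the list of raw per-row results (``None``
    for failed rows) to scalar scores — used for per-round normalized
    targets; by default raw results are used as scores directly.
    """
    design = build_design(space)
    raw: list = [None] * design.n_rows
    errors: dict[int, str] = {}

    def _run_one(idx: int):
        try:
            return idx, evaluate(design.settings[idx]), None
        except Exception as exc:  # noqa: BLE001 - captured per row by contract
            return idx, None, f"{type(exc).__name__}: {exc}"

    if n_workers > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(_run_one, range(design.n_rows)))
    else:
        results = [_run_one(i) for i in range(design.n_rows)]
    for idx, value, err in results:
        raw[idx] = value
        if err is not None:
            errors[idx] = err

    if score_transform is not None:
        scores = list(score_transform(raw))
    else:
        scores = [np.nan if r is None else float(r) for r in raw]

    warn_msgs = [f"experiment {i} failed: {msg}" for i, msg in errors.items()]
    valid = [i for i in range(design.n_rows) if not np.isnan(scores[i])]
    ncoef = n_coefficients(design.k)
    if len(valid) < ncoef:
        raise ValidationError(
            f"only {len(valid)} experiments succeeded; need at least {ncoef} "
            f"to fit the response surface"
        )

    if len(valid) < design.n_rows:
        sub = Design(
            names=design.names,
            coded=design.coded[valid],
            settings=[design.settings[i] for i in valid],
            n_center=design.n_center,
        )
        surface = fit_response_surface(sub, [scores[i] for i in valid])
    else:
        surface = fit_response_surface(design, scores)

    best_coded = locate_maximum(surface)
    best_decoded = space.decode(best_coded)
    try:
        next_space, actions = adjust_ranges(space, best_decoded, best_coded)
    except InfeasibleRangeError as exc:
        next_space, actions = None, {}
        warn_msgs.append(f"range adjustment infeasible: {exc}")
    focus = FocusResult(
        best_coded=best_coded,
        best_decoded=best_decoded,
        actions=actions,
        next_space=next_space,
    )
    return DoEResult(
        design=design,
        raw_results=raw,
        scores=scores,
        surface=surface,
        focus=focus,
        errors=errors,
        warnings=warn_msgs,
    )
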