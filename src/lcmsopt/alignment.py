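"""Retention-time alignment and density-based feature grouping.

Alignment follows the profile-similarity idea: each run is binned into an
m/z × scan intensity matrix ("profile"), per-scan-pair similarity is the
Pearson correlation of the binned columns, and a global dynamic program
with affine gap costs (gapInit to open, gapExtend to extend) finds the
monotone path of maximal summed similarity.  The path yields a monotone
warp from the run's scan times onto the reference run's times, applied to
peak RTs by linear interpolation (clamped at the ends).

Grouping mirrors the kernel-density method: peaks are sliced by m/z
(width mzwid, 50% overlap), a Gaussian density over RT with bandwidth bw is
scanned for maxima, and each density maximum collects the peaks under it.
Groups must contain peaks from at least minfrac × n_runs distinct runs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import FeatureGroup, Peak, Run, ValidationError

__all__ = [
    "AlignParams",
    "GroupParams",
    "ProfileMatrix",
    "profile_matrix",
    "make_profiles",
    "RtWarp",
    "similarity_matrix",
    "align_run",
    "apply_warp",
    "group_density",
]

_NEG = -1e30


@dataclass(frozen=True)
class AlignParams:
    profStep: float = 1.0
    gapInit: float = 0.3
    gapExtend: float = 2.4

    def validate(self) -> None:
        if not self.profStep > 0:
            raise ValidationError(f"profStep must be > 0 (got {self.profStep})")
        if self.gapInit < 0 or self.gapExtend < 0:
            raise ValidationError("gap penalties must be nonnegative")


@dataclass(frozen=True)
class GroupParams:
    bw: float = 5.0
    mzwid: float = 0.025
    minfrac: float = 0.5

    def validate(self) -> None:
        if not self.bw > 0 or not self.mzwid > 0:
            raise ValidationError("bw and mzwid must be > 0")
        if not (0.0 < self.minfrac <= 1.0):
            raise ValidationError(f"minfrac must be in (0, 1] (got {self.minfrac})")


@dataclass
class ProfileMatrix:
    """Binned intensity matrix: rows are m/z bins of width profStep starting
    at ``mz_min``, columns are scans at ``times``."""

    matrix: np.ndarray
    mz_min: float
    prof_step: float
    times: np.ndarray

    def compatible(self, other: "ProfileMatrix") -> bool:
        return (
            self.prof_step == other.prof_step
            and self.mz_min == other.mz_min
            and self.matrix.shape[0] == other.matrix.shape[0]
        )


def profile_matrix(
    run: Run, prof_step: float, mz_min: float | None = None, n_bins: int | None = None
) -> ProfileMatrix:
    """Bin a run's centroids into an m/z × scan intensity matrix.

    Bin b covers [mz_min + b·profStep, mz_min + (b+1)·profStep); intensities
    are summed per bin per scan, so total intensity is conserved.
    """
    if prof_step <= 0:
        raise ValidationError(f"profStep must be > 0 (got {prof_step})")
    all_mz = [s.mz_values for s in run.scans if s.mz_values.size]
    lo = min((float(a[0]) for a in all_mz), default=0.0)
    hi = max((float(a[-1]) for a in all_mz), default=0.0)
    if mz_min is None:
        mz_min = math.floor(lo / prof_step) * prof_step
    if n_bins is None:
        n_bins = max(1, int(math.floor((hi - mz_min) / prof_step)) + 1)
    mat = np.zeros((n_bins, run.n_scans))
    for j, scan in enumerate(run.scans):
        if not scan.mz_values.size:
            continue
        bins = np.floor((scan.mz_values - mz_min) / prof_step).astype(int)
        ok = (bins >= 0) & (bins < n_bins)
        np.add.at(mat[:, j], bins[ok], scan.intensities[ok])
    return ProfileMatrix(matrix=mat, mz_min=mz_min, prof_step=prof_step, times=run.scan_times)


def make_profiles(runs, prof_step: float) -> list[ProfileMatrix]:
    """Profile matrices for several runs on one shared m/z bin grid."""
    lo = math.inf
    hi = -math.inf
    for run in runs:
        for s in run.scans:
            if s.mz_values.size:
                lo = min(lo, float(s.mz_values[0]))
                hi = max(hi, float(s.mz_values[-1]))
    if not math.isfinite(lo):
        lo, hi = 0.0, prof_step
    mz_min = math.floor(lo / prof_step) * prof_step
    n_bins = max(1, int(math.floor((hi - mz_min) / prof_step)) + 1)
    return [profile_matrix(r, prof_step, mz_min=mz_min, n_bins=n_bins) for r in runs]


@dataclass
class RtWarp:
    """Monotone mapping from a run's native RT axis onto the reference axis,
    defined by matched scan-time pairs and linear interpolation between them
    (clamped beyond the first/last match)."""

    src_times: np.ndarray
    dst_times: np.ndarray

    def __call__(self, rt):
        return np.interp(rt, self.src_times, self.dst_times)

    @classmethod
    def identity(cls, times: np.ndarray) -> "RtWarp":
        return cls(src_times=np.asarray(times, float), dst_times=np.asarray(times, float))


def similarity_matrix(run_profile: ProfileMatrix, center_profile: ProfileMatrix) -> np.ndarray:
    """Pearson correlation between every pair of binned scan columns.

    Columns are z-normalized; pairs involving a zero-variance column get
    similarity 0.
    """
    if not run_profile.compatible(center_profile):
        raise ValidationError("profile matrices are on different m/z bin grids")

    def znorm(mat: np.ndarray) -> np.ndarray:
        mu = mat.mean(axis=0, keepdims=True)
        sd = mat.std(axis=0, keepdims=True)
        out = np.where(sd > 0, (mat - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        return out

    a = znorm(run_profile.matrix)
    b = znorm(center_profile.matrix)
    nbins = a.shape[0]
    return (a.T @ b) / nbins


def _affine_dp(S: np.ndarray, gap_init: float, gap_extend: float):
    """Global monotone path through S with affine gap penalties; returns the
    three DP matrices (match / vertical gap / horizontal gap)."""
    n1, n2 = S.shape
    M = np.full((n1 + 1, n2 + 1), _NEG)
    X = np.full((n1 + 1, n2 + 1), _NEG)  # gap consuming run scans (rows)
    Y = np.full((n1 + 1, n2 + 1), _NEG)  # gap consuming center scans (cols)
    M[0, 0] = 0.0
    # initial gaps along the edges
    for j in range(1, n2 + 1):
        Y[0, j] = -gap_init - (j - 1) * gap_extend
    for i in range(1, n1 + 1):
        X[i, 0] = -gap_init - (i - 1) * gap_extend

    js = np.arange(n2 + 1)
    for i in range(1, n1 + 1):
        X[i, 1:] = np.maximum(M[i - 1, 1:] - gap_init, X[i - 1, 1:] - gap_extend)
        prev = np.maximum(M[i - 1, :-1], np.maximum(X[i - 1, :-1], Y[i - 1, :-1]))
        M[i, 1:] = S[i - 1] + prev
        # Y[i,j] = max_{l<=j-1} P[i,l] - gapInit - (j-1-l)*gapExtend, via running max
        P = np.maximum(M[i], X[i])
        run_max = np.maximum.accumulate(P + js * gap_extend)
        Y[i, 1:] = run_max[:-1] - gap_init - (js[1:] - 1) * gap_extend
    return M, X, Y


def _traceback(S, M, X, Y, gap_init, gap_extend):
    """Recover the matched (run scan, center scan) pairs of the optimal path."""
    n1, n2 = S.shape
    i, j = n1, n2
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    pairs: list[tuple[int, int]] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == 0:  # match at (i, j)
            pairs.append((i - 1, j - 1))
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:  # vertical gap
            if i == 0:
                state = 2
                continue
            from_open = M[i - 1, j] - gap_init
            if abs(X[i, j] - from_open) <= tol:
                state = 0
            i -= 1
        else:  # horizontal gap
            if j == 0:
                state = 1
                continue
            p_m, p_x = M[i, j - 1], X[i, j - 1]
            from_open = max(p_m, p_x) - gap_init
            if abs(Y[i, j] - from_open) <= tol:
                state = 0 if p_m >= p_x else 1
            j -= 1
    pairs.reverse()
    return pairs


def align_run(
    run_profile: ProfileMatrix,
    center_profile: ProfileMatrix,
    params: AlignParams,
    similarity: np.ndarray | None = None,
) -> RtWarp:
    """Compute the monotone RT warp mapping a run onto the center run.

    ``similarity`` may be passed in to reuse a precomputed matrix (it only
    depends on profStep, not on the gap penalties).
    """
    params.validate()
    S = similarity if similarity is not None else similarity_matrix(run_profile, center_profile)
    M, X, Y = _affine_dp(S, params.gapInit, params.gapExtend)
    pairs = _traceback(S, M, X, Y, params.gapInit, params.gapExtend)
    if not pairs:
        return RtWarp.identity(run_profile.times)
    src = np.array([run_profile.times[i] for i, _ in pairs])
    dst = np.array([center_profile.times[j] for _, j in pairs])
    # enforce strict monotonicity of the interpolation knots
    keep = np.concatenate([[True], np.diff(src) > 0])
    return RtWarp(src_times=src[keep], dst_times=np.maximum.accumulate(dst[keep]))


def apply_warp(peaks, warp: RtWarp) -> list[Peak]:
    """Rewrite peak rt/rtmin/rtmax through the warp."""
    out = []
    for p in peaks:
        rt, rtmin, rtmax = (float(warp(v)) for v in (p.rt, p.rtmin, p.rtmax))
        rtmin, rtmax = min(rtmin, rt), max(rtmax, rt)
        out.append(
            Peak(
                run_id=p.run_id,
                mz=p.mz,
                mzmin=p.mzmin,
                mzmax=p.mzmax,
                rt=rt,
                rtmin=rtmin,
                rtmax=rtmax,
                intensity=p.intensity,
            )
        )
    return out


def _density_regions(rts: np.ndarray, bw: float):
    """Gaussian kernel density over RT; yields (lo, hi) RT intervals, one per
    density maximum, bounded by the surrounding minima."""
    lo_t, hi_t = rts.min() - 3 * bw, rts.max() + 3 * bw
    step = bw / 4.0
    n = min(4096, max(64, int((hi_t - lo_t) / step) + 1))
    grid = np.linspace(lo_t, hi_t, n)
    dens = np.exp(-0.5 * ((grid[:, None] - rts[None, :]) / bw) ** 2).sum(axis=1)
    # local maxima, plateau-aware (a flat top counts once, at its middle)
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and dens[j + 1] == dens[i]:
            j += 1
        left = dens[i - 1] if i > 0 else -np.inf
        right = dens[j + 1] if j + 1 < n else -np.inf
        if dens[i] > left and dens[i] > right:
            maxima.append((i + j) // 2)
        i = j + 1
    if not maxima:
        return []
    # watershed: regions split at the minima between consecutive maxima
    bounds = [grid[0]]
    for a, b in zip(maxima, maxima[1:]):
        k = a + int(np.argmin(dens[a : b + 1]))
        bounds.append(grid[k])
    bounds.append(grid[-1])
    return [(bounds[t], bounds[t + 1], dens[m]) for t, m in enumerate(maxima)]


def group_density(
    peaklists: dict[str, list[Peak]] | list[list[Peak]],
    params: GroupParams,
    n_runs: int | None = None,
) -> list[FeatureGroup]:
    """Group peaks across runs by m/z slice and RT kernel density.

    Deterministic and invariant to the order peaks are supplied in: peaks
    are canonically sorted, candidate groups are processed in descending
    peak-count order, and every peak joins at most one group.  Groups with
    fewer than ``minfrac × n_runs`` distinct runs are discarded.
    """
    params.validate()
    if isinstance(peaklists, dict):
        lists = list(peaklists.values())
    else:
        lists = list(peaklists)
    if n_runs is None:
        n_runs = len(lists)
    peaks = [p for lst in lists for p in lst]
    if not peaks:
        return []
    peaks.sort(key=lambda p: (p.mz, p.rt, p.run_id, -p.intensity))
    mz = np.array([p.mz for p in peaks])
    rt = np.array([p.rt for p in peaks])

    half = params.mzwid / 2.0
    mz_lo = float(mz.min())
    n_slices = int(math.floor((float(mz.max()) - mz_lo) / half)) + 1
    candidates = []  # (member index tuple, peak_count, mz_center, median_rt)
    seen = set()
    for s in range(n_slices):
        lo = mz_lo + s * half
        hi = lo + params.mzwid
        sel = np.where((mz >= lo) & (mz < hi))[0]
        if sel.size == 0:
            continue
        for r_lo, r_hi, _ in _density_regions(rt[sel], params.bw):
            members = tuple(int(i) for i in sel[(rt[sel] >= r_lo) & (rt[sel] <= r_hi)])
            if members and members not in seen:
                seen.add(members)
                candidates.append(members)

    candidates.sort(
        key=lambda m: (
            -len(m),
            float(np.median(mz[list(m)])),
            float(np.median(rt[list(m)])),
        )
    )
    assigned = np.zeros(len(peaks), dtype=bool)
    groups: list[FeatureGroup] = []
    for members in candidates:
        free = [i for i in members if not assigned[i]]
        if not free:
            continue
        assigned[free] = True
        groups.append(FeatureGroup(member_peaks=[peaks[i] for i in free]))

    kept = [g for g in groups if len(g.runs_represented) >= params.minfrac * n_runs - 1e-9]
    kept.sort(key=lambda g: (g.mz_center, g.median_rt))
    return kept
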