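"""Parameterized centWave-style peak picking.

Two stages, as in high-resolution LC-MS practice: (1) regions of interest
(ROIs) are built by chaining centroids across consecutive scans whose m/z
stays within a ppm tolerance of the ROI's running mean; (2) within each ROI
a continuous wavelet transform (Mexican-hat) over scales spanning the
configured peak-width range detects chromatographic peaks, whose measured
width must fall inside [min_peakwidth, max_peakwidth].

This is a simplified detector, not a port of any existing one: Gaussian-fit
refinement, m/z-dependent ROI extension and in-ROI baseline estimation are
omitted.  The contract is that the four public parameters (ppm,
min_peakwidth, max_peakwidth, mzdiff) steer detection in the documented
directions, which is what the optimizer exercises.
"""
from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .model import Peak, Run, ValidationError

__all__ = ["PickParams", "ROI", "find_rois", "detect_peaks_in_roi", "pick_peaks"]

#: FWHM of a Gaussian = 2·sqrt(2·ln 2) · sigma
_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))
#: scans an ROI may skip before it is closed
_MAX_SCAN_GAP = 2
_N_SCALES = 10


@dataclass(frozen=True)
class PickParams:
    """Peak-picking parameters; names match the common usage for
    high-resolution centroid data."""

    ppm: float = 25.0
    min_peakwidth: float = 20.0
    max_peakwidth: float = 50.0
    mzdiff: float = 0.005
    noise: float = 0.0
    prefilter_k: int = 3
    prefilter_I: float = 100.0

    def violations(self) -> list[str]:
        out = []
        if not self.ppm > 0:
            out.append(f"ppm must be > 0 (got {self.ppm})")
        if not self.min_peakwidth > 0:
            out.append(f"min_peakwidth must be > 0 (got {self.min_peakwidth})")
        if not self.min_peakwidth < self.max_peakwidth:
            out.append(
                f"min_peakwidth ({self.min_peakwidth}) must be < max_peakwidth ({self.max_peakwidth})"
            )
        if self.noise < 0:
            out.append(f"noise must be >= 0 (got {self.noise})")
        return out

    def validate(self) -> None:
        v = self.violations()
        if v:
            raise ValidationError("invalid peak-picking parameters: " + "; ".join(v))


@dataclass
class ROI:
    """A chain of centroids across consecutive scans within a ppm tolerance
    of the chain's running mean m/z."""

    scan_indices: list[int] = field(default_factory=list)
    mzs: list[float] = field(default_factory=list)
    intensities: list[float] = field(default_factory=list)
    mz_sum: float = 0.0

    @property
    def mean_mz(self) -> float:
        return self.mz_sum / len(self.mzs)

    @property
    def n(self) -> int:
        return len(self.mzs)

    def add(self, scan_idx: int, mz: float, intensity: float) -> None:
        self.scan_indices.append(scan_idx)
        self.mzs.append(mz)
        self.intensities.append(intensity)
        self.mz_sum += mz


def find_rois(run: Run, params: PickParams) -> list[ROI]:
    """Chain centroids into ROIs; drop ROIs failing the prefilter
    (fewer than ``prefilter_k`` members at or above ``prefilter_I``)."""
    active: list[ROI] = []
    done: list[ROI] = []

    for s, scan in enumerate(run.scans):
        # close ROIs that have not been extended recently
        still = []
        for roi in active:
            if s - roi.scan_indices[-1] > _MAX_SCAN_GAP:
                done.append(roi)
            else:
                still.append(roi)
        active = still
        means = [r.mean_mz for r in active]
        order = np.argsort(means, kind="stable")
        sorted_means = [means[i] for i in order]
        taken: set[int] = set()  # one centroid per ROI per scan
        new_rois: list[ROI] = []

        for mz, inten in zip(scan.mz_values, scan.intensities):
            tol = params.ppm * mz * 1e-6
            pos = bisect_left(sorted_means, mz)
            best = None
            best_d = tol
            for idx in (pos - 1, pos, pos + 1):
                if 0 <= idx < len(sorted_means):
                    j = int(order[idx])
                    if j in taken:
                        continue
                    d = abs(sorted_means[idx] - mz)
                    if d <= best_d:
                        best, best_d = j, d
            if best is not None:
                active[best].add(s, float(mz), float(inten))
                taken.add(best)
            else:
                roi = ROI()
                roi.add(s, float(mz), float(inten))
                new_rois.append(roi)
        active.extend(new_rois)

    done.extend(active)

    def keep(roi: ROI) -> bool:
        n_above = sum(1 for i in roi.intensities if i >= params.prefilter_I)
        return n_above >= params.prefilter_k

    kept = [r for r in done if keep(r)]
    kept.sort(key=lambda r: (r.scan_indices[0], r.mean_mz))
    return kept


def _ricker(points: int, a: float) -> np.ndarray:
    """Mexican-hat wavelet on ``points`` samples at scale ``a`` (in samples)."""
    x = np.arange(points) - (points - 1) / 2.0
    amp = 2.0 / (math.sqrt(3.0 * a) * math.pi**0.25)
    xsq = (x / a) ** 2
    return amp * (1.0 - xsq) * np.exp(-xsq / 2.0)


def _half_max_width(trace: np.ndarray, apex: int, left: int, right: int, dt: float) -> float:
    """FWHM estimate by linear interpolation of the half-maximum crossings
    inside [left, right]; falls back to the boundary width where the trace
    never descends to half maximum."""
    half = trace[apex] / 2.0
    lo_t = float(left)
    for i in range(apex, left, -1):
        if trace[i - 1] <= half:
            frac = (trace[i] - half) / (trace[i] - trace[i - 1])
            lo_t = i - frac
            break
    hi_t = float(right)
    for i in range(apex, right):
        if trace[i + 1] <= half:
            frac = (trace[i] - half) / (trace[i] - trace[i + 1])
            hi_t = i + frac
            break
    return (hi_t - lo_t) * dt


def detect_peaks_in_roi(roi: ROI, run: Run, params: PickParams) -> list[Peak]:
    """Detect chromatographic peaks in one ROI via a Mexican-hat CWT.

    Scales span [min_peakwidth, max_peakwidth]; CWT maxima above the noise
    floor become candidate apexes, boundaries descend from the apex to the
    surrounding minima, and peaks whose measured width falls outside the
    configured peak-width window are rejected.
    """
    times = run.scan_times
    dt = float(np.median(np.diff(times))) if times.size > 1 else 1.0
    first, last = roi.scan_indices[0], roi.scan_indices[-1]
    length = last - first + 1
    if length < 3:
        return []

    trace = np.zeros(length)
    mz_at = np.full(length, np.nan)
    for s, mz, inten in zip(roi.scan_indices, roi.mzs, roi.intensities):
        i = s - first
        if inten > trace[i]:
            mz_at[i] = mz
        trace[i] = max(trace[i], inten)

    # scales in scan units covering the requested peak-width range
    sigmas = (
        np.geomspace(params.min_peakwidth, params.max_peakwidth, _N_SCALES)
        / _FWHM_TO_SIGMA
        / dt
    )
    cwt = np.empty((_N_SCALES, length))
    for k, a in enumerate(sigmas):
        a = max(a, 0.5)
        wav = _ricker(min(length, int(10 * a) + 1), a)
        cwt[k] = np.convolve(trace, wav, mode="same")
    best = cwt.max(axis=0)

    # candidate apexes: local maxima of the raw trace confirmed by the CWT
    peaks: list[Peak] = []
    for i in range(length):
        if trace[i] < max(params.noise, 1e-12):
            continue
        if i > 0 and trace[i] <= trace[i - 1]:
            continue
        if i < length - 1 and trace[i] < trace[i + 1]:
            continue
        if best[i] <= 0:
            continue
        # descend to boundaries
        left = i
        while left > 0 and trace[left - 1] < trace[left] and trace[left - 1] > 0:
            left -= 1
        right = i
        while right < length - 1 and trace[right + 1] < trace[right] and trace[right + 1] > 0:
            right += 1
        width = _half_max_width(trace, i, left, right, dt)
        if width < params.min_peakwidth or width > params.max_peakwidth:
            continue
        sel = slice(left, right + 1)
        mzs = mz_at[sel]
        ints = trace[sel]
        ok = ~np.isnan(mzs)
        if not ok.any():
            continue
        w = ints[ok]
        m = mzs[ok]
        mz_apex = float(np.average(m, weights=w)) if w.sum() > 0 else float(m.mean())
        peaks.append(
            Peak(
                run_id=run.run_id,
                mz=mz_apex,
                mzmin=float(m.min()),
                mzmax=float(m.max()),
                rt=float(times[first + i]),
                rtmin=float(times[first + left]),
                rtmax=float(times[first + right]),
                intensity=float(trace[i]),
            )
        )
    return peaks


def _merge_mzdiff(peaks: list[Peak], mzdiff: float) -> list[Peak]:
    """Keep the more intense of any two peaks with overlapping RT extents
    closer than ``mzdiff`` in m/z (the documented mzdiff semantics)."""
    if mzdiff <= 0 or len(peaks) < 2:
        return peaks
    order = sorted(range(len(peaks)), key=lambda i: (-peaks[i].intensity, peaks[i].mz, peaks[i].rt))
    kept: list[Peak] = []
    for i in order:
        p = peaks[i]
        clash = any(
            abs(p.mz - q.mz) < mzdiff and p.rtmin <= q.rtmax and p.rtmax >= q.rtmin
            for q in kept
        )
        if not clash:
            kept.append(p)
    kept.sort(key=lambda p: (p.mz, p.rt))
    return kept


def pick_peaks(run: Run, params: PickParams) -> list[Peak]:
    """Full peak picking on one run: ROIs, per-ROI CWT detection, mzdiff merge.

    Deterministic: identical input and parameters give the identical list.
    """
    params.validate()
    peaks: list[Peak] = []
    for roi in find_rois(run, params):
        peaks.extend(detect_peaks_in_roi(roi, run, params))
    peaks = _merge_mzdiff(peaks, params.mzdiff)
    peaks.sort(key=lambda p: (p.mz, p.rt))
    return peaks
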