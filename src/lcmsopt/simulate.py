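"""Synthetic multi-injection pooled-sample LC-HRMS data with ground truth.

Each simulated compound elutes as a Gaussian of known FWHM and produces two
ion traces: the ¹²C parent and the M+1 ¹³C isotopologue at +1.0033548 Da
with relative apex intensity n_carbons × IA (first-order binomial; M+2 is
negligible at these carbon counts).  Injections share the compound list but
get an injection-specific smooth RT drift (linear + one sinusoid), so the
aligner has real work to do.  Centroid m/z values carry ppm-scale jitter
and random noise sticks can be sprinkled per scan.

The generator keeps distinct compounds' traces separated in m/z (rejection
sampling) so the ground truth stays unambiguous — one detectable trace maps
to one expected feature group.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .model import CentroidScan, Run, RunSet, ValidationError
from .scoring import C13_C12_DELTA, NATURAL_13C_ABUNDANCE, max_carbons

__all__ = ["SyntheticConfig", "GroundTruth", "generate_runset", "truth_feature_count",
           "default_carbon_model"]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def default_carbon_model(mz: float) -> int:
    """Hydrocarbon-like heuristic: ~0.7 of the mass is carbon backbone,
    clamped to the physically possible [1, maxC(mz)]."""
    n = int(round(mz * 0.7 / 14.0))
    return max(1, min(n, max(1, max_carbons(mz))))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated pooled-sample run set."""

    n_compounds: int = 30
    mz_range: tuple[float, float] = (100.0, 600.0)
    rt_range: tuple[float, float] = (0.0, 600.0)
    fwhm_range: tuple[float, float] = (18.0, 22.0)
    log10_intensity_range: tuple[float, float] = (4.5, 6.0)
    carbon_model: Callable[[float], int] = default_carbon_model
    isotope_abundance: float = NATURAL_13C_ABUNDANCE
    scan_interval: float = 1.0
    mz_jitter_ppm: float = 3.0
    noise_peak_rate: float = 2.0
    n_injections: int = 4
    rt_drift_amplitude: float = 30.0
    dropout_prob: float = 0.0
    seed: int = 0
    #: minimum m/z spacing enforced between any two ion traces of different
    #: compounds, keeping truth-to-feature mapping unambiguous
    min_trace_mz_gap: float = 0.2
    #: centroids below this intensity are not written to scans
    emission_floor: float = 50.0

    def validate(self) -> None:
        for name in ("mz_range", "rt_range", "fwhm_range", "log10_intensity_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name}: empty range ({lo}, {hi})")
        if not (0.0 <= self.isotope_abundance < 1.0):
            raise ValidationError("isotope_abundance must be in [0, 1)")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ValidationError("dropout_prob must be in [0, 1)")
        if self.n_injections < 1 or self.scan_interval <= 0:
            raise ValidationError("need n_injections >= 1 and scan_interval > 0")


@dataclass
class GroundTruth:
    """Per-trace truth table: one row per (compound, injection, trace).

    ``trace`` is "M0" (¹²C parent) or "M1" (¹³C isotopologue); ``rt_true``
    is the drifted apex time in that injection; ``apex_intensity`` the
    emitted apex height; ``dropout`` marks traces withheld from the data.
    Invariant: the M1 apex equals n_carbons × IA × the M0 apex.
    """

    traces: pd.DataFrame
    compounds: pd.DataFrame
    config: SyntheticConfig


def _drift_function(rng: np.random.Generator, cfg: SyntheticConfig):
    """Smooth per-injection RT warp: linear + one sinusoid, bounded by the
    configured amplitude."""
    t0, t1 = cfg.rt_range
    span = t1 - t0
    a = rng.uniform(-0.5, 0.5) * cfg.rt_drift_amplitude
    b = rng.uniform(-0.5, 0.5) * cfg.rt_drift_amplitude
    phase = rng.uniform(0.0, 2.0 * math.pi)

    def drift(t: np.ndarray | float):
        u = (np.asarray(t) - t0) / span
        return a * (2.0 * u - 1.0) + b * np.sin(2.0 * math.pi * u + phase)

    return drift


def _draw_compound_mzs(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    """Rejection-sample parent m/z values so every pair of traces (parents and
    their +1.0033548 partners) stays at least ``min_trace_mz_gap`` apart."""
    taken: list[float] = []
    mzs: list[float] = []
    attempts = 0
    lo, hi = cfg.mz_range
    while len(mzs) < cfg.n_compounds:
        attempts += 1
        if attempts > 10000 * max(1, cfg.n_compounds):
            raise ValidationError(
                "cannot place compounds with the requested m/z separation; "
                "widen mz_range or lower min_trace_mz_gap/n_compounds"
            )
        mz = rng.uniform(lo, hi)
        cand = (mz, mz + C13_C12_DELTA)
        if all(abs(c - t) >= cfg.min_trace_mz_gap for c in cand for t in taken):
            mzs.append(mz)
            taken.extend(cand)
    return np.array(mzs)


def generate_runset(config: SyntheticConfig) -> tuple[RunSet, GroundTruth]:
    """Generate a deterministic run set plus its ground truth.

    Deterministic given ``config.seed``: the same config yields bit-identical
    scans and truth tables.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    mzs = _draw_compound_mzs(rng, cfg)
    # keep apexes away from the run edges so full elution profiles fit
    margin = 4.0 * cfg.fwhm_range[1] + cfg.rt_drift_amplitude
    t0, t1 = cfg.rt_range
    if t1 - t0 <= 2 * margin:
        raise ValidationError("rt_range too short for the configured peak widths and drift")
    rts = rng.uniform(t0 + margin, t1 - margin, size=cfg.n_compounds)
    fwhms = rng.uniform(*cfg.fwhm_range, size=cfg.n_compounds)
    apex = 10.0 ** rng.uniform(*cfg.log10_intensity_range, size=cfg.n_compounds)
    n_carbons = np.array([cfg.carbon_model(m) for m in mzs], dtype=int)
    for mz, nc in zip(mzs, n_carbons):
        mc = max_carbons(mz)
        if nc > mc:
            raise ValidationError(
                f"carbon model assigns {nc} carbons at m/z {mz:.4f}, above the "
                f"hydrocarbon-chain maximum maxC={mc}"
            )

    comp = pd.DataFrame(
        {
            "compound": np.arange(cfg.n_compounds),
            "mz": mzs,
            "rt_nominal": rts,
            "fwhm": fwhms,
            "apex_intensity": apex,
            "n_carbons": n_carbons,
        }
    )

    drifts = [_drift_function(rng, cfg) for _ in range(cfg.n_injections)]
    dropout = rng.random((cfg.n_injections, cfg.n_compounds, 2)) < cfg.dropout_prob

    scan_times = np.arange(t0, t1 + 0.5 * cfg.scan_interval, cfg.scan_interval)
    sigma = fwhms / _FWHM_TO_SIGMA
    iso_apex = n_carbons * cfg.isotope_abundance * apex

    runs: list[Run] = []
    truth_rows: list[dict] = []
    for j in range(cfg.n_injections):
        rt_true = rts + drifts[j](rts)
        trace_defs = []  # (mz, apex, rt_true, sigma, compound, which)
        for c in range(cfg.n_compounds):
            for which, trace_mz, trace_apex in (
                ("M0", mzs[c], apex[c]),
                ("M1", mzs[c] + C13_C12_DELTA, iso_apex[c]),
            ):
                dropped = bool(dropout[j, c, 0 if which == "M0" else 1])
                truth_rows.append(
                    {
                        "compound": c,
                        "injection": j,
                        "trace": which,
                        "mz": trace_mz,
                        "n_carbons": int(n_carbons[c]),
                        "rt_nominal": rts[c],
                        "rt_true": rt_true[c],
                        "fwhm": fwhms[c],
                        "apex_intensity": trace_apex,
                        "dropout": dropped,
                    }
                )
                if not dropped:
                    trace_defs.append((trace_mz, trace_apex, rt_true[c], sigma[c]))

        scans = []
        for t in scan_times:
            stick_mz = []
            stick_int = []
            for mz_tr, apex_tr, rt_tr, sig in trace_defs:
                inten = apex_tr * math.exp(-0.5 * ((t - rt_tr) / sig) ** 2)
                if inten >= cfg.emission_floor:
                    jitter = rng.normal(0.0, cfg.mz_jitter_ppm) * mz_tr * 1e-6
                    stick_mz.append(mz_tr + jitter)
                    stick_int.append(inten)
            n_noise = rng.poisson(cfg.noise_peak_rate)
            if n_noise:
                noise_mz = rng.uniform(*cfg.mz_range, size=n_noise)
                lo_i = math.log10(max(cfg.emission_floor, 1.0))
                noise_int = 10.0 ** rng.uniform(lo_i, lo_i + 1.5, size=n_noise)
                stick_mz.extend(noise_mz.tolist())
                stick_int.extend(noise_int.tolist())
            mz_arr = np.asarray(stick_mz, dtype=float)
            int_arr = np.asarray(stick_int, dtype=float)
            order = np.argsort(mz_arr, kind="stable")
            mz_arr, int_arr = mz_arr[order], int_arr[order]
            # collapse pathological exact-duplicate m/z values (keeps scans valid)
            if mz_arr.size > 1 and np.any(np.diff(mz_arr) <= 0):
                uniq, inverse = np.unique(mz_arr, return_inverse=True)
                summed = np.zeros_like(uniq)
                np.add.at(summed, inverse, int_arr)
                mz_arr, int_arr = uniq, summed
            scans.append(CentroidScan(rt=float(t), mz_values=mz_arr, intensities=int_arr))
        runs.append(Run(run_id=f"injection_{j:02d}", scans=scans, meta={"injection": j}))

    truth = GroundTruth(traces=pd.DataFrame(truth_rows), compounds=comp, config=cfg)
    return RunSet(runs=runs), truth


def truth_feature_count(
    truth: GroundTruth, floor: float = 0.0, per_injection: bool = False
):
    """Number of ion traces expected detectable at the stated intensity floor.

    With ``per_injection=False`` a trace counts once if its apex is at or
    above the floor and it was never dropped in any injection — exactly the
    traces that can yield a complete ("reliable") feature group.  With
    ``per_injection=True`` returns a Series of per-injection counts of
    emitted traces above the floor.
    """
    tr = truth.traces
    ok = (tr["apex_intensity"] >= floor) & (~tr["dropout"])
    if per_injection:
        return ok.groupby(tr["injection"]).sum()
    per_trace = ok.groupby([tr["compound"], tr["trace"]]).all()
    return int(per_trace.sum())
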