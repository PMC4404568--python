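import numpy as np
import pytest

from lcmsopt.model import CentroidScan, Peak, Run, RunSet
from lcmsopt.simulate import SyntheticConfig, generate_runset


def make_peak(
    mz=200.0,
    rt=100.0,
    intensity=1e5,
    run_id="r0",
    rt_halfwidth=10.0,
    mz_halfwidth=0.001,
):
    return Peak(
        run_id=run_id,
        mz=mz,
        mzmin=mz - mz_halfwidth,
        mzmax=mz + mz_halfwidth,
        rt=rt,
        rtmin=rt - rt_halfwidth,
        rtmax=rt + rt_halfwidth,
        intensity=intensity,
    )


def gaussian_run(
    fwhm=20.0,
    apex_rt=100.0,
    apex_intensity=1e5,
    mz=200.0,
    scan_interval=1.0,
    t_end=200.0,
    run_id="g0",
    floor=1.0,
):
    """Single noiseless Gaussian trace on a regular scan grid."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    scans = []
    for t in np.arange(0.0, t_end + 0.5 * scan_interval, scan_interval):
        inten = apex_intensity * np.exp(-0.5 * ((t - apex_rt) / sigma) ** 2)
        if inten >= floor:
            scans.append(CentroidScan(rt=float(t), mz_values=np.array([mz]), intensities=np.array([inten])))
        else:
            scans.append(CentroidScan(rt=float(t), mz_values=np.array([]), intensities=np.array([])))
    return Run(run_id=run_id, scans=scans)


@pytest.fixture(scope="session")
def small_runset():
    """3 injections × 12 compounds, modest drift: fast shared fixture."""
    cfg = SyntheticConfig(
        n_compounds=12,
        n_injections=3,
        rt_range=(0.0, 400.0),
        rt_drift_amplitude=15.0,
        seed=42,
    )
    return generate_runset(cfg)


@pytest.fixture(scope="session")
def study_runset():
    """The full-size study conditions: 4 injections × 30 compounds,
    ~20 s FWHM peaks, 30 s drift amplitude."""
    cfg = SyntheticConfig(seed=7)
    return generate_runset(cfg)
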