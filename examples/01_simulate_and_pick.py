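"""Simulate a pooled-sample run set and pick peaks from one injection.

The simulator produces centroided MS1 runs in which every compound elutes as
a Gaussian and carries an M+1 carbon-13 isotopologue trace at natural
abundance.  The picker chains centroids into regions of interest within a
ppm tolerance and detects chromatographic peaks with a Mexican-hat wavelet.
"""
from lcmsopt import PickParams, SyntheticConfig, generate_runset, pick_peaks, truth_feature_count

config = SyntheticConfig(n_compounds=10, n_injections=2, rt_range=(0.0, 400.0), seed=3)
runset, truth = generate_runset(config)
run = runset.runs[0]

params = PickParams(ppm=25.0, min_peakwidth=14.0, max_peakwidth=30.0)
peaks = pick_peaks(run, params)

print(f"run {run.run_id}: {run.n_scans} scans")
print(f"expected detectable ion traces (parents + isotopologues): "
      f"{truth_feature_count(truth, floor=100.0)}")
print(f"picked peaks: {len(peaks)}")
for p in peaks[:5]:
    print(f"  m/z {p.mz:9.4f}  rt {p.rt:6.1f} s  apex {p.intensity:10.0f}")
print("...")
# With 10 compounds each trace pair (parent + M+1) should be picked, so the
# peak count matches the expected trace count when the width window fits.
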