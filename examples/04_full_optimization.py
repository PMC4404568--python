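"""The full semi-sequential optimization on a small synthetic study.

Stage 1 tunes peak-picking parameters (min/max peakwidth, ppm) against the
PPS with iterated Box-Behnken designs and response-surface maximum focusing;
stage 2 tunes alignment and grouping parameters (gapInit, gapExtend, bw)
against the per-round normalized combined target RGTV = norm(RCS) + norm(GS).
"""
from lcmsopt import OptimizeConfig, SyntheticConfig, generate_runset, run_full_optimization

runset, truth = generate_runset(
    SyntheticConfig(n_compounds=15, n_injections=3, rt_range=(0.0, 450.0),
                    rt_drift_amplitude=20.0, seed=11)
)
report = run_full_optimization(runset, OptimizeConfig(max_rounds_pick=3, max_rounds_align=2))

pick, ag = report["picking"], report["align_group"]
print("peak picking:")
print(f"  default   PPS {pick['default']['pps']:8.1f}  ({pick['default']['n_rp']} RP"
      f" / {pick['default']['n_peaks']} peaks)")
print(f"  optimized PPS {pick['optimized']['pps']:8.1f}  ({pick['optimized']['n_rp']} RP"
      f" / {pick['optimized']['n_peaks']} peaks)")
s = pick["optimized_settings"]
print(f"  optimized peakwidth [{s['min_peakwidth']:.1f}, {s['max_peakwidth']:.1f}] s, "
      f"ppm {s['ppm']:.1f}")
print("alignment / grouping:")
for tag in ("default", "optimized"):
    r = ag[tag]
    print(f"  {tag:9s} ARTS {r['arts']:.3f} s  reliable {r['n_reliable']}"
          f"  non-reliable {r['n_nonreliable']}  GS {r['gs']:.0f}")
# The optimized peak-width window should bracket the simulated ~20 s FWHM,
# and the optimized grouping should approach one reliable group per true
# ion trace with no non-reliable groups.
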