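# Methods

This note documents the models, numerical choices and limitations behind
`lcmsopt`. The README gives the score definitions; here we state how each
component actually computes them, which knobs matter, and what the synthetic
data does and does not emulate.

## Isotopologue detection and the peak picking score

Reliable peaks (RP) are found by scanning, for every peak, a mass window of
`mass_tol_ppm` (default 10 ppm) around m/z + 1.0033548 (the ¹³C−¹²C mass
difference; charge 1 is assumed throughout). Candidates must co-elute —
overlapping RT extents *and* apex distance at most `rt_window_frac` (default
0.5) of the parent's RT width — and their apex intensity must lie in
[IA·I, maxC·IA·I], optionally widened by a multiplicative
`intensity_slack` (default 0, because the bundled simulator produces exact
intensities; real centroid data typically needs 0.2–0.5). Both members of an
accepted pair are labeled RP: belonging to an isotopologue is the evidence,
regardless of which member is the parent.

The low-intensity cut-off is the mean of the lowest ⌈3%⌉ of peak
intensities (at least one value). A non-RP peak is LIP when
`intensity × maxC(mz) × IA` — the most favorable isotope signal it could
have produced — falls strictly below the cut-off. The strictness at the
boundary is arbitrary but fixed and documented; it only matters for exact
ties.

PPS is computed from counts pooled over the runs of one experiment (sums of
RP, total and LIP, then one application of the formula). Pooling keeps a
single scalar per experiment for the response surface; computing PPS per run
and averaging would weight small runs equally with large ones.

Degenerate cases: RP = 0 or a non-positive denominator give PPS = 0.

## The peak-picking backend

The picker is a deliberately compact centWave-style detector, not a port:
regions of interest (ROIs) chain centroids across scans while each stays
within `ppm` of the ROI's *running mean* m/z; a centroid joins at most one
ROI per scan (nearest mean wins) and ROIs pause at most 2 missing scans
before closing. ROIs with fewer than `prefilter_k` centroids at or above
`prefilter_I` are dropped (defaults 3 and 100; kept fixed rather than
optimized). Within an ROI, a Mexican-hat CWT over 10 geometrically spaced
scales spanning [min_peakwidth, max_peakwidth] confirms local maxima of the
intensity trace; boundaries descend from the apex to the surrounding minima,
and the measured full width at half maximum (linear interpolation of the
half-max crossings, falling back to the boundary width for truncated peaks)
must lie inside [min_peakwidth, max_peakwidth]. Peaks with overlapping RT
extents closer than `mzdiff` in m/z are merged, keeping the more intense.

Omitted relative to full centWave: Gaussian-fit refinement, m/z-dependent
ROI extension, in-ROI baseline estimation, and signal-to-noise filtering
beyond the plain `noise` apex floor. The contract the optimizer relies on is
only that the four public parameters steer detection in the documented
directions, and that detection is deterministic.

## Alignment

Each run is binned into a profile matrix (m/z bins of width `profStep`,
columns = scans; bin b covers [mz_min + b·profStep, mz_min + (b+1)·profStep)).
Scan-pair similarity is the Pearson correlation of z-normalized columns
(zero-variance columns contribute similarity 0). A global dynamic program
with affine gap costs — `gapInit` to open, `gapExtend` to extend — finds the
monotone path of maximal summed similarity; matched scan pairs become knots
of a piecewise-linear warp from run times onto center-run times, clamped
beyond the first/last knot. The center run is the one whose picked peaks
have the highest mean intensity (ties: first in input order).

This is a documented simplification of profile-correlation alignment: no
m/z warping, no alternative score functions, no local path constraints. The
horizontal-gap recurrence is evaluated with a running-maximum trick so each
DP row costs O(n) vector work; the whole alignment of two ~600-scan runs
takes tens of milliseconds. The similarity matrix depends only on
`profStep`, so the optimizer caches it across experiments and rounds and
re-runs only the (cheap) DP when gap penalties change.

## Grouping

Peaks are sorted by m/z and sliced into overlapping windows of width
`mzwid` (50% overlap, so a feature straddling a slice edge is always fully
contained in the neighboring slice). Within a slice, a Gaussian kernel
density over RT with bandwidth `bw` is evaluated on a grid of step ~bw/4;
plateau-aware local maxima are found and region boundaries placed at the
minima between consecutive maxima (watershed), with the outer regions
extending to the grid edges. Candidate groups are processed in descending
peak-count order and every peak joins at most one group. Groups must contain
peaks from at least `minfrac × n_runs` *distinct runs* — duplicate peaks
from one run cannot satisfy the fraction, which keeps the "exactly one peak
per injection" reliability criterion meaningful downstream.

## The DoE engine

Designs: Box-Behnken for k ≥ 3 (every parameter pair at the four (±1, ±1)
combinations, others at 0, plus one center point — 13 rows at k = 3, 25 at
k = 4); a full 3-level factorial at k = 2 and a three-point sweep at k = 1,
preserving the three-evenly-spaced-levels property below BBD's domain. One
center point suffices because the evaluators are deterministic — replicated
centers would add cost without information.

The full quadratic (1 + 2k + k(k−1)/2 coefficients) is fitted by least
squares in coded units; exact quadratics are recovered to machine precision.
Rows whose evaluator raised are excluded from the fit (with a warning) as
long as at least as many rows as coefficients remain. The surface maximizer
over [−1, 1]^k is located on a dense grid (step 0.01 for k ≤ 3, 0.05 at
k = 4, 0.2 above — the finer steps are memory-infeasible in high dimension)
refined by bounded L-BFGS ascent; among tied grid points the exact center is
preferred if tied, otherwise the lexicographically smallest, making the
result deterministic even on flat surfaces.

Range adjustment re-centers every parameter on the located maximum. The
zoom-out trigger is "the maximum lies on a bound of that parameter's range"
(|coded| ≥ 1 − 1e−9); zoom-in requires |coded| < 0.25. Floors (positivity of
ppm, widths, bandwidths; nonnegativity of gap penalties; minfrac ∈ (0, 1])
are enforced by clamping the lower bound, which can leave a range asymmetric
around its center — accepted. Ordering constraints (min_peakwidth <
max_peakwidth) are checked on the new centers; violations raise with a
repair suggestion. Decoded settings that are individually infeasible
(min ≥ max after decoding) are evaluated as score 0, penalizing that region
of the surface rather than leaving a hole in the design.

## The optimizer

Semi-sequential: picking parameters first against PPS, then alignment and
grouping parameters simultaneously against RGTV — grouping is needed to
assess the RT correction, and the split avoids re-running the (expensive)
picking inside alignment rounds. Each stage stops when a round's best score
fails to strictly exceed the running best, or at `max_rounds` (default 10),
and returns the global best over all evaluated experiments, guarding against
a final degraded round.

RGTV is only comparable within one round (its normalization is per-round),
so rounds of the second stage are compared on the lexicographic (GS, RCS)
pair of each round's best experiment. Within a round, experiments are ranked
by RGTV with ties broken on the same (GS, RCS) pair — ties are common after
the ARTS = 0 sentinel mapping (a perfectly aligned experiment has
RCS = ∞, which the normalization maps to the round's largest finite RCS
rather than propagating infinity into the surface fit).

Default start ranges: peakwidth window centered on [20, 50] s (min ∈
[12, 28], max ∈ [35, 65]), ppm ∈ [10, 40], mzdiff fixed at 0.005 Da;
gapInit ∈ [0, 0.8], gapExtend ∈ [0.5, 2.5], bw ∈ [3, 15] s with profStep
fixed at 1.0 Da, mzwid at 0.025 Da (the classic 0.25 Da default is far too
wide for high-resolution data) and minfrac at 1.0 — the pooled sample is
identical in every injection, so a trustworthy feature should appear in all
of them. Keeping profStep, mzwid and minfrac fixed also keeps the second
stage at k = 3 (13 experiments per round) and lets the similarity-matrix
cache absorb most of the alignment cost.

## The synthetic study

The generator emulates repeated injections of one pooled sample: each
compound elutes as a Gaussian (FWHM drawn from `fwhm_range`, default
18–22 s) with an M+1 trace at +1.0033548 Da and relative apex intensity
n_carbons × IA — a first-order binomial isotope model; M+2 (~0.5% of the
parent at 30 carbons) is ignored, consistent with the single-¹³C detection
criteria. Carbon counts follow a hydrocarbon-like heuristic
(round(m/z·0.7/14), clamped to [1, maxC]); a user-supplied carbon model that
exceeds maxC is rejected, keeping simulation and scoring mutually
consistent. Per-injection drift is linear plus one sinusoid with amplitude
`rt_drift_amplitude` (default 30 s) — smooth and run-wide, as LC drift is.
Centroid m/z values get N(0, 3 ppm) jitter; Poisson-rate noise sticks
(default 2 per scan) are sprinkled at low intensities; intensities below an
emission floor (50 counts) are not written, mimicking detector sensitivity.

Compound m/z values are rejection-sampled so all ion traces sit at least
0.2 Da apart, making the truth-to-feature mapping unambiguous — one
detectable trace should become exactly one feature group. This is the main
idealization: real data has co-eluting isobars, adducts, in-source
fragments, multiply charged species, intensity noise and saturation, none of
which the simulator produces. Passing tests therefore demonstrate that the
scores, designs and optimization loop behave as specified and that the
backends respond to their parameters in the documented directions — not
that the picker or aligner is competitive on real instrument files.

Study sizes were chosen to exercise every code path at desk scale: the
bundled study is 4 injections × 30 compounds (≈600 scans/run, ~8 centroids
per scan), on which a full two-stage optimization takes well under a minute;
the acceptance script runs exactly this study, routed through mzML files so
the public input path is covered.

## Known limitations

- mzML support is narrow by design: centroided MS1, 32/64-bit float arrays,
  no-compression or zlib. Profile-mode files are rejected, not centroided.
- The intensity convention is apex height everywhere; integrated areas are
  not computed.
- Only singly charged ions are considered in both simulation and the
  isotopologue criteria.
- A matchedFilter-style low-resolution backend is not provided; the
  parameter machinery is generic, but the only bundled picker is the
  centWave-style one.
- Cross-round RGTV comparison is an interpretation (see above); scores from
  different rounds are never compared directly.
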