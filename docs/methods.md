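# Methods

This note records the models the package implements, the assumptions and
defaults behind them, and the choices made where the underlying measurement
conventions are genuinely open.

## FRAP normalization and recovery model

A FRAP trace consists of the mean intensity of a bleached ROI (I_t) and of a
cell-free background ROI (I_bgt), with the first `n_prebleach` frames
acquired before the bleach. Normalization is

    RFI_t = (I_t − I_bgt) / (I_pre − I_bgpre),

with I_pre and I_bgpre the means over all prebleach frames (plural prebleach
timepoints are aggregated by the mean, the standard choice). Time is
re-zeroed at the first postbleach frame, so the mean prebleach RFI is 1 by
construction and RFI is invariant to affine rescaling of the camera
(I → aI + b applied to both ROIs, a > 0).

Recovery is modeled as a single exponential with a distinct immobile
fraction,

    RFI(t) = floor + (plateau − floor)(1 − e^{−kt}),

the minimal model that yields one half-time per cell: t½ = ln2/k, reported
from the fitted rate rather than by curve-crossing interpolation (equivalent
for this model class, and robust to noise). The mobile fraction is
(plateau − floor)/(1 − floor). Fitting is bounded trust-region least squares
parameterized as (floor, Δ = plateau − floor, k) so floor ≤ plateau is
structural; bounds floor ∈ [−0.2, 1], plateau ≤ 1.5, k ∈ (0, 10] 1/s;
initialization: floor = first postbleach RFI, plateau = mean of the last 10%
of frames, k = ln2 over the interpolated time to reach halfway between
them. Non-convergence and degenerate cases are reported through flags
(`converged`, `k_unidentifiable` for flat curves, `k_at_bound`), never
raised, so cohort pipelines can skip and log. Double-exponential and
diffusion-reaction FRAP models, bleach-depth spatial profiles and
acquisition-photobleaching correction are out of scope.

Cohort ("cumulative") curves linearly interpolate each cell's RFI onto a
common grid and report mean ± population SD with n. Cohort half-times are
summarized as the mean ± SD of per-cell fits; a fit to the pooled curve can
be obtained by passing the cohort mean curve back through `fit_recovery`.

## Adhesion lifetime kinetics

Lifetime traces are background-subtracted per frame and smoothed with a
centered three-frame running average; at the trace ends the window is
truncated to the available frames (the first smoothed value of a window-3
trace is the mean of frames 0 and 1). The peak is the argmax of the
smoothed trace, earliest frame on ties.

The assembly phase (frames up to and including the peak) is fit with a
3-parameter logistic A_a/(1 + e^{−r_a(t − t_a)}) — zero baseline, since
background is removed upstream. The disassembly phase (frames from the
peak) is fit with

    I(t) = A_d · e^{−r_d · max(t − t_d, 0)},   t_d ≥ t_peak,

a plateau-then-decay form whose free onset t_d absorbs any dwell the
adhesion spends at maximum intensity before disassembling; for a trace that
decays immediately the onset collapses to the peak time and the model is an
anchored exponential. "Steepness" rates are r_a and r_d (the only steepness
parameters these models expose); the maximum logistic slope A_a·r_a/4 is
reported as an auxiliary output. Lifetime is the unique interval the two
half-times define:

    lifetime = (t_d + ln2/r_d) − t_a.

Two refinements relative to the naive recipe, both forced by exactness on
noiseless data:

1. **Fit source.** The running average sets the phase boundaries, but the
   least-squares fits run on the *unsmoothed* background-subtracted trace by
   default (`source="bgsub"`). Smoothing an exponential or logistic flattens
   its curvature — a systematic relative rate bias of order (r·Δt)²/6, about
   1–7% at 30-s frames — and correlates adjacent noise. Fitting the raw
   trace removes that bias; `source="smooth"` reproduces the
   fit-the-smoothed-curve behavior when needed.
2. **Split-anchor refinement.** A centered running average can displace the
   argmax of an asymmetric peak by up to half a window, which would place
   rising frames inside the decay segment. The split frame is therefore the
   argmax of the fit-source values within one smoothing half-window of the
   smoothed peak (earliest on ties).

Each phase uses bounded least squares with multi-start (3 logistic rate
starts; 2 decay onset starts), since the original spreadsheet-solver
settings such fits historically used are not reproducible; a grid-search
oracle arbitrates in the tests. A phase with fewer than 4 frames is flagged
not-fit; a constant post-peak segment yields rate 0 with
`rate_unidentifiable`; a rising post-peak segment is flagged
`non_decaying`. Traces are expected to span assembly through full
disassembly (first and last smoothed values below 25% of peak, threshold
configurable); incomplete traces produce a warning, and the peak-anchored
disassembly-only fit (`fit_disassembly_from_peak`) covers recordings whose
assembly phase is undetectable. Automatic detection of adhesion birth/death
from movies is out of scope — traces are assumed extracted per adhesion, as
in a manual-ROI workflow.

## Motility metrics

Mean velocity is the average of per-interval speeds (displacement over Δt
for each consecutive frame pair), converted to µm/min — not total path over
total time, which is reported separately as `path_velocity`. The
directionality ratio d/D uses the straight-line start-to-end distance d and
the total path length D, computed at the final frame (one ratio per cell);
D = 0 yields NaN with a warning. MSD is time-averaged over all overlapping
frame pairs at each lag (the common default among tracking tools; stated
explicitly here because conventions differ), requires uniform frame
intervals, and is pooled across cells as mean ± SD of per-track MSDs.
Wound-directed trajectories are aligned by translating each track's start
to the origin and applying the proper rotation that maps the start→wound
direction onto +x; the transform is rigid, so all inter-frame distances are
preserved. The wound is a single reference point per recording, supplied in
the track-file header or on the command line. Statistical comparison
between groups is left to standard library calls on the exported tables; 3D
tracks are out of scope.

## Imaging

Maximum-intensity projection takes the per-pixel maximum over a selected
z-range. Spot segmentation thresholds the image (Otsu by default — 
reproducible where a hand-picked threshold is not — with an absolute
override), labels 8-connected components, removes components below
`min_area_px` (default 4 px, suppressing single-pixel noise), and reports
area = pixel count × pixel_size² plus intensity-weighted (sub-pixel)
centroids. Coordinates use pixel (0,0) at top-left, x = column·pixel_size,
y = row·pixel_size, 0-based indices; label images are deterministic
(raster-scan order). Centroid tracking assumes one object of interest per
movie: per frame the largest component's centroid is taken and linked to
the previous position by nearest neighbor within `max_link_dist_um`; frames
with no linkable object are gaps, and a series with >50% gaps is flagged
unusable. Multi-object tracking with crossing resolution, 3D segmentation,
deconvolution and vendor formats are out of scope.

## Synthetic data and what passing tests show

The generators emulate the acquisition regimes of the measurements (FRAP:
2-s frames, 3 prebleach, 5 min postbleach, instantaneous bleach between the
last prebleach and first postbleach frame; lifetime: 20/30-s frames within
a 1-h window; wound response: 30-s frames for 10 min; random migration:
5-min frames for 10 h) with deliberately simple generative stand-ins:

- FRAP: prebleach plateau, instantaneous drop to `bleach_depth`, then
  single-exponential recovery of a `mobile_fraction` of the bleached
  signal. Defaults: prebleach level 1000 a.u. over a background of 100,
  bleach depth 0.2, mobile fraction 0.8 — a deep bleach with a mostly
  mobile pool, typical of adaptor-protein FRAP.
- Lifetime: logistic rise truncated at the frame where it reaches 99.5% of
  plateau, a dwell at that level, then exponential decay cut off at 0.5%;
  phase boundaries snap to the frame grid so the noiseless trace is
  continuous with its maximum at the last assembly frame. Defaults
  (r_a = 0.01/s, midpoint 300 s, dwell 60 s, r_d = 0.005/s, 30-s frames)
  describe an adhesion assembling over minutes and turning over well inside
  the 1-h acquisition.
- Tracks: biased persistent random walk — step direction is the
  renormalized sum of persistence-weighted previous direction,
  bias-weighted wound direction, and an isotropic random component weighted
  (1−persistence)(1−bias); step lengths are folded-normal with underlying
  mean equal to the target mean step and σ = mean/3 (the folded mean then
  exceeds the target by ~0.03%, negligible against the 5% recovery
  tolerance; zero speed maps to exactly zero steps).
- Spot images: isotropic Gaussian peaks on a constant background.

Noise is additive Gaussian on intensities, truncated at zero; Poisson
photon statistics, reversible photobleaching, acquisition bleaching,
diffusion-coupled recovery and 3D point-spread functions are deliberately
not modeled. Every simulated object carries exactly one ground-truth record
(including the model name, marking it as a stand-in), and all generators
are bit-reproducible for a fixed seed.

Passing the recovery suites therefore demonstrates that the estimators are
unbiased and correctly implemented *under these generative models* — it
does not certify performance on real imaging artifacts (uneven
illumination, focus drift, adhesion splitting/merging, tracking errors),
which have no stand-in here.

## Validation problem sizes

The acceptance workflow uses cohorts of 36 FRAP traces per condition
(matching a typical in-vitro cohort) at half-times spanning 5–20 s plus a
6.5 s vs 15.5 s pair for statistical separation; a 3×3 kinetics grid
spanning one decade in each rate with 50 noisy traces per cell (5%
intensity noise in both suites); 20-instance oracle-equivalence batches;
and 40-cell round-trip track cohorts. These sizes give Monte-Carlo error
comfortably below the acceptance tolerances (10% cohort-mean half-time
error, 15% median rate error) while completing in well under a minute for
FRAP and a few seconds for the rest.

## Known limitations

- The single-exponential recovery model cannot represent binding-diffusion
  coupling; half-times from multi-component recoveries will be effective
  values.
- The lifetime fitter assumes one assembly→peak→disassembly cycle per
  trace; oscillating or re-assembling adhesions violate the model and are
  flagged only indirectly (poor residuals, incompleteness warning).
- MSD assumes uniform sampling; tracks with dropped frames must be
  resampled upstream.
- Centroid tracking assumes a single dominant object; a brighter transient
  object in the field will capture the link unless `max_link_dist_um`
  excludes it.
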