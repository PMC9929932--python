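# fadyn

Quantification of focal-adhesion dynamics and single-cell migration from
live-imaging measurements: FRAP recovery fitting, adhesion
assembly/disassembly kinetics, cell-track statistics, and threshold-based
spot analysis — with a synthetic-data generator so every stage can be
validated against known ground truth.

## Who this is for

Cell biologists quantifying adhesion turnover and migration from
fluorescence time-lapse data: ROI intensity traces exported from FIJI
(FRAP and adhesion lifetime experiments), manually or automatically tracked
cell coordinates, and 2D projections of z-stacks with fluorescent puncta.

## What it computes

**FRAP** (`fadyn.frap`). Raw bleached-ROI and background traces are
normalized to relative fluorescence intensity,

    RFI_t = (I_t − I_bgt) / (I_pre − I_bgpre),

where I_pre and I_bgpre are prebleach means, and fit with a
single-exponential recovery

    RFI(t) = floor + (plateau − floor)(1 − e^{−kt}),

yielding the half-time t½ = ln2/k, the plateau, and the mobile fraction
(plateau − floor)/(1 − floor). Cohort curves are interpolated onto a common
grid and reported as mean ± SD.

**Adhesion kinetics** (`fadyn.kinetics`). An adhesion's
background-subtracted intensity life history is smoothed with a three-frame
running average and split at the peak. The assembly phase is fit with a
logistic A_a/(1 + e^{−r_a(t − t_a)}), the disassembly phase with a
single-exponential decay A_d·e^{−r_d·max(t − t_d, 0)} whose onset t_d
absorbs any dwell at the plateau. Assembly and disassembly rates are the
steepness constants r_a and r_d; the lifetime is the interval between the
two half-times, (t_d + ln2/r_d) − t_a. A peak-anchored, disassembly-only
fit handles traces whose assembly phase is undetectable.

**Motility** (`fadyn.motility`). Mean velocity (average of per-interval
speeds, µm/min), directionality ratio d/D (straight-line distance over path
length), time-averaged mean squared displacement per lag, and rigid
alignment of wound-directed trajectories so every cell starts at the origin
with the wound on the +x axis.

**Imaging** (`fadyn.imaging`). Maximum-intensity projection, Otsu or
absolute-intensity thresholding with 8-connected component labeling and
minimum-size filtering (areas in µm², intensity-weighted centroids), and
single-object centroid tracking that feeds directly into the motility
metrics.

**Synthetic data** (`fadyn.sim`). Generators for FRAP traces, adhesion
lifetime traces, biased persistent-random-walk tracks, and Gaussian-spot
images, each emulating a real acquisition regime (2-s FRAP frames with 3
prebleach frames and 5 min postbleach; 20/30-s lifetime frames; 30-s or
5-min tracking intervals) and each returning a ground-truth record of its
generative parameters.

## Worked example

Simulate a cohort of 16 FRAP traces with a generative half-time of 6.5 s
and 5% intensity noise, then fit each cell:

```python
import numpy as np
from fadyn.frap import fit_recovery, normalize_frap
from fadyn.sim import FrapSimParams, simulate_frap_trace

k = np.log(2) / 6.5  # 1/s
thalfs, mobiles = [], []
for i in range(16):
    trace, truth = simulate_frap_trace(FrapSimParams(k=k, noise_sd=50.0, seed=100 + i))
    fit = fit_recovery(normalize_frap(trace))
    thalfs.append(fit.t_half)
    mobiles.append(fit.mobile_fraction_est)

print(f"n = {len(thalfs)} cells")
print(f"t_half = {np.mean(thalfs):.1f} +/- {np.std(thalfs, ddof=1):.1f} s  (generative: 6.5 s)")
print(f"mobile fraction = {np.mean(mobiles):.2f} +/- {np.std(mobiles, ddof=1):.2f}  (generative: 0.80)")
```

Output:

```
n = 16 cells
t_half = 6.4 +/- 0.9 s  (generative: 6.5 s)
mobile fraction = 0.79 +/- 0.04  (generative: 0.80)
```

The cohort mean recovers the generative half-time within the per-cell
scatter, and the mobile fraction matches the simulated exchangeable pool.

The same workflow is available from the shell:

```sh
fadyn simulate frap --n 16 --k 0.1066 --noise-sd 50 --seed 100 --outdir sim
fadyn frap fit sim/trace_*.csv --outdir fits   # fits.csv + cohort_summary.csv
```

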