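# fretpulse

Analysis pipeline for single-cell FRET biosensor experiments in budding
yeast: ratiometric quantification of donor/acceptor time-lapse traces,
saturation dose-response fitting, k-means clustering of response
trajectories, plate-reader growth-rate estimation, and flow-cytometry FRET
quantification with control-strain corrections — plus a forward simulator
that generates all three input kinds (microscopy trace tables, cytometry
event tables, OD600 curves) with known ground truth, so every stage of the
pipeline is testable without instrument data.

## The problem

A genetically encoded kinase-activity reporter (an AKAR-family sensor)
changes its FRET efficiency when phosphorylated. In microscopy, each cell
yields a donor-channel and an acceptor-channel emission trace over time; a
nutrient perturbation at t = 0 elicits a response on top of a resting
baseline. Raw channel intensities cannot be compared across cells — they
mix sensor expression level, donor-to-acceptor spectral bleedthrough, and
background — so the pipeline computes, per cell:

1. **Background subtraction** per channel.
2. **Bleedthrough correction**: corrected acceptor = acceptor − β·donor,
   with β = 0.40 by default (the donor fraction spilling into the acceptor
   channel, measurable from a donor-only strain).
3. **FRET ratio** R = corrected acceptor / donor.
4. **Baseline normalization**: divide by the mean pre-perturbation ratio,
   so 1.0 is the resting state of every cell.
5. **Features**: basal ratio, change in normalized FRET at a chosen time,
   maximal slope (best windowed-regression slope, per minute), final FRET
   (mean of the last 3 frames), and an expression proxy.

Downstream, final FRET versus ligand concentration c is fit with a
single-site saturation curve, `response − 1 = max·c / (K05 + c)`;
trajectories are clustered by k-means with canonical cluster ordering
(descending final FRET); growth rates come from a moving-average /
sliding-window log-linear regression with tenth-fastest-slope selection;
and cytometry events pass a scatter-saturation filter, empty-plasmid
median subtraction, a donor-only bleedthrough estimate, a minimum
direct-acceptor gate, and a non-responsive-sensor correction.

The simulator inverts all of this: it partitions a cell's total sensor
emission S between channels so that donor = S/(1+R) and acceptor =
S·R/(1+R), then adds bleedthrough, background, and noise. A perfect
correction therefore recovers R exactly on noise-free data — the
correction is falsifiable, not decorative.

## Worked example

Simulate a heterogeneous three-class response to a sugar transition,
quantify it, and cluster the trajectories:

```python
from fretpulse import simulate, fret, clustering

design = simulate.mannose_design(n_cells=200, seed=0)
table, truth = simulate.simulate_trace_set(design)
table.head(3)
#   cell_id  frame  time_min   donor  acceptor  background_donor  background_acceptor
# cell_0000      0     -10.0 1144.74   1572.97             100.0                100.0
# cell_0000      1      -9.0 1116.98   1522.41             100.0                100.0
# cell_0000      2      -8.0 1184.53   1532.18             100.0                100.0

norm, feats, qc = fret.analyze_traces(table, beta=0.40)
matrix, _ = clustering.resample_traces(norm)
result = clustering.cluster_traces(matrix, k=3, seed=0)
clustering.summarize_clusters(result, feats)
#  cluster  n  final_fret_mean  final_fret_std  max_slope_mean
#        1 61            1.239           0.041           0.075
#        2 77            1.079           0.028           0.265
#        3 62            0.899           0.028           0.049
```

Cluster 1 holds sustained switchers, cluster 2 fast-but-weak transient
responders, cluster 3 declining cells — recovered from the raw channel
tables alone.

Fit a dose-response curve and estimate a growth rate:

```python
from fretpulse import dose_response, growth

pts = simulate.simulate_dose_response(
    0.24, 0.24, [0.0, 0.06, 0.12, 0.24, 1.0, 10.0, 100.0], noise_sd=0.02, seed=1
)
print(dose_response.fit_dose_response(pts).summary())
# Saturation dose-response fit (response - 1 = max*c/(K05 + c))
#   max_response :     0.2379
#   K05 (mM)     :     0.2458
#   RSS          :  2.703e-05   (mean fit)

curve = simulate.simulate_growth_curve(mu=0.36, seed=0)
res = growth.estimate_growth_rate(curve)
print(f"{res.selected_rate:.3f} /h")   # 0.355 /h
```

The same stages are available as a CLI (`fretpulse simulate-traces`,
`timelapse`, `dose`, `cluster`, `growth`, `flow`); every subcommand writes
its outputs plus the exact configuration used into the chosen directory.

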