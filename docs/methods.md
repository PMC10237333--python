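# Methods

This note defines the forward models behind `fretpulse.simulate`, the
quantification conventions behind the analysis modules, and the reasoning
for every default. Units: time-lapse time in minutes (t = 0 at the
perturbation), growth time in hours, fluorescence in arbitrary units (a.u.),
OD600 in OD units.

## 1. Microscopy forward model

### Emission partition

Each cell has a total sensor emission budget `S` (expression level) and a
true FRET ratio trajectory `R(t)`. The two channels split `S` as

```
D(t) = S / (1 + R(t))          true donor emission
Y(t) = S · R(t) / (1 + R(t))   true acceptor emission
```

so `Y/D = R` and `D + Y = S` at every frame. Measured channels are

```
donor    = D·(1 + η_m) + η_a + bg
acceptor = Y·(1 + η_m) + β·D_noisy + η_a + bg
```

with multiplicative noise `η_m ~ N(0, cv_m)`, additive noise
`η_a ~ N(0, σ_a)`, flat background `bg`, and donor-to-acceptor
bleedthrough fraction `β`. Because the bleedthrough term uses the donor's
noisy realization, the analysis-side correction
`acceptor − β·donor` removes it *exactly* when background is subtracted
first — on noise-free data the pipeline recovers `R(t)` to machine
precision, which the test suite asserts. This is the point of the
partition: the correction has a ground truth to be wrong against.

### Response trajectory family

`R(t) = r0 · g(t)` with `g = 1` for `t < 0` and, for `t ≥ 0`,

```
g(t) = 1 − d·exp(−k_dip·t)
         + A·(1 − exp(−k_rise·(t − t0))) · (f + (1 − f)·exp(−k_dec·(t − t0)))
```

(rise term zero before the onset delay `t0`). Parameters per response
class (`ResponseClassParams`):

| parameter | meaning | units |
|---|---|---|
| `basal_ratio` (r0) | resting FRET ratio | — |
| `amplitude` (A) | asymptotic fractional change | — |
| `rise_rate` (k_rise) | activation rate | min⁻¹ |
| `delay` (t0) | onset delay after perturbation | min |
| `sustained_fraction` (f) | fraction of A that persists; plateau = 1 + f·A | — |
| `decay_rate` (k_dec) | decay of the transient part | min⁻¹ |
| `dip_depth` (d), `dip_rate` (k_dip) | brief initial dip and its recovery | —, min⁻¹ |
| `cv_r0`, `cv_amplitude` | cell-to-cell log-normal variability | — |
| `grower_prob` | probability a cell of this class resumes growth | — |

The family covers sustained switches (f = 1), overshoot-then-decay
transients (f < 1), declines (A < 0), and the perturbation-associated dip.
Per-cell `r0` and `A` are log-normal with the class mean and CV
(arithmetic-mean parameterization; negative means keep their sign).

Design-level defaults (`TraceSimulationDesign`): 1-min frames, 10 min
baseline, 60 min total, β = 0.40, expression mean 2000 a.u. (CV 0.3),
additive noise SD 1 a.u., multiplicative noise CV 0.02, background 100 a.u.

### Slope calibration

The `max_slope` feature is the best least-squares slope over contiguous
3-frame windows of the normalized trace. Its population mean on simulated
cells is *not* the analytic maximum derivative of `g`: frame discretization
loses the instantaneous peak, and taking a maximum over noisy windows adds
an extreme-value bias. When a fixture must reproduce a printed slope
statistic, `calibrate_rise_rate` therefore solves for `k_rise` such that
the *pipeline-measured* mean max slope on a dedicated simulation (fixed
internal seed 9173, 150 cells) equals the target, by Brent root finding.
Targets outside the attainable range clamp to the nearest bound with a
warning — e.g. the grower class target 0.12 min⁻¹ slightly exceeds what a
monotone riser can show at 1-min sampling (the measured slope saturates
near 0.117 min⁻¹), so its rate clamps and the realized mean sits within
one standard error of the target. Calibration happens once, at design
construction; nothing downstream feeds back into it.

A consequence worth stating: a class whose plateau is barely elevated
(1.08) but whose measured slope is high (0.26 min⁻¹) must overshoot and
decay — a monotone rise to +0.08 cannot produce that slope. The
weak-responder class is therefore a transient (A = 0.70, f = 0.08/0.70,
k_dec = 0.2 min⁻¹). Similarly, a "non-responding" population whose FRET
change has SD three times its mean (0.07 ± 0.20) cannot be one unimodal
class; it is modelled as an equal mixture of mild responders (Δ = +0.24)
and decliners (Δ = −0.10) whose pooled moments match.

## 2. Quantification conventions

* Pipeline order is fixed: background → bleedthrough → ratio → baseline
  normalization. Ratios are per frame; frames with non-positive donor are
  dropped and counted in a QC record, as are cells losing every frame.
* Baseline = all frames with negative time unless a window is given.
  Basal FRET is the raw (non-normalized) baseline-mean ratio.
* Final FRET = mean of the last 3 normalized frames; the FRET change
  Δ is evaluated at the frame nearest a chosen time (or at the last frame
  with `t_eval="end"`).
* `max_slope` evaluates post-perturbation frames only, so steep baseline
  artifacts cannot masquerade as responses.
* Clustering operates on normalized traces resampled (linear
  interpolation) onto the shared post-perturbation grid; cells covering
  less than half the grid are excluded and reported. k-means uses 25
  restarts, Lloyd's algorithm, tolerance 1e-6, rows sorted by cell id, so
  results are deterministic given the seed and invariant to row order.
  Labels are canonical: clusters renumbered 1..k by descending mean final
  FRET. k is a user choice (default 3); an inertia/silhouette report is
  available but nothing auto-selects.
* Group contrasts use the classical pooled-variance two-sample t-test
  (Welch available via `equal_var=False`).

## 3. Dose response

Model: `response − 1 = max_response · c / (K05 + c)`, fit by
Levenberg–Marquardt on log-parameters (both positive by construction;
an unconstrained variant exists for cross-checking). Default fits
per-concentration means; a per-cell fit is available. Flat or declining
response sets pin `max_response` near zero and are flagged
`k05_identifiable = False` — with no amplitude there is no information
about K05. The test suite checks the fit against a dense grid-search
oracle and exact recovery on noise-free data.

## 4. Growth rates

Estimator: centered moving average of the OD series, least-squares slope
of `ln(OD − blank)` versus time (h) in every contiguous sliding window,
tenth-fastest slope selected. Blank defaults to the minimum of the first
three readings. On a noise-free exponential every window slope equals μ
exactly, for any smoothing and window size (a centered moving average
rescales an exponential by a constant, which the log-slope ignores).

Defaults: smoothing window **15 points**, regression window **90 min** of
points, rank **10**. The wide smoothing window is deliberate: with
plate-reader noise of 0.005 OD, windows taken where the culture is still
dilute have log-noise of several percent per point, and the rank-10
selection over many overlapping windows otherwise rides the upper noise
tail. Since smoothing is slope-neutral on exponentials, widening it buys
variance without bias; at these defaults the estimator recovers
μ ∈ {0.16, 0.25, 0.34, 0.36} h⁻¹ from noisy logistic fixtures within
±0.02 h⁻¹ across 1,000+ seeded runs.

The rank-10 rule suppresses short artifacts (bubbles, condensation) only
while the artifact's footprint — spike width plus smoothing smear —
inflates fewer than ten windows. A 5-point doubling artifact is absorbed
exactly with no smoothing and 60-min windows, but *not* at the wide
defaults; the tests exercise the rule in its valid regime.

Generator (`simulate_growth_curve`): OD(t) = blank + logistic growth from
`od0` toward `carrying_capacity` at maximum specific rate μ after a lag,
plus Gaussian read noise. Defaults: od0 = 0.12 (24× the default noise SD,
so the inoculum is resolvable), carrying capacity 8.0 (od0/K = 1.5%, so a
genuine exponential phase exists — in a logistic the realized specific
rate is μ(1 − OD/K) and never reaches μ unless od0 ≪ K), lag 1 h, noise
SD 0.005 OD, 5-min sampling, 24 h.

## 5. Flow cytometry

Gate chain, in order: drop events with saturating forward/side scatter;
subtract the empty-plasmid strain's per-channel medians; estimate β as
the median FRET/donor ratio of the donor-only (eCFP) strain; keep events
with direct-excitation acceptor ≥ 2500 a.u. (inclusive — the gate keys on
sensor expression, not FRET state); compute per-event corrected ratios
`(fret − β·donor)/donor` and take per-condition medians. The
non-responsive (NR) sensor strain corrects kinase-independent signal by
condition-matched division (subtraction available), then levels are
normalized to a reference condition (default glucose).

The simulator draws event expression log-normally (median 8000 a.u.,
CV 0.8 — chosen so the acceptor gate actually removes a ~10% tail and the
gate logic is load-bearing), splits sensor emission with the same
partition as microscopy, gives the donor-only strain a β-proportional
FRET channel, the empty strain background only, and marks a set fraction
of events with saturating scatter. Noise-free, the recovered β is exactly
0.40 and per-condition ratios equal the design's true ratios.

## 6. What the simulator does and does not emulate

Emulated: baseline-then-perturbation trace structure with heterogeneous
response classes; expression variability; additive + multiplicative
channel noise; bleedthrough; background; saturating dose-response;
log-normal cytometry populations with all four control/sample strains;
exponential-to-logistic growth with lag, blank, and read noise.

Not emulated: pixels, segmentation, or tracking errors (inputs are
per-cell tables downstream of segmentation); photobleaching and focus
drift; cell-cycle or lineage structure; correlated (temporal or
spatial) noise; plate-reader nonlinearity at high OD; spectral
compensation beyond a single bleedthrough term; doublets or debris in
cytometry. Statistical consequence: noise is independent per frame and
per event, so real-data error bars will generally be wider than the
simulator suggests.

## 7. Numerical choices

* Sliding-window regressions use vectorized centered least squares
  (`sliding_window_view`), verified against `np.polyfit` per window.
* Log-normal draws are parameterized by arithmetic mean and CV:
  σ² = ln(1 + cv²), μ = ln(mean) − σ²/2.
* k-means is scikit-learn's Lloyd with fixed seed; the dose fit is
  SciPy's Levenberg–Marquardt; the t-test is SciPy's `ttest_ind`.
* All simulation randomness flows through `numpy.random.default_rng`
  seeds; equal seeds give byte-identical tables.

## 8. Limitations

* The ±0.02 h⁻¹ growth-rate guarantee is validated for the generator's
  sampling regime (5-min intervals, 24 h, noise SD 0.005, od0 ≫ noise);
  sparser sampling or louder noise requires re-examining the smoothing
  and window defaults.
* The tenth-fastest rule's artifact robustness is regime-dependent (see
  §4); it is not a general outlier-rejection method.
* Canonical cluster ordering assumes final FRET separates the clusters;
  clusters differing only in kinetics would need a different ordering key.
* The dose-response fit assumes independent errors across concentrations
  and reports no confidence intervals; for inference beyond point
  estimates, bootstrap the per-cell table.
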