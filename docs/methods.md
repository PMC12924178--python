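# Methods

This note documents the models implemented in `protonbdt`: the synthetic
delivery simulator, the feature and regression pipeline, the Shapley
attribution machinery, and the two downstream applications. It records the
design choices made where the design was genuinely open, and what the
synthetic studies do and do not demonstrate.

## 1. Machine model and synthetic log generator

### Delivery structure

A plan is an ordered spot list per beam. Each beam opens with a
**low-charge verification layer**: a copy of its first treatment layer
delivered at a fixed 5 pC per pulse (the machine uses it to measure and
correct spot positions). Treatment layers follow in descending energy
order. Within a layer, spots follow a serpentine raster on a square grid
whose spacing is drawn per layer from U(3, 8) mm. Spot charges are drawn
from U(2, 20) pC and split into pulses by *fill-to-cap*: ⌈q/8⌉ pulses, all
at the 8 pC cap except a final remainder. Fill-to-cap (rather than equal
division) maximises per-pulse charge the way a synchrocyclotron extraction
would; the cap and the low charge are config fields.

### Energy selection

161 energy levels spaced 2.1 mm water-equivalent are realised by a
range-modulator of 18 plates. Plate thicknesses are not public, so the
simulator assigns binary weights 1, 2, 4, …, 128 (in spacing units) to the
first eight plates and keeps the rest as spares; this is the minimal scheme
reproducing the level count and spacing, it makes level→occupancy a
bijection, and it gives "plates moved" (the Hamming distance between
occupancies) a concrete meaning. Note that 160 × 2.1 mm = 336 mm; the
simulator honours the level count and spacing rather than any nominal
range endpoint.

### Adaptive aperture

The 14-leaf aperture is abstracted as 14 points on a circle around the
active raster row: the **leaves re-trim when the beam enters a new row or
layer and stay put within a row**, so same-row spot steps involve no leaf
motion. The trim radius is an energy-dependent base (8 + 0.1·level mm) plus
a per-row component drawn from U(0, 25) mm, standing in for row-to-row
variation of the trimmed cross-section; this makes the summed leaf travel
ΔAA span roughly 10–370 mm, which is what places aperture-move intervals
across the whole 50–1000 ms band. Real leaf-bank mechanics (opposed leaf
pairs, travel limits) are not modelled, and whether "14" counts single
leaves or pairs is unresolved; the leaf count is a config field.

### Deterministic timing model

The inter-pulse time between consecutive pulses is additive:

    ΔT_det = t_base
           + t_spot_per_mm · ΔS
           + t_charge_per_pc · |Δq|
           + [ΔAA > 0] · (t_aa_latency + t_aa_per_mm · ΔAA)
           + [ΔE ≠ 0] · (t_energy_latency + t_plate · plates_moved)
           + t_tx_extra · [low-charge → treatment]
           + t_first_extra · [beam's first transition]

with defaults (ms): t_base = 7, t_spot_per_mm = 1 /mm, t_charge_per_pc = 1
/pC, t_aa_latency = 50, t_aa_per_mm = 2 /mm, t_energy_latency = 900,
t_plate = 120 /plate, t_tx_extra = 400, t_first_extra = 200. The functional
form (fixed latencies plus terms linear in leaf travel and plates moved)
and the constants are this package's own calibration to the machine's
observed regime structure — same-layer pulses below 50 ms, aperture-only
moves within 50–1000 ms, any energy change above 1000 ms — not vendor
values; all are config-exposed. The spot-travel and charge-step terms model
scanning-magnet settling and charge regulation; they are what gives the
short-interval regime internal structure (7–20 ms) for the model and the
attribution analysis to recover, rather than a single constant.

### Noise model

Fraction-to-fraction variability is Gaussian with standard deviation
σ = σ_floor + σ_rel · ΔT_det (defaults 0.5 ms and 8%), plus a rare
exponential outlier (probability 10⁻³ per transition, mean 300 ms), with
the noisy interval truncated below at 0.5 ms. Only the per-interval
magnitude of real inter-fraction error is known (it grows with ΔT); the
generative law here is a design choice producing that qualitative pattern,
with no claim of matching any measured values. Under the defaults ~99.9%
of repeated-delivery intervals fall within ±500 ms of a reference
fraction.

Timestamps are cumulative sums per beam-fraction (first pulse at t = 0),
rounded to 4 decimals (0.1 µs) so CSV round trips are bit-stable. All
randomness flows through explicit integer seeds; a course derives one
sub-seed per fraction from `SeedSequence([seed, k])`.

## 2. Features, target and split

One feature row per transition (a log of N pulses yields N−1 rows; the
first pulse has no predecessor, and `is_first_pulse` flags the transition
out of it, capturing start-up delay). ΔE is carried in energy-level index
units (1 unit = one 2.1 mm step) because the plate model is index-native.
Geometric magnitudes and the target use log1p to compress three decades of
dynamic range. The 70/30 split is stratified over 10 quantile bins of the
log target (bin count is a package default); splitting is by transition
row, not by fraction — a leakage-relevant convention worth noting when
fractions of the same plan appear in both halves, but the intended use
(predicting unseen plans) is tested separately by the held-out-plan
analyses below.

## 3. Regression pipeline

Robust scaling (median / IQR with linear-interpolation quantiles; constant
columns fall back to unit scale; booleans pass through) feeds a
`RandomForestRegressor` on the log target. Hyperparameters are tuned by
randomized search over a documented default space (trees 100–300, depth
8–12, min leaf 2–20, feature fraction 0.4–1.0) with 5-fold CV scored by MAE
in log space, then refit on all training rows. Predictions are mapped back
through expm1 and clamped at zero before any millisecond-scale metric.
Error reporting bins by the *reference* interval into half-open bins
[0, 50), [50, 500), [500, 1000), [1000, ∞) ms; MAPE uses the reference in
the denominator. The expm1 back-transform predicts the conditional median-
like forest output of the log target, which gives a small systematic
underestimate of long intervals — visible in the repainting analysis.

Inter-fraction variability uses the first fraction as reference and
reports per-bin MAE/MAPE of later fractions against it plus the share of
residuals within ±500 ms; residuals of different fractions share the
reference fraction's noise and are therefore correlated.

## 4. Shapley attribution

The value function is **interventional**: f(S) is the mean model output
over a background set with features in S taken from the explained instance
and the rest from each background row. This choice is forced by
consistency — "prediction using only the features in S" is not otherwise
well-defined for a forest — and both computation routes must share it or
they diverge.

- `exact_shapley` enumerates all 2^d coalitions (d ≤ 15) and applies the
  Shapley weights directly; it is the oracle.
- `tree_shap` computes the same quantity in polynomial time: for each
  (instance, background-row) pair and each leaf, the features where the
  two inputs part ways along the leaf's path split into A (instance-side,
  must be in S) and B (background-side, must not be). The Shapley value of
  the resulting indicator game is closed-form — φᵢ = v·(a−1)!b!/(a+b)! for
  i∈A and −v·a!(b−1)!/(a+b)! for i∈B — and summing over leaves, trees and
  background rows gives exact values. The two routes agree to ~1e-15 in
  tests; additivity φ₀ + Σφᵢ = prediction holds per instance.

Attributions are reported in log-target units (the model's native output
space). Default physical groups: aperture {log_daa}, spot {log_ds}, charge
{charge, delta_charge}, energy {delta_e, log_de}, boolean {is_first_pulse,
is_tx_pulse}; the grouping is user-overridable since any published
grouping's exact membership is not available. Global importance is the
mean |φ| over a 100-instance explanation set stratified across target
deciles; per-interval importance is the max |φ| among instances binned by
*predicted* ΔT. The background set defaults to 64 training rows; larger
backgrounds change little but cost linearly.

## 5. Applications

**Cumulative delivery time / repainting.** A volumetric-repainting plan
repeats each beam's treatment-layer sequence k times (default 5), so each
repaint boundary is a lowest-to-highest energy jump. The model — trained
only on non-repainted plans — predicts per-transition ΔT from plan
geometry, and the cumulative sums are compared: the exported statistic is
(predicted − reference)/reference of the total. On the default synthetic
study this deviation is about −2.5%: the boundary jumps are
out-of-distribution (training plans only descend in energy) and the forest
underestimates them, mirroring the underestimation of rare long delays
expected of any log-target tree model extrapolating beyond its training
support.

**Interplay phase mapping.** Each pulse is assigned a phase of a
sinusoidal breathing surrogate by uniform-in-time binning of the cycle:
phase = ⌊n_phases · frac(t/T + φ₀/2π)⌋, with n_phases = 10 (a typical
time-resolved CT binning; the trace amplitude is metadata only). Per-phase
charge maps from model-predicted timestamps are compared with maps from
each logged fraction by total-variation distance and per-pulse label
agreement, for periods 2, 4 and 5 s. The exported pass criterion is that
the mean model-vs-fraction TV does not exceed the largest
fraction-vs-fraction TV (model uncertainty within intrinsic delivery
variability). Dose recalculation (D98/D95/V95, DVHs) requires a dose
engine and 4D imaging and is out of scope; the pipeline stops at
phase-resolved charge distributions. Phase binning by displacement
amplitude rather than time is a possible alternative convention not
currently implemented.

## 6. Study sizes and numerical choices

The default synthetic study uses 4 beams × 10 treatment layers × 64 spots
over 11 fractions (~52k transitions, ~70/30 split) with a 6-candidate
search — sizes chosen so the full pipeline, including attribution, runs in
minutes on one CPU while keeping every ΔT regime populated. The held-out
analyses use separate single-beam plans (distinct seeds and beam
identifiers; a leakage check rejects plans whose beams appear in
training). Charge bookkeeping through phase maps is exact up to float
summation order (verified at 1e-12 relative). Degenerate inputs are
handled explicitly: constant features fall back to unit scale, constant
targets predict the constant, single-pulse records yield an empty feature
table with a warning, and quantile strata collapse (with a warning) when
the target has too few distinct values.

## 7. What the synthetic studies show — and what they do not

The simulator reproduces the *structure* assumed by the analysis: three
timing regimes, heteroscedastic inter-fraction noise, a low-charge prelude
per beam, capped pulse charges, and aperture-dominated mid-range latency
with spot/charge-structured short intervals. Passing the study-level tests
shows the pipeline recovers a known generative process at realistic scale
— it does not validate the timing constants against any real machine, nor
cover vendor log formats (>300 parameters, undocumented), delivery-order
optimisation beyond a serpentine raster, gantry/couch motion, or dose.
Applying the pipeline to real logs requires only a reader producing the
documented pulse-log schema.
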