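# Methods

This note records the statistical model the package implements, the
choices made where the design was genuinely open, and what the tests do
and do not demonstrate.

## Velocity-increment standard

A velocity increment for a pair of scans of the same fetus and biometry
is `v = (Y2 − Y1)/(t2 − t1)` in mm/wk, carried at the mid-interval
gestational age `(t1 + t2)/2`. The published standard models the mean
and SD of `v` as fractional polynomials (FP) of gestational age in the
Royston–Altman convention: powers from {−2, −1, −0.5, 0, 0.5, 1, 2, 3},
power 0 meaning the natural log and a repeated power p contributing
`x^p` and `x^p·ln x`. Mean models use the predictor GA/10; SD models use
bare GA (HC, BPD, OFD: linear) or (GA/10)³ (AC, FL). The predictor
scale is stored per model, never global. Centiles are `mean + z·sd`
under a normal model.

**Validity range.** The charts print 16–38 completed weeks; evaluation
outside that range warns by default (`out_of_range="warn"`), can be
made strict (`"error"`) or silent (`"ignore"`). Gestational ages
outside (0, 45) weeks are always an error — no pregnancy reaches them.

**Centile multipliers.** The seven named centiles use the printed
multipliers ±1.88, ±1.645, ±1.28, 0 exactly rather than the full
normal quantiles (±1.8808…), because the printed charts were computed
with them; any other centile uses the exact normal quantile. Low
centiles that fall below zero near term (HC, OFD C3) are returned as
printed, not clamped: a negative lower envelope simply means a small
measured shrinkage is within measurement noise at that age.

**Chart rounding.** Printed cells are reproduced with a two-stage
half-up rounding: first to 2 decimals, then to the chart's display
precision (2 dp for HC, 1 dp otherwise). The 1-dp charts were evidently
derived from a 2-dp intermediate — 39 of the 805 printed cells sit in
the [x.x45, x.x50) band where single-stage rounding differs, and the
two-stage rule reproduces every cell. All internal computation is
unrounded.

**Peak velocity.** The continuous argmax of the mean model over the
validity range. For the repeated-power-2 family the interior stationary
point is closed-form, `ln s* = −(2b + c)/(2c)` with `s = GA/10`; other
families are scanned for derivative sign changes and refined by
bisection. The week-level statement "peaks at 16 and 17 weeks" is a
reporting convention on top of the continuous argmax and is left to the
caller.

## Pairing policy

Protocol visits every ~5 weeks yield adjacent intervals of 4–6 weeks
and one-skip intervals of 8–12 weeks. The default policy pairs each
scan with the next and the next-but-one (`adjacent_plus_one_skip`) and
keeps intervals in [4, 12] weeks, mirroring the interval census of the
source cohort; `adjacent` and `all_pairs` are available. Duplicate
visits at identical gestational age keep the first scan with a warning:
a zero denominator is a protocol violation, not data. Each pair counts
once in fitting even though fetuses contribute several pairs; no
weighting by interval length is applied (a documented limitation — the
repeated-pairs correlation within fetus is ignored, as it was in the
original construction).

## Chart construction

The mean curve is fitted by exhaustive least squares over all FP2 power
combinations (36 with repetition; FP1 has 8), minimum residual sum of
squares, ties broken by the first model in lexicographic power order.
The SD curve is fitted to scaled absolute residuals: regressing
`sqrt(π/2)·|e|` on gestational age is unbiased for a normal residual
SD. Candidate SD families default to the two published forms (linear in
GA; cubic in GA/10), selected by RSS. Degree selection beyond this is
deliberately out of scope: degree is configuration, defaulting to FP2
means and single-term SDs.

Goodness of fit reports, per completed week (38 = 38+0 to 38+6, bins
with fewer than `min_per_week=20` observations skipped): empirical
order-statistic centiles vs fitted centiles, the proportion of fitted
Z-scores outside each named centile, q-q data of residual Z-scores
against normal quantiles, and the overall mean/SD of fitted Z.

## Conditional velocity

Serial distance-standard Z-scores Z1, Z2 at t1 < t2 with correlation r
give the conditional SD score `cSDS = (Z2 − r·Z1)/√(1 − r²)`, standard
normal when (Z1, Z2) is standard bivariate normal with correlation r.
cSDS > 0 iff Z2 > r·Z1: growth faster than expected *given the first
visit*, which is the correct yardstick under regression to the mean.
One rendering of this formula in print divides by `1 − r²` without the
square root; that form does not have unit variance and fails the
calibration the method relies on, so the square-root form is the
implementation and the literal form is available only behind
`literal_denominator=True`.

The correlation surface is user configuration: the published values
come from a separate two-stage estimation that is out of scope here.
The package ships (a) the exponential family
`r = (1 − nugget)·exp(−(Δt/range)^shape)` — shape 1 exponential, shape
2 Gaussian, nugget absorbing measurement error at zero lag — and (b) a
correlation-table loader with bilinear interpolation between tabulated
(t1, t2) nodes, both restricted to the 14–40-week window. Both paths
are provided because either could stand behind a deployed calculator.

## Synthetic cohort generator

The generator emulates the prescriptive longitudinal design: first
visit in the 14–18-week window (16 ± 1), later visits advancing
5 ± 1 weeks (uniform jitter), clipped into the protocol windows 14–18,
19–23, 24–28, 29–33, 34–38, 39–42 so gaps stay in [4, 6] weeks;
drop-out after the fourth visit with probability 0.4 per remaining
window gives mean ≈ 5 scans (median 5, range 4–6 — six windows admit at
most one scan each). Adjacent observed intervals therefore fall in the
4/5/6 completed-week classes, with 8–12-week intervals arising from
one-skip pairing rather than missed visits.

The generating model is separable in Z-space. Per fetus and biometry,

    Z(t) = z_scale · (τ·α + √(1 − τ²)·G(t)),

with α ~ N(0,1) a fetus-level intercept (τ = between-fetus SD, default
√0.5) and G a zero-mean Gaussian process with Gaussian-shape lag
correlation (range 10 weeks, shape 2). Sizes are

    Y(t) = baseline + ∫ mean_velocity + σ_s(t)·Z(t),

integrated by trapezoid at 0.1-week steps from 14 weeks, plus iid
replicate error per measurement (three masked replicates; the reported
value is their mean).

**Size-scale calibration.** σ_s(t) is solved numerically so that an
adjacent pair at the nominal 5-week gap has increment variance equal to
the published velocity SD² at the pair midpoint: the pair-variance
identity is a quadratic in σ_s(t+5) given σ_s(t), solved by forward
recursion on a 0.1-week grid (the first 5 weeks use the slope-free
solution). The Gaussian correlation shape makes the induced velocity SD
nearly interval-invariant across the 4–6-week jitter range (within a
few percent), which a shape-1 exponential would not. Measurement-error
SDs (HC 2, BPD 1, OFD 1.5, AC 3, FL 1 mm) and 14-week baseline sizes
are **placeholders** of the right order — replicate reproducibility was
not published with the standard — and are configuration, not claims.

**What passing tests show.** Recovery tests demonstrate that the
pipeline refits the published curves from data generated *under the
pipeline's own assumptions* (normal week-specific increments, the
stated visit design). They do not validate the standard against real
ultrasound data, nor the placeholder noise magnitudes. One intrinsic
approximation is documented here: an increment of an integrated smooth
mean curve equals the mid-interval mean plus `M″·Δ²/24`, ≈0.06 mm/wk
for HC near term at Δ = 5 but ≈0.2 at Δ = 10; the median-recovery test
therefore uses the adjacent pairing policy, where the bias is well
inside its ±0.1 mm/wk band, and mixing one-skip pairs into a refit will
bias the late-gestation HC median by up to ~0.1–0.2 mm/wk by design of
the midpoint convention itself.

Reproducibility: one seed drives a `SeedSequence`; per-fetus child
streams are spawned deterministically, so output is byte-identical for
a given (seed, config) and independent of generation order.

## Problem sizes used in verification

Chart reproduction checks all 805 printed cells exactly. The
median-recovery run simulates 5,000 fetuses (~19,700 adjacent pairs per
biometry, close to the ~20,000 measures behind the published charts).
Conditional-score calibration uses 10⁵ bivariate-normal pairs per
correlation in {0, 0.3, 0.6, 0.9} (sample mean within ±0.01, SD within
[0.99, 1.01]). Noiseless self-consistency refits all ten published
equations (five means, five SDs) to powers exactly and coefficients to
1e−6.

## Known limitations

- Distance (size-for-GA) Z-scores are inputs; converting raw mm to Z
  requires the separate size standards, accepted via precomputed
  columns or a user evaluator.
- The published correlation-surface parameters are not shipped; users
  must supply their own table or parameters.
- Estimated fetal weight, dating, outlier cleaning and site effects are
  out of scope.
- The fitter treats pairs as independent observations (see above).
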