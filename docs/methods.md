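# Methods

## The calibration model

An insect's thermal age at adult emergence (its "true k", k_t) is treated
as a random variable correlated with adult body length l. Under the linear
degree-day model, k_t of an individual reared at constant temperature T is
`time × (T − D0)` in ADD (×24 for ADH), with D0 the lower developmental
threshold below which no development accrues.

The calibration line is the reduced major axis (RMA) regression of k_t on l
recovered *without* individual-level data, from three moment
approximations:

1. **sd(k_t) ≈ s_e·√m/2.** The standard error of a species' thermal
   summation constant k, multiplied by √m (m = number of experimental
   temperatures), recovers the spread of individual thermal ages that the
   averaging over temperatures concealed; the factor 1/2 converts the
   resulting range-like quantity to a standard deviation.
2. **sd(l) ≈ √3·(l_max − l_min)/6.** The population sd of lengths that
   cover the species range roughly evenly — the n→∞ limit of the sd of an
   arithmetic sequence over [l_min, l_max] (equivalently the sd of a
   continuous uniform on it). The exact n-point value is
   `w·√((n+1)/(12(n−1)))`, so the relative error of the approximation is
   `√((n+1)/(n−1)) − 1`: 4.88 % for the 21-point half-millimetre grid of a
   10 mm range, below 1 % from 101 points on. The tests assert this error
   law exactly rather than an ad-hoc tolerance.
3. **mean(l) ≈ (l_min + l_max)/2.**

With the RMA slope `sign(r)·sd(y)/sd(x)` and an assumed correlation sign
(negative for necrophagous/predatory species, positive for parasitoids —
an ecological convention, overridable per registry entry), these give

    K_c(l) = k ∓ s_e·√(3m)/(l_max − l_min) · (l − (l_max + l_min)/2).

Invariants maintained (and property-tested): K_c(midpoint) = k; total
spread across the range = s_e·√(3m); linearity in l; exact ×24 scaling
between ADD and ADH; pointwise agreement between `calibrate_k` and the
`CalibrationLine` object.

### Degenerate and boundary inputs

* s_e = 0 degenerates to the constant line y = k (warned, not an error).
* l outside [l_min, l_max] extrapolates with a warning — casework insects
  may slightly exceed literature ranges.
* l_min = l_max is rejected at `SizeRange` construction (the slope would
  divide by zero).

## RMA regression and its loss

`RMA(endog, exog).fit()` computes slope `sign(r)·sd(y)/sd(x)` and intercept
`ȳ − slope·x̄`, with population (divide-by-n) standard deviations — the
convention under which the moment identities above are exact. n ≥ 3 is
required; sd(x) = 0, sd(y) = 0 and r = 0 raise distinct errors (sign(0) is
undefined, and silently picking a sign would corrupt every downstream
quantity). No confidence intervals are computed for the RMA coefficients;
nothing downstream uses them.

The product loss deserves a note. For any line y = bx + a, the pointwise
product of vertical and horizontal residuals is identically
`−(1/b)·(y − bx − a)²`, so all terms share one sign and the *signed* sum is
≤ 0 whenever b > 0 — under the signed definition the RMA fit would be a
maximum there, not a minimum. The geometrically meaningful quantity, twice
the summed area of the residual triangles, is the magnitude of that sum;
`rma_loss` therefore returns the magnitude. It is non-negative, zero for
collinear data, and minimal at the closed-form fit among lines of the same
slope sign — verified against a 100×100 grid-search oracle.

## Thermal-time arithmetic

Degree-day accumulation over a temperature log is rectangular per sampling
interval with clamping at D0 (`Σ max(T_i − D0, 0)·step/24`), not
trapezoidal: the standard linear-threshold convention, and identical to it
at the constant temperatures used everywhere here. Day-based ADD is
canonical; ADH is derived by ×24 so mixed-unit species never double
convert. D0 is a user input; the registry ships defaults only for the two
beetle species with stated thresholds (11.7 °C for *Creophilus
maxillosus*, 8.5 °C for *Necrodes littoralis*).

The thermal summation fitter regresses development rate 1/time on
temperature (k = 1/slope, D0 = −intercept/slope) and propagates the slope's
standard error to k to first order, `s_e(k) = se(slope)/slope²`. This error
propagation is a documented convention of this package's fitter, not a
claim about how any published s_e was obtained. At least three distinct
temperatures are required; a non-positive slope (no thermal response) is an
error.

## Species registry

The registry is a human-editable CSV (mirrored as JSON) rather than code
constants, because users should substitute the size range of the
geographic population closest to their casework. Columns:
`species,family,k,se,unit,m,l_min,l_max,range_source,ecology,corr_sign,d0`.

* **m inversion.** Published calibration lines omit m; it is recovered by
  brute-force search of `s_e·√(3m)/width` against the published slope over
  m ∈ [2, 30]. All eleven shipped species invert with residuals below
  0.07 % of the slope; a residual above 0.5 % warns, and an exact tie
  between two m values is an error rather than a silent choice.
* **Broadest-range rule.** Among candidate ranges the widest is selected
  (it best represents natural size variation); equal widths break toward
  the larger l_max — a convention, flagged with a warning, consistent with
  the shipped selection for *N. littoralis* (15–25 over 12–22).
* **Correlation sign by ecology.** positive iff parasitoid; stored as data
  and overridable, since the ecological rule is an assumption to be tested,
  not a law.
* **The parasitoid intercept.** For *Nasonia vitripennis* the published
  line (8328.49 + 2034.1·l) is internally inconsistent: with a positive
  slope the intercept must be k − slope·midpoint ≈ 1209.1 for the line to
  pass through k on the species' 1.3–2.2 mm range, whereas 8328.49 equals
  k + slope·midpoint. The package computes from first principles, matches
  the published slope magnitude, and keeps the published intercept only as
  a recorded discrepancy — it is never used.

## Validation pipeline

Records are snapped to the nearest 0.5 mm (ties at .25 round half up —
lengths were measured with half-millimetre accuracy, and snapping makes
binning deterministic for synthetic data), grouped into one class per
distinct length, and each class summarized by its median true k; medians
remove the leverage of the heavily unequal class sizes. Three models are
evaluated on the class medians:

* RMA fitted to the medians;
* the K_c line built from (k, s_e, m) and the *dataset's own* minimal and
  maximal lengths;
* the constant line y = k.

MSE over classes is unweighted by class size — weighting would reintroduce
the imbalance the medians were meant to remove. The extreme-size analysis
keeps records strictly below the 33rd / strictly above the 66th length
percentile (linear-interpolation percentiles; realized thresholds are
reported). Per-class squared errors of the three models then enter an
unpaired one-way ANOVA; Fisher's LSD pairwise t-tests use the pooled
within-group mean square and its degrees of freedom, and the three p-values
are Benjamini–Hochberg adjusted. The ANOVA is computed from textbook sums
of squares so the degenerate cases are explicit: zero between-group
variation gives F = 0, p = 1 (identical groups thus yield adjusted p = 1
throughout); zero within-group variation with real differences gives
F = ∞, p = 0. Class-level (not individual-level) squared errors are used
in the extreme-subset ANOVA, consistent with the median-only design of the
pipeline.

## Synthetic data

The generator emulates the two rearing datasets behind the validation:
173 *C. maxillosus* records over 15–24 mm and 954 *N. littoralis* records
over 12–22 mm. Lengths are drawn from a truncated normal centred at the
range midpoint with sd parameter √3·w/6, discretized to the half-mm grid by
exact bin probabilities (normal CDF differences, renormalized over the
range) — reproducing the central concentration that motivated class
medians. A uniform-grid mode exists to exercise the arithmetic-sequence
lemma. True k is the species' K_c line on the dataset range plus Gaussian
residuals; one seed governs both draws.

The residual sd comes from the variance decomposition
`sd_res² = max(0, sd_total² − slope²·sd_len²)` with target marginal sd
`sd_total = s_e·√m/2`. A subtlety: if sd_len were taken as the analytic
√3·w/6, the decomposition would be *identically zero* — the K_c slope is by
construction sd_total divided by exactly that quantity. The generator
instead uses the exact sd of its discretized-truncated-normal length pmf,
which truncation pulls below the analytic value, leaving a strictly
positive residual term (≈19 ADD for the *N. littoralis* emulation, ≈11 ADD
for *C. maxillosus*). If a user-supplied spec makes the decomposition
negative, the residual sd clips to zero with a warning.

What the generator does *not* emulate: sex differences, between-population
variation, temperature-dependent size plasticity, and the true (unknown)
empirical length and residual distributions of the source datasets. Tests
passing on synthetic data therefore demonstrate that the pipeline and the
formula behave as designed under the model's own assumptions — not that
the assumptions hold for any particular field population.

## Problem sizes and stochastic checks

Stochastic properties are checked at the emulated dataset sizes (n = 954
and 173) over 50–100 seeds, plus single larger draws (n = 1e5–2e5) for
moment convergence; the full suite runs in a few seconds. Monte-Carlo
acceptance checks assert frequencies (e.g. both calibrated models beat the
constant k on the extreme subset in ≥ 95 of 100 seeds) rather than exact
values. The similarity of the RMA and K_c errors is operationalized as a
mutual factor ≤ 4 — both sit at the class-median noise floor, whereas the
constant-k error is one to two orders of magnitude above it.

## Known limitations

* The calibration is derived, not empirically fitted; its accuracy
  inherits the quality of the three moment approximations and of the
  literature size range chosen.
* The correlation-sign-by-ecology rule rests on general life-history
  patterns and two beetle datasets; for unstudied taxa it is an assumption.
* Only linear (clamped) thermal accumulation is supported — no curvilinear
  development models, no rate summation beyond the rectangular rule.
* The registry's published-line cross-checks reproduce printed coefficients
  at printed precision; exact reproduction of the original datasets'
  F-statistics and error-reduction percentages is impossible without those
  (undeposited) data and is out of scope.
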