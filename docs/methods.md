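# Methods

This note records the statistical models implemented in `bcivalidate`,
the defaults and why they were chosen, and the limits of what the
synthetic-data tests can show.

## Line-fitting (module `regression`)

Allometry is modelled as M = aL^b, fit on natural logarithms:
ln M = ln a + b ln L. Three estimators are provided.

* **OLS** minimizes vertical squared deviations; slope Sxy/Sxx. Its
  95% CI uses the t distribution on n − 2 df.
* **SMA** (standardized major axis) minimizes the summed triangle
  areas between points and line; slope = sign(r)·sd(y)/sd(x). This is
  the conventional estimator for allometric exponents because both
  variables carry biological variability: the OLS slope attenuates by
  the factor r. The 95% CI is the F-statistic construction
  b·(√(B+1) ± √B), B = F₀.₉₅(1, n−2)(1−r²)/(n−2).
* **MA** (major axis) minimizes orthogonal deviations; slope from the
  first principal axis of the covariance matrix, with Jolicoeur's
  eigenvalue-based CI on the axis angle.

All three report **vertical** residuals y − a − bx. For MA/SMA one
could instead use fitted-axis residuals; vertical residuals were
chosen because residual condition indices are defined as "observed
minus predicted mass", which is a vertical quantity, and because it
puts all residual indices on one scale. This is a genuine open choice
and is isolated in one place (`LineFit.residuals`).

**Common-slope test.** For candidate slope b, the SMA residual scores
u = y − bx and axis scores v = y + bx are uncorrelated within a group
exactly when b is that group's SMA slope. The statistic
−Σᵢ nᵢ ln(1 − r²ᵤᵥ,ᵢ(b)), minimized over b, is twice the
log-likelihood ratio against separate slopes and is referred to χ²
with (groups − 1) df. Measured size at n = 250/group is ≈ 0.05
(calibrated in the acceptance suite).

## Segmented size-class model (module `segmentation`)

A single allometric curve can systematically mis-predict mass at the
extremes of a wide length range, so size classes are defined where the
raw mass–length relationship changes slope. The mean response is
continuous piecewise-linear on the link scale of a GLM with k
breakpoints ψ₁ < … < ψ_k:

η(x) = β₀ + β₁x + Σⱼ γⱼ(x − ψⱼ)₊

Two families are exposed: gaussian with identity link, and gamma with
the negative inverse link η = −1/μ (variance ∝ μ², the natural choice
for strictly positive right-skewed masses; the negative sign keeps η
increasing in μ).

**Estimation** is by iterative linearization: augment the design with
hinge terms (x − ψ)₊ and indicator terms −1(x > ψ), refit, update
ψ ← ψ + γ̂/β̂. Iterations stop when the largest breakpoint move falls
below 10⁻⁴ cm or the segmented deviance is stationary; proposals are
step-halved if they leave the data range or worsen the deviance.
Breakpoints start at interior quantiles; one perturbed restart is
attempted before a fit is flagged non-converged. Breakpoint standard
errors use the delta method SE(ψ̂) = SE(γ̂)/|β̂| on the final
linearized fit.

**Model size selection.** Candidates k = 0…k_max (default 10) are
compared by BIC = −2ℓ + p·ln n with p = 2k + 3 (intercept, base
slope, k slope changes, k breakpoints, dispersion). Two refinements
matter in practice:

* *Significance guard.* A candidate is admissible only if every slope
  change is significant at the Bonferroni-corrected level α/k
  (α = 0.05). Under the gaussian family the Wald test uses an HC1
  sandwich covariance, so a slope change supported only by a
  high-variance stretch of the data (large animals, under
  multiplicative noise) does not count as evidence. Without the
  guard, pure minimum-BIC selection plants a spurious extra breakpoint
  in the high-variance region in roughly 13% of simulated datasets;
  with it, the correct k = 2 is selected in ≈ 96% and the breakpoint
  means are essentially unbiased. `guard_alpha=None` restores pure
  minimum-BIC selection.
* *Estimated-breakpoint df.* Each slope-change Wald statistic is
  referred to χ² with 2 df rather than 1, counting the estimated
  breakpoint location — a nuisance parameter that exists only under
  the alternative. The naive 1-df test rejects a straight-line null
  ~21% of the time at nominal 5%; the 2-df reference brings this to
  ~8.5%.

Exact BIC ties break toward fewer breakpoints. Size classes are the
half-open intervals [ψⱼ₋₁, ψⱼ): a length exactly at a breakpoint
belongs to the class above it.

## Condition indices (module `condition_indices`)

Definitions are in the README. Numerical conventions:

* Natural logarithms throughout.
* Predicted mass prM = exp(a + b ln L) with **no** smearing/bias
  correction — the index is defined through the fitted line, not an
  unbiased mean predictor.
* Under by-size-class grouping, *every* regression-derived quantity
  (prM, all residual indices, the SMI exponent and its reference
  length L₀, scaled and residual fat) is refit within each class,
  using that class's mean SVL as L₀. Ratio indices are
  group-independent. Consequence: SMI and the SMA residual index are
  perfectly rank-correlated within any group (ln SMI = SMAres +
  constant), which the tests assert.
* Zero-fat animals must be removed before the ln-based fat measures;
  the functions raise if one slips through.

## Diagnostics (module `diagnostics`)

RESET uses powers {2, 3} of the fitted values (the conventional
default) with an F reference on (2, n−4) df. Breusch–Pagan is the
studentized (Koenker) LM = n·r² variant, robust to non-normality.
Shapiro–Wilk is restricted to 3 ≤ n ≤ 5000; D'Agostino skewness
requires n ≥ 9 and Anscombe–Glynn kurtosis n ≥ 20. Kendall's τ is the
tie-corrected τ-b, with exact enumeration when n ≤ 8 and tie-free;
Mann–Whitney uses the continuity- and tie-corrected normal
approximation, exact when both samples have n ≤ 8 without ties. All
tests are two-sided at α = 0.05, with no multiple-testing correction
across the battery (each cell is reported, not aggregated).

In the assumption battery, RESET and Breusch–Pagan are computed only
for variable pairs with a vertical-error regression (the OLS ln–ln row
and the mass-on-length-cubed pair); MA/SMA rows carry NaN there, since
those tests are defined through an OLS auxiliary regression. Skewness
and kurtosis tests are always computed but flagged as conditional —
they are conventionally consulted only when normality is rejected.

## Cleaning and validation (module `pipeline`)

Exclusion rules are applied in a fixed order so per-rule counts are
reproducible: incomplete necropsy → unknown sex → physical abnormality
→ held more than `max_days` (default 4; a record held exactly 4 days
is retained) → wet-fat mass exactly 0 (not ln-transformable). A record
is counted once, under the first rule it matches.

Validation regresses each **BCI on** each fat measure and on SVL (the
index is the response), reporting Kendall's τ with p and OLS adjusted
r² with the slope's two-sided p. Percent fat is the designated
reference measure — it is the least length-entangled of the three —
but all three are always reported, together with a bias block
regressing each fat measure on ln SVL. The ranking orders indices by
adjusted r² against percent fat and flags an index as size-biased when
its τ against SVL has p < 0.05; size-biased indices are flagged, not
excluded, since the tradeoff is a judgement call.

## Synthetic data (module `synthetic_data`)

The generator emulates a necropsy intake stream of a large lizard:

* **Lengths**: ln-SVL Gaussian (mean ln 24.65 cm, sd 0.22) truncated
  by rejection to [10.0, 46.4] cm, rounded to 0.1 cm. The sd gives an
  SVL spread of ≈ 5.4 cm, and is small enough that truncation distorts
  the nominal ln-sd by < 1%, so generated moments can be compared to
  nominal parameters directly. The ln-normal shape itself is a
  modelling choice, not an empirical fact.
* **Mass, moment model** (default): ln-mass jointly Gaussian with
  ln-length, parameterized by the sd ratio (3.13) and correlation
  (0.995) — the parameterization under which the sample SMA slope is a
  consistent estimator of the configured slope. A vertical-noise
  model would inflate the SMA estimand by 1/|r|. The conditional draw
  uses the realized sample moments of ln-length, so the targeted sd
  ratio holds in-sample. Mean ln-mass 6.0 puts the mean body mass
  near 550 g. Rounded to 1 g.
* **Mass, segmented model**: mean mass continuous piecewise-linear in
  SVL with breakpoints (20.2, 30.0) cm and slopes (30, 90, 180) g/cm,
  anchored so the mean at 17 cm is 158.2 g (a juvenile-group centre);
  multiplicative log-normal noise with CV 0.10. With that anchor the
  first segment extrapolates through zero near 11.7 cm, so the mean is
  floored at 1 g; the floor's kink is far below the fit's noise floor
  (Δlog-likelihood ≈ 0.4 against a BIC penalty of 13.6 at n = 883)
  and moves the noiseless breakpoint estimate by only ~0.14 cm.
* **Fat**: ln-fat jointly Gaussian with ln-length, sd ratio 6.91,
  correlation √0.37, mean ln-fat 0.6 at the mean length (median
  ≈ 1.8 g, mean ≈ 9 g — coelomic stores of order 1–2% of body mass).
  Optional per-sex slope offsets (+0.47 female, −0.36 male) make the
  female fat allometry steeper, with the mass allometry deliberately
  sex-free. With probability `zero_fat_prob` (default 0.02) fat is
  exactly 0 — exercising the cleaning rule — and fat is capped below
  body mass after rounding to 0.0001 g.
* **Flags and days held**: independent Bernoulli flags (default 1%
  each for incomplete necropsy, abnormality, unknown sex; an
  unknown-sex flag also sets the sex to unknown) and uniform days held
  on 0–8, so that the >4-day rule dominates exclusions, as it does in
  real intake streams.

Everything is driven by one integer seed through split child
generators, so a configuration reproduces its dataset byte-for-byte.

**What passing tests do and do not show.** The generator draws
log-normal, independent records with exactly the assumed mean
structures; it has no seasonal fat cycles, no month or year
covariates, no measurement error beyond rounding, and no correlation
between flags and morphometrics. Parameter-recovery results therefore
validate the *estimators* (they recover the truth when the model
holds), not the indices' biological performance on real populations —
which is exactly the question a validation study must answer with its
own data.

## Problem sizes used in the shipped experiments

The recovery experiments use 200 replicates of n = 883 animals (the
slope recoveries take seconds; the 200-fold breakpoint-selection
experiment ~20 s on one CPU). Test-battery calibration uses 2000 null
replicates at n = 500 per test. These sizes put Monte-Carlo error
comfortably inside the asserted tolerances (e.g. the sd of a mean
slope over 200 replicates of n = 883 is ≈ 0.0004 against a 1%
tolerance of 0.03).

## Known limitations

* Breakpoint SEs come from the delta method on the final linearized
  fit and are mildly optimistic near weakly identified breakpoints.
* The gamma/negative-inverse family models the *linear predictor* as
  piecewise-linear; if the raw-scale mean is piecewise-linear, the
  link's curvature within segments will be absorbed by extra
  breakpoints. Use the gaussian family when the identity-scale mean is
  the object of interest.
* The common-slope test assumes bivariate normality within groups and
  a common slope sign.
* `read_records` preserves unknown CSV columns as opaque strings; no
  unit inference is attempted.
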