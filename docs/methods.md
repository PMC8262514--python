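# Methods

## The measurement problem

A single 24-h recall or food record measures one day of intake, which is
the person's usual intake plus a large day-to-day deviation. The population
distribution of single-day intakes is therefore wider than the distribution
of usual intakes, and any tail statistic computed from it — above all the
prevalence of intake below the Estimated Average Requirement (EAR) — is
biased away from 0.5. Removing the day-to-day (within-individual) variance
requires knowing what fraction of the observed variance it accounts for:
the WIV:total ratio β, or equivalently WIV:BIV α = β/(1−β). With repeat
days the ratio is estimable from the data (the 2-d workflow); with one day
per person it must be assumed from external sources (the 1-d workflow), and
the package treats that assumption as the object of a sensitivity analysis
rather than a fixed input.

## Model and estimation

Transformed intakes follow a linear mixed model: fixed effects for recall
sequence (categorical, first recall as reference) and an optional weekend
indicator, a subject random intercept with variance s_b², and independent
day residuals with variance s_w². Estimation is REML. The implementation
first fits `statsmodels` `MixedLM`, then polishes the estimate by profiling
the REML criterion down to the single free parameter ψ = s_b²/s_w² (block-
diagonal covariance makes the GLS fixed effects and the residual variance
closed-form given ψ) and maximizing that scalar function to ~1e-12. The
polish exists because general-purpose optimizers stop at ~1e-5 relative
accuracy, which is visible when comparing against closed-form estimators.

REML constrains s_b² ≥ 0; an estimate at the boundary is reported as 0 with
a `boundary` flag. The classical one-way method-of-moments (ANOVA)
estimator is provided as `method="anova"`: it is unbounded below, so a
sample can legitimately report s_b² < 0 and hence β > 1. Such values are
propagated and flagged `implausible`, never truncated — silently clipping
them would hide exactly the artifact that motivates plausibility screening
of published ratios (the default screen is α > 10, i.e. β > 10/11 ≈ 0.91,
configurable).

Survey weights: the default decomposition is unweighted. The single-day
total-variance path accepts weights (weighted least squares on the fixed
effects, weighted residual variance), which is the path BRR replication
reweights. A weighted REML was deliberately not attempted: `MixedLM` has no
sampling-weight support, and design-based uncertainty is handled by
replication instead.

## Box-Cox selection

The transformation family is g(x) = ((x+c)^λ − 1)/λ (log at λ = 0) with a
shift c ≥ 0 defaulting to half the smallest positive intake when zeros
occur. λ is selected on the grid −2…2 in steps of 0.05, refined once at
0.01 resolution around the best candidate, by maximizing the Shapiro–Wilk
statistic of the model residuals refitted at each candidate.

Two residual sets are available. The default scores the *marginal*
residuals (person effect + day deviation, both normal under the model),
computed by least squares on the fixed effects. The *conditional*
(within-subject) set is also offered, but it identifies λ only through the
day-to-day spread — after within-subject demeaning of a 2-day design its
variance is s_w²/2 — and in simulation it recovers a generative λ = 1 in
only a minority of replicates at realistic dietary coefficients of
variation, versus ~19/20 for the marginal set. The chosen set and the
search trace are stored in the fitted `TransformSpec`, so every run is
self-describing. The fast scoring path (OLS + demeaning) coincides with the
REML conditional residuals on balanced designs; a full REML-per-candidate
engine exists for audit.

Shapiro–Wilk is evaluated on at most 5,000 residuals (a fixed-seed
subsample beyond that), since the statistic's implementation degrades for
larger n and the objective only ranks candidates.

## Back-transformation and the usual-intake distribution

A person's usual intake on the transformed scale is mu + b; mapping it back
must account for the day-level noise that re-enters through the curvature
of g⁻¹. The package applies the second-order Taylor correction

    BT(y) = g⁻¹(y) + ½ · s_w² · (g⁻¹)″(y),

the standard device in usual-intake macros. For λ = 1 the correction
vanishes identically; for λ < 1 (convex inverse, including log) it is
nonnegative. The distribution is represented as a deterministic percentile
grid: BT evaluated at mu + s_b·z_p for p = (k−0.5)/G, equal masses 1/G,
G = 400 by default (the mean is stable to ~0.1% between G = 100 and 1000).
A deterministic grid keeps downstream prevalence free of Monte-Carlo noise.
Grid points outside the inverse domain are clamped to the boundary, counted
in the distribution's metadata, and warned about; for λ < 0 the upper
boundary is +∞, in which case clamped points are capped at the largest
finite grid value. When a weekend coefficient is present, the per-person
usual value uses the 5/7 weekday + 2/7 weekend mixture on the transformed
scale (equivalently mu + 2/7·w).

The external-ratio split s_w² = β·s², s_b² = (1−β)·s² is exact arithmetic.
β = 1 is refused (the distribution would collapse to a point), and the
sensitivity grid rejects any assumed value ≥ 0.995, since the model loses
validity as the ratio approaches 1; the default grid is 0.05…0.95 in steps
of 0.05 plus 0.99.

## Prevalence and its flags

The EAR cut-point prevalence is the grid mass strictly below the EAR. The
method is known to be reliable only when the true prevalence is neither
very low nor very high; estimates below 10% or above 90% carry soft flags
(`near_zero_bound`, `near_one_bound`) and those outside 8–92% additionally
carry `outside_cutpoint_validity`. A built-in registry ships EARs for
dietary folate (320 µg/d, IOM), vitamin A (500 µg RAE/d, IOM) and zinc
(6 mg/d, IZiNCG, mixed/refined vegetarian diet); any run can override them.
When the external ratio is uncertain, the `SensitivityCurve` exposes the
min–max prevalence over the tested grid, which is the honest summary to
report.

## Balanced repeated replication

For stratified designs with exactly two clusters per stratum, replicate r
keeps one half-sample at weight (2−fay) and the complement at fay, with
half-sample membership following the columns of a Hadamard matrix;
SE² = (1/(R(1−fay)²))·Σ(θ_r − θ)². Defaults are 48 replicates and
fay = 0.7. Hadamard matrices are built by the Sylvester construction
(powers of two), the Paley type-I construction (order q+1 for primes
q ≡ 3 mod 4 — this covers 48), and doubling; an infeasible requested order
is rounded up to the nearest constructible one with a warning. By default
the replicated statistic re-runs the full weighted 1-d pipeline (variance
estimation through prevalence) inside every replicate; replicating only the
final step would understate the variance contributed by estimation.

Calibration was checked against a Monte-Carlo oracle: on a 24-strata ×
2-cluster design the *mean* BRR SE over 30 independent survey realizations
is compared with the empirical SD of the estimator over several hundred
realizations. A single dataset's BRR SE has ≈ (2H)⁻¹ᐟ² ≈ 14% relative noise
by construction, so averaging across realizations is what makes a 20%
comparison informative rather than a coin flip.

## The synthetic-data generator

`simulate.generate` draws from exactly the model the estimators assume:
transformed-scale person effects and day residuals, additive weekend
(Bernoulli 2/7 unless scheduled) and recall-sequence shifts, exact inverse
transformation at the generative λ. Draws whose transformed value leaves
the inverse domain are resampled (counted; >1% aborts with advice to fix
the configuration). Default parameters emulate a two-recall micronutrient
survey: 500 subjects × 2 days, log-scale truth with s_b² = 0.25 and
s_w² = 0.5 (β = 2/3, total CV ≈ 0.4 on the original scale). The survey
design option assigns subjects evenly to strata, splits each stratum's
subjects equally between 2 clusters, attaches weights that are a fixed
deterministic pattern in (stratum, cluster) — so replication SEs are
design-conditional, not weight-draw-conditional — and can tilt intakes by a
lognormal cluster effect. A subsample mode gives everyone day 1 and a
random fraction day 2, mimicking repeat-on-subsample designs. Every dataset
carries a truth sidecar (JSON) with the generating parameters and derived
β, so tests never re-derive truth by hand.

What the generator does *not* emulate — and therefore what passing tests do
not establish about real data: reporting error in the recalls themselves
(energy under-reporting), intake-amount correlation with probability of
consumption (nutrients are assumed consumed daily), heteroscedastic day
variance across the usual-intake range, seasonality beyond a group label,
and informative sampling. An AR(1) day-correlation knob exists to emulate
consecutive-day designs, which depress the apparent within-individual
variance; it defaults to 0 (nonconsecutive days).

## Numerical choices and problem sizes

- Ratio conversions are exact algebra; β = 1 → α raises an explicit
  infinite-alpha error; conversions to CV ratios are refused because means
  are not recoverable from variances.
- REML boundary detection: ψ < 1e-8 with no criterion improvement over
  ψ = 0 is reported as exactly 0.
- Simulation-based tests use 500 subjects × 2 days (≈ the size of the
  motivating surveys' subgroup analyses) with 5–20 seeds per claim; BRR
  calibration uses 300–500 Monte-Carlo survey realizations of 240 subjects.
  These sizes put estimator noise well inside the asserted tolerances while
  keeping the full suite under a minute of compute.
- The BRR SE-versus-β trend test pins the EAR near the population median:
  the trend of increasing SE with increasing assumed ratio holds while the
  prevalence is informative, and reverses mechanically once the prevalence
  saturates toward 0 or 1 (the estimator flatlines), which is also visible
  in real-data analyses at extreme ratios.

## Known limitations

- Only the one-random-intercept model is supported; no two-part
  (probability × amount) model for episodically consumed foods, and no
  multivariate (nutrient-correlated) modeling.
- The weighted decomposition path is method-of-moments/WLS, not weighted
  REML.
- The Taylor back-transformation is second-order; alternative devices
  (higher-order or 9-point approximations) would change extreme-percentile
  behavior slightly. The operation is isolated so a variant can be swapped
  in one place.
- BRR requires exactly two clusters per stratum; other designs need a
  different replication scheme (not provided).
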