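# Methods

## The estimand and the two analyses

A composite responder endpoint declares a patient a responder when a
continuous measurement y passes a threshold τ (direction `at_least` or
`at_most`, inclusive at τ) AND a binary criterion b is met.  Both analyses
in this package target the same estimand — the per-arm probability of
response, its between-arm difference and log odds ratio — and use the same
rule; they differ only in how the probability is estimated.

**Binary comparator.**  Patients are classified by the rule; any needed
component missing ⇒ *undetermined* and excluded (with a logged count).
Per-arm proportions, Wald SE for the difference, `sqrt(Σ 1/cell)` SE for the
log OR from the 2×2 table, with an optional 0.5 continuity correction when
a cell is zero.

**Augmented analysis.**  A six-parameter joint model is fitted by maximum
likelihood:

    y | z    ~  N(α + θz, σ²),          z ∈ {0,1} arm indicator
    b | y, z ~  Bernoulli(expit(γ₀ + γ₁z + γ₂y))

The logistic dependence of b on (z, y) is the simplest structure that makes
the components non-independent; γ₂ can be fixed at 0 (config
`gamma2_free: false`), in which case the likelihood separates into a pure
normal and a pure logistic part and the joint MLE coincides with the
standalone fits (a tested invariant).  The response probability

    p(z) = ∫_region N(y; α+θz, σ²) · expit(γ₀+γ₁z+γ₂y) dy

is evaluated at the MLE by adaptive quadrature (absolute tolerance 1e-8;
the standardised integrand is clipped to |u| ≤ 10 where the neglected tail
mass is < 1e-23).  The threshold τ enters only here — never the likelihood —
so the fit is identical under any rule.

**Inference.**  SEs come from the delta method: central-difference gradients
(relative step 1e-5) of (logit p₀, logit p₁, p₁−p₀, log OR) with respect to
the six parameters, propagated through the inverse observed information.
CI scales: logit for the per-arm probabilities (back-transformed), identity
for the difference, log for the OR — bounded-parameter coverage without
bespoke transforms.  The primary test is the two-sided Wald z-test on the
difference; no multiplicity adjustment (single primary contrast).

## Missing data

Missingness is assumed **ignorable given arm and the observed components**
(missing at random).  This is a real assumption and it is not testable from
the data: a missing b contributes only the normal term; a missing y
contributes the Bernoulli probability marginalised over the normal law of y
(40-node Gauss–Hermite); a fully missing record contributes nothing.  The
augmented analysis therefore retains subjects the binary analysis must
drop — one of the method's practical advantages — but if missingness is
informative both analyses are biased, the augmented one included.

## Response weights

The fitted model grades each patient by a response weight in [0, 1],
smooth in the distance of y to the threshold with the fitted residual SD as
the smoothing scale: w = Φ((y−τ)/σ̂) for `at_least` rules (mirrored for
`at_most`).  Default variant **gated**: the observed b is a hard gate
(b = 0 ⇒ w = 0), so the weight softens only the dichotomisation, not the
observed binary criterion.  Variant **model_based** replaces the gate by the
fitted logistic probability, w = Φ(·)·expit(γ̂₀+γ̂₁z+γ̂₂y), which also damps
misclassification in b.  Missing components are replaced by the model-based
predictive probability of response given what is observed (an observed
b = 0 forces w = 0 in both variants, since response requires b = 1).  The
smoothing-scale choice makes a measurement error near the threshold move
the weight slightly instead of flipping a 0/1 classification.

## Fitting: numerical choices

* Optimisation: BFGS on (α, θ, log σ, γ₀, γ₁[, γ₂]) with numeric gradients,
  gradient tolerance 1e-8, from deterministic moment-based starts (per-arm
  means and pooled residual SD; logit of the overall b̄ for γ₀; 0 for
  γ₁, γ₂).  No randomness: fits are bit-reproducible.
* Covariance: central-difference Hessian of the negative log-likelihood in
  the **natural** parameters at the MLE, relative step 1e-4 per coordinate
  (a step small enough for first differences is noise-dominated in second
  differences in double precision), symmetrised as (H+Hᵀ)/2 before
  inversion.  A singular or indefinite information raises with the advice to
  fix γ₂ = 0.
* Separation: if every observed b is identical, or a fitted |γ| exceeds 12
  on the logit scale, the fit returns `converged=False` with a diagnostic
  instead of pretending the logistic sub-model is estimable.
* Box-Cox: profile log-likelihood over λ ∈ [−3, 3] in steps of 0.01 with the
  Jacobian term (λ−1)Σlog y; residuals are taken about per-arm means so a
  treatment shift is not mistaken for skew.  `boxcox: auto` transforms y and
  τ with the estimated λ (the transform is increasing, so the responder set
  is unchanged); τ must be positive on the original scale.

## Synthetic-trial generator and default scenarios

`simulate_trial` draws from exactly the model above — normal y with arm
shift, logistic b given (z, y), independent component-wise missingness —
seeded by (scenario seed, replicate index) for bit-reproducibility.

Default **effect scenario**: α = 0, θ = 0.4, σ = 1, γ₀ = 2, γ₁ = 0,
γ₂ = 0.5, responder = (y ≥ 0 AND b = 1), n = 100/arm.  A 0.4 SD shift is a
moderate, realistic treatment effect; the threshold at the control median is
the *most favourable* cut for the binary analysis (the dichotomisation cost
is minimised at p = 0.5), so efficiency gains measured here are
conservative; γ₀ = 2 makes the binary criterion met for ~88% of patients,
typical of secondary safety-style criteria; γ₁ = 0 routes the whole
treatment effect through the continuous component.  The **null scenario**
sets θ = γ₁ = 0.  The **single-endpoint scenario** fixes the binary
criterion as always met (γ₀ = 30), reducing the composite to a pure
median-dichotomised endpoint.

What the generator does **not** emulate: non-normal y (other than via the
inverse Box-Cox in the skewed fixture), informative missingness,
baseline covariates, longitudinal measurement, or more than two components.
Passing simulations therefore certify the method under its own assumptions;
they do not certify robustness to violations of them.

## Power, ESS and the analytic dichotomisation cost

`run_power_study` analyses each simulated trial with every method (common
random numbers by construction) and reports rejection rates (two-sided Wald
at α), MC standard errors sqrt(r(1−r)/n_completed), mean CI width, mean
difference, and coverage of the true difference (computed by quadrature
from the true parameters).  Replicates whose fit fails count as
non-rejections (conservative) and are excluded from the width/coverage
means; the failure count is reported, with a warning above 10%.

`effective_sample_size_gain` finds the n at which the reference method's
power matches the target method's power at the scenario n: every replicate
is simulated once at 10n per arm and each evaluation uses the first n
subjects of each arm, so the power-vs-n curve is computed on nested datasets
(common random numbers across n as well as across methods); integer
bisection to unit resolution, then linear interpolation between the
bracketing powers.  The target power must lie in (0.2, 0.95) for a stable
match.  Gain = 100·(n_matched/n − 1).

The closed-form counterpart: under a local shift of a normal endpoint, a
proportions test on the cut at the quantile with response fraction p needs
p(1−p)/φ(Φ⁻¹(p))² times the t-test's sample size — π/2 at the median, the
minimum over p, and our simulated single-endpoint gain reproduces it within
Monte-Carlo error (a tested invariant).

## Problem sizes used by the shipped experiments

The statistical test suite and the acceptance script use 500 replicates for
the effect-scenario experiments and 1000 for the null-scenario type-I /
coverage checks, at n = 100 per arm (parameter recovery at n = 2000/arm) —
desk-scale study sizes chosen so the full suite runs in a few minutes while
keeping MC standard errors below ~1.6 percentage points on a rejection
rate.  Claims inherited from larger published simulation studies are
verified as inequalities (e.g. ESS gain ≥ 30%), not as point values.

## Known limitations

* Single timepoint, two arms, one continuous + one binary component; m-of-k
  responder definitions (e.g. ACR20's "three of five") are rejected at rule
  construction.
* Wald-type inference: in very small samples or with response probabilities
  near 0/1 the delta-method CIs can undercover; the suite checks calibration
  at n = 100/arm.
* The normality assumption matters; the Box-Cox option corrects monotone
  skew only.
* Intercurrent-event style binary components ("no rescue therapy") are
  treated as ordinary binary criteria, which is a choice, not a neutrality.
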