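# Methods

## Model

`genspm` implements a discrete-time stochastic process model of aging in
which a physiological variable and mortality are modeled jointly, with every
coefficient indexed by a binary genotype `G` (1 = noncarrier of a risk
allele, 0 = carrier) and `P(G = 1) = p1`.

**Dynamics.** On a one-year age grid,

    Y(t+1) = Y(t) + a(t,G) (Y(t) - f1(t,G)) + sigma1(G) Z_t,     Z_t ~ N(0,1)
    Y(t0)  ~ N(f1(t0,G), sigma0(G)^2)

with the quadratic mean allostatic trajectory
`f1(t,G) = a_f1 + b_f1 t + c_f1 t^2` and the linear feedback
`a(t,G) = a_Y + b_Y t`, `a_Y < 0`, `b_Y >= 0`. `|a(t,G)|` is the adaptive
capacity; the one-year step is the Euler discretization of the underlying
mean-reverting diffusion and is used identically by the simulator and the
likelihood, so estimation is exactly matched to the generative law.

**Mortality.** Conditional on the variable,

    mu(t, Y, G) = mu0(t,G) + (Y - f(t,G))^2 mu1(t,G)

where `mu0` is gamma-Gompertz (logistic),
`mu0 = a e^{bt} / (1 + sigma2^2 (a/b)(e^{bt} - 1))` with `a = exp(ln_a_mu0)`
and the frailty integral taken from age 0 as the formula is written;
`mu1(t,G) = max(0, a_mu1 + b_mu1 t)` is the U-shape sensitivity. The clamp
is needed because several published coefficient pairs make the fitted line
negative at some ages while the model requires a nonnegative multiplier; the
unclamped line is what the optimizer sees, the clamp is applied at
evaluation. Death within the year `[t, t+1)` occurs with probability
`1 - exp(-mu(t, Y(t)))`: `mu` is a rate, not a probability, and this form is
valid at any hazard level.

**Optimal trajectory `f(t,G)`.** Operationally a cubic polynomial fitted by
unweighted OLS to 5-year-bin average trajectories (bins 40–44 … 85–89, 90+,
represented by midpoints 42.5 … 87.5 and 92.5) of long-lived subjects —
women who survived to 90, men to 85. Averages pool person-exams; bin
membership floors the exam age. Censored subjects count only toward the
long-lived group: a censoring age below the threshold says nothing about
eventual life span, so such subjects get no group. Cubics are trusted only
on the fitted bin-midpoint range; outside it evaluation clamps to the
boundary value, because cubic extrapolation diverges quickly. Where no
empirical fit is wanted (simulation studies), the default `f` is the
allostatic quadratic expressed as a degenerate cubic.

## Likelihood

For a subject with known genotype the log-likelihood is the sum of three
blocks, mirroring the generative law exactly:

1. **Initial term** — the first measurement is `N(f1(t_first), sigma0^2)`.
2. **Transition terms** — between consecutive measurement occasions the
   Gaussian transition obtained by composing the one-year mean/variance
   recursions `m <- m + a(t)(m - f1(t))`, `v <- (1+a(t))^2 v + sigma1^2`
   across the gap. Interpolated annual values carry no density of their own
   (they are deterministic functions of the measurements), so only actual
   exams contribute here.
3. **Survival terms** — each survived year contributes `-mu(t, Yhat(t))`
   with `Yhat` the measurement series linearly interpolated onto integer
   ages; the final year contributes `log(1 - exp(-mu))` for a death and
   `-mu` for censoring. Between the last measurement and the event the last
   value is carried forward, never more than the two-year censoring lag,
   which the censoring rule itself guarantees.

Known-genotype subjects add the Bernoulli factor `log p1` or `log(1 - p1)`;
unknown-genotype subjects contribute
`log(p1 e^{ll_1} + (1 - p1) e^{ll_0})` evaluated via `logaddexp`, stable far
below `exp(-700)`. Genotype missingness that depends on survival to the
genotyping age is ignorable here because survival is part of the observed
data: the joint fit corrects the survivor-enriched genotyped fraction, which
is why `p1` is recovered even though the naive carrier share among the
genotyped is biased.

The plug-in of interpolated values into the hazard (rather than integrating
the latent process between exams) is the one deliberate approximation; with
biennial exams its effect is confined to hazard-block terms in off-exam
years and was not detectable against the Monte-Carlo noise of the recovery
experiments.

Left truncation at study entry is not modeled: the likelihood conditions on
entry through the initial term, matching the generator, which starts every
subject at its entry exam.

## Estimation

Optimization maximizes the total log-likelihood on a transformed scale —
log for `sigma0`, `sigma1`; softplus with a floor at zero for `sigma2`
(boundary estimates at `sigma2 = 0` are routine and must not crash); logit
for `p1`; identity otherwise — with per-coordinate rescaling by
characteristic magnitudes so the numerically differentiated L-BFGS-B search
is well conditioned across ten orders of magnitude. Box constraints keep
`a_Y < 0` and `b_Y >= 0` (making "no decline in adaptive capacity" a
boundary null). Defaults: relative function tolerance 1e-10, finite
difference step 1e-6 in scaled units, at most 400 iterations, optional
multistart with jittered initial points. Method-of-moments starting values
are available: pooled quadratic fit for `f1`, first-measurement spread for
`sigma0`, increment regression for `a_Y` and `sigma1`, a plain Gompertz
survival fit for the baseline, genotyped fraction for `p1`.

Restricted fits for likelihood-ratio tests reuse the same machinery with
carrier parameters tied to noncarrier ones and/or parameters fixed at zero;
degrees of freedom equal the plain free-parameter count of the restriction
(3 for baseline equality including `sigma2`, 2 for feedback equality, 3 for
allostatic equality, 2/1/1 for the per-stratum zeroing nulls). For the
boundary null `b_Y = 0` both the naive chi-square(1) p-value and the 50:50
chi-bar-square mixture are reported, the naive one as the headline number.

## Synthetic cohorts

The generator emulates a long-running biennial-exam study: integer entry
ages uniform on 40–50 by default, exams every two years while alive, the
enrollment exam always measured and each later exam independently missed
with probability 0.1 (the attendance process of real cohorts is not
modeled; this is a design knob, not an estimate), latent dynamics and yearly
mortality exactly as above, follow-up to age 110. Genotype is revealed only
for survivors to age 78 (thinned to 50%), reproducing DNA collection at a
late exam; a flag switches to completely-at-random missingness for null
studies. Anyone whose death falls more than two years after their last
measurement is censored at last measurement + 2; survivors are censored at
last measurement + 2, capped at the maximum age. Sex is a stratification
label only — parameter sets are fully sex-specific and never shared.

What the generator deliberately does not reproduce: measurement error on
top of the latent process, exam attendance correlated with health,
competing risks, cohort/period effects, and covariates beyond the single
physiological variable. Passing recovery tests therefore demonstrate
internal consistency of estimator and generative law under the stated
design, not robustness to those real-data features.

The bundled reference parameter sets (cholesterol and diastolic blood
pressure, by sex and carrier status, estimated on the Framingham original
cohort) are stored on the display scale of the published tables — `a_mu1`
x1e4, `b_mu1` x1e5, `b_Y` x1e3 — and converted to the natural scale at load
time by a dedicated converter, preventing silent scale bugs.

## Numerical and design notes

- Parameter validation requires the feedback to stay negative on a
  configurable span with default upper bound 95 years: some published
  cholesterol coefficient pairs cross zero near 95, an age range whose
  survivorship is negligible under the same parameter sets; the simulator
  tolerates the crossing beyond the validated span.
- `sigma2`'s softplus floor is 1e-12, so transform round trips on sets with
  `sigma2` printed as 0.00 are exact to 1e-12.
- Measurement ages are rounded to integer years when the likelihood is
  assembled; sub-year exam offsets are not modeled.
- Ages use half-open annual intervals `[t, t+1)` for hazard terms; a death
  in that interval is recorded at `t + 1`.
- All artifacts (simulated cohorts, fit tables, test batteries, reports)
  are timestamp-free and seed-deterministic; reruns are byte-identical.

## Validation experiments and their sizes

The test suite regenerates everything programmatically; there are no stored
fixtures. Problem sizes were chosen to exercise the asymptotics the checks
rely on while keeping a full run in minutes: single-stratum recovery at
n = 2,000 with tolerance bands from ten replicate fits at n = 500 scaled by
sqrt(500/2000); mixed-cohort `p1` recovery at n = 5,000 with bands from ten
replicates at n = 1,000; latent-moment and survival closed-form oracles at
10,000 replicates; type-I-error calibration of the three tying nulls at 150
replicates of n = 250 cohorts with nuisance parameters held at their
generative values (a classical known-nuisance likelihood-ratio setting).
The calibration truth is a designed interior parameter point — strong gamma
heterogeneity so `sigma2` is identified from old-age deceleration, feedback
decline two standard errors inside the `b_Y >= 0` boundary, mortality low
enough that follow-up reaches the 90s — because the chi-square reference
presupposes such regularity.

## Known limitations

- The intercepts of the quadratic/linear components (`a_f1` especially) are
  values at age 0, four decades outside the observed window, and are
  weakly identified: their sampling SD barely shrinks between n = 500 and
  n = 2,000 while the fitted curves over 40–90 are stable. Interpret the
  curves, not individual polynomial coefficients.
- `sigma2` is near-unidentifiable when mortality data carry little old-age
  deceleration; boundary estimates at 0 are expected and flagged.
- Likelihood-ratio tests involving parameters pinned at bounds are
  conservative; the calibration experiments quantify this for the tying
  nulls.
- Standard errors are not computed from the information matrix; use profile
  curves or replicate simulations.
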