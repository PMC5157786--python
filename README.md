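# moverstayer

Trivariate mover-stayer truncated negative binomial counting-process models
for intermittently observed joint-damage data.

## The problem

In psoriatic arthritis, permanent joint damage accumulates in distinct joint
areas — the 28 hand joints, 20 foot joints and 16 large joints — and is
observed only at irregular clinic visits. Two features dominate such cohorts:

* **Excess zeros.** A large fraction of patients never develop damage in a
  given area even after decades of follow-up, suggesting a subpopulation of
  *stayers* with no propensity for the event, alongside the *movers* who
  accumulate damage.
* **Cross-process dependence.** Damage in one area may drive progression in
  another (e.g. attained hand damage predicting foot-joint progression), and
  these relationships can be asymmetric.

This package implements a trivariate model for exactly this situation, for
biostatisticians analysing bounded multivariate count processes with
structural zeros, and for methodologists who need a tested reference
implementation of its closed-form marginal likelihood.

## The model

For patient *i*, area *k* ∈ {h, f, l}, the damage increment between visits
*j* and *j*+1 is truncated negative binomial,

    D_ij^k | N_ij = n_ij  ~  TNB(Λ_ij^k, θ^k)  on  0..T^k − n_ij^k,

with intensity Λ_ij^k = (t_ij+1 − t_ij) λ0^k exp(β^k' z_ij), where z_ij
stacks the attained damage counts n_ij^h, n_ij^f, n_ij^l (*dynamic
covariates*) and any configured per-visit covariates; T^k is the area
capacity. Damage accrued between arthritis onset and clinic entry follows an
analogous truncated NB with its own λ0^{k0}, θ^{k0}.

Conditional on a unit-mean patient-level frailty U_i with variance γ, the
probability of being a stayer in area *k* is

    π_i1^k = 1 − exp(−U_i ω_i^k),   ω_i^k = exp(α_1^k' z_i*),

a complementary log-log structure whose marginal, π* = 1 − (1 + γ e^α)^(−1/γ),
spans the logit link (γ = 1) and the cloglog link (γ → 0). Expanding each
area's conditional likelihood factor into signed exponential terms turns the
frailty integral into a finite sum of gamma (or inverse-Gaussian) Laplace
transforms, so the marginal likelihood is **closed form** — fitting needs
only BFGS, no quadrature, EM or MCMC.

Nested variants: **TNB** (no stayers), **TM-SP** (mover-stayer truncated
Poisson, θ ≡ 0), and a **two-level** extension that splits stayers into true
stayers (immune since onset) and clinic-induced stayers (movers who become
immune at clinic entry), with two independent frailties marginalised by a
double signed expansion.

## Worked example

Simulate a 200-patient cohort from the built-in recovery-study design
(18 visits, 6-month spacing, known truth) and refit the full model:

```bash
moverstayer simulate --n-patients 200 --seed 7 --out demo.csv
moverstayer fit demo.csv --variant full --out demo_fit.csv
```

which prints (abridged):

```
              parameter  estimate       se  ci_lower  ci_upper
          hands.lambda0  0.351515 0.042812  0.276869  0.446287
hands.beta.damage_hands  0.142252 0.033513  0.076567  0.207937
            hands.theta  7.944184 0.910257  6.346251  9.944462
 feet.beta.damage_hands  0.065738 0.051140 -0.034495  0.165972
                  gamma  4.095215 1.497861  1.999596  8.387086
         p_stayer_hands  0.330717 0.046840  0.238912  0.422522
          p_stayer_feet  0.358700 0.040182  0.279945  0.437455
         p_stayer_large  0.356710 0.059204  0.240671  0.472748
log-likelihood: -3288.47  (19 parameters)
```

The generating values here are λ0^h = 0.37, β_hh = 0.1, θ^h = 8, γ = 3.9
and stayer proportions (0.37, 0.31, 0.29); the estimates track them at the
precision a single 200-patient replicate allows (one of the nineteen 95%
intervals misses its true value in this draw, as nominal coverage
predicts). `p_stayer_*` are the derived marginal stayer probabilities π*
with delta-method standard errors.

Python API equivalents live in `moverstayer.simulate` (generator and study
harness), `moverstayer.inference` (`fit_model`, `profile_loglik`) and the
likelihood modules; `moverstayer study` runs a full simulate-and-refit
recovery study and writes the summary table.

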