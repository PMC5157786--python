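# Methods

## Model structure

Each joint area k ∈ {hands, feet, large} (capacities T = 28, 20, 16) carries
a mover-stayer truncated negative binomial counting process observed at
clinic visits. For movers, the increment between consecutive visits is NB
with mean Λ = Δt · λ0 · exp(β'z) and dispersion θ, right-truncated to the
remaining undamaged capacity T − n at the interval's left endpoint; the
truncation bound follows the model formula as printed, so pre-clinic damage
reduces in-clinic capacity. Dynamic covariates (the attained damage counts of
all three areas) and any configured per-visit covariates are evaluated at the
interval's left endpoint: values at visit j predict the increment to visit
j+1. Damage between arthritis onset and clinic entry is a single truncated NB
draw with mean (t_entry − t_onset) · λ0_pre and dispersion θ_pre, truncated
at the full capacity; a zero onset-to-entry gap degenerates to a point mass
at zero, which forces entry counts of zero.

The stayer component is conditional on a unit-mean patient-level frailty U
with variance γ: π_1^k = 1 − exp(−U ω^k), ω^k = exp(α_1^k'z*). The shared
frailty is what lets never-damaged areas inform each other's stayer
probabilities. Marginally π* = 1 − (1 + γ e^lp)^(−1/γ), a link family
containing the logistic (γ = 1) and complementary log-log (γ → 0) inverses.

Marginalisation over U uses the signed expansion of the conditional
likelihood: each never-damaged area contributes a two-term factor
1 − e^{−uω}(1 − P), each damaged area a single term e^{−uω}P, and the
product expands into at most 2^(#never-damaged) ≤ 8 signed terms whose
expectations are Laplace transforms of the frailty. Gamma
(LT(s) = (1+γs)^(−1/γ)) and inverse-Gaussian
(LT(s) = exp((1 − √(1+2ψs))/ψ)) families are supported through the same
slot.

Nested variants: `tnb` removes the stayer component (likelihood is the plain
product of path probabilities, no frailty); `tmsp` keeps the mover-stayer
structure with all four dispersions per area fixed at exactly zero — a
dedicated Poisson branch, not a small-θ plug-in.

### Two-level extension

The two-level model distinguishes true stayers (C1 = 0, immune since onset)
from clinic-induced stayers (C2 = 0 given C1 = 1, movers who become immune at
clinic entry), with independent unit-mean frailties U (gamma, variance γ1)
and V in the two binary components. Each patient-area falls in exactly one
of three cases — never damaged; damaged only before clinic entry (final
count equals the entry count ≠ 0); damaged in clinic — whose conditional
factors are bilinear in e^{−uω1} and e^{−vω2}. The double marginalisation
re-derives the one-level expansion mechanically: each area factor expands
into at most three signed bilinear terms, the product over areas is
enumerated (≤ 3^3 terms), and independence factorises every term's
expectation into LT_U × LT_V. Because this derivation is done afresh here,
its correctness is enforced by a 2-D quadrature oracle in the test suite
rather than trusted. One display of the in-clinic product in the
damaged-in-clinic case reads as if all increments were zero; we treat that
as a typesetting slip and use the observed increments, consistent with the
one-level cases.

The default family for V is inverse Gaussian: its density vanishes at zero,
so small clinic-induced probabilities cannot be mimicked by V ≈ 0, which is
exactly the identifiability failure the gamma choice invites. Marginally
π_2* = 1 − exp((1/ψ)(1 − √(1+2ψ e^α))).

## Numerical choices

* All pmf arithmetic is on the log scale via log-gamma functions; truncation
  constants by log-sum-exp. The NB log pmf factorises as
  c_r(θ) + r·a − normaliser with a = log(θΛ/(1+θΛ)) (a = log Λ for the
  Poisson branch), so truncated pmfs over a capacity window need only the
  per-area weight vector c_r and one scalar per observation.
* The signed expansion is accumulated in linear space (signed terms of
  magnitude ≤ 1 preclude pure log-space accumulation); the common factor
  ∏ P over damaged areas is kept in logs. Derivatives with respect to the
  never-damaged path probabilities are assembled from partial products
  rather than divided out, so P → 1 causes no 0/0. A patient contribution
  that still underflows is floored at 1e−300 and logged; the dataset
  log-likelihood returns a −1e10 sentinel if non-finite.
* The inverse-Gaussian Laplace transform is evaluated in the rationalised
  form −2s/(1+√(1+2ψs)), stable as ψ → 0.
* The packed dataset engine deduplicates interval observations on
  (increment, remaining capacity, interval length, covariate row) and
  computes each distinct truncated pmf once per likelihood call, scattering
  per-patient sums by index. On the recovery-study design this compresses
  ~25k observations to a few hundred distinct rows.
* The one-level likelihood also returns its analytic score (verified against
  central finite differences in the tests); BFGS consumes it directly. The
  two-level model, the observed information and the delta method use central
  finite differences (relative step 1e−4 for the Hessian, 1e−6 for
  gradients of transforms), implemented in `inference.py`.
* Working scale: log transforms for λ0, λ0_pre, θ, θ_pre, γ, ψ; identity
  for β and α. Default starting values are data driven: crude events per
  person-year for λ0, the cloglog inverse of the damage-free fraction for
  stayer intercepts, θ = γ = 1, slopes 0. Working parameters beyond ±30 set
  a boundary flag (beyond ±60 the objective is replaced by a quadratic
  wall); non-convergence is reported in the result, never raised. The
  two-level fit uses five jittered starts (fixed seed) because its
  clinic-induced component can sit near the identifiability boundary.
* Wald intervals are computed on the working scale and mapped through the
  monotone transforms, so natural-scale intervals always bracket the
  estimate and respect positivity. Derived stayer probabilities use the
  delta method and are reported untruncated.
* Zero-length intervals are rejected at validation; the CSV loader can merge
  duplicate-date rows keeping the maximum counts. Single-visit patients
  contribute an empty interval product; with a zero onset gap their
  contribution is exactly 1 (uninformative), the mathematically forced
  consequence of P = 1.

## Synthetic data

The generator reproduces the published recovery-study conditions, which are
its defaults: 18 visits at 6-month spacing; entry with zero damage and onset
at entry (no pre-clinic period, so λ0_pre/θ_pre are not exercised there —
they are covered by unit-level oracles instead); gamma frailty; per-area
Bernoulli mover indicators with success probability exp(−u e^α); mover
increments drawn by categorical sampling over the exact truncated NB
probabilities, with the three areas updated jointly each interval. The
generating truth is β_hh = 0.1, β_hf = 0.08, β_ff = 0.04, β_lf = 0.1,
β_hl = 0.03 (other cross terms 0), λ0 = (0.37, 0.61, 0.14),
θ = (8, 13, 8), γ = 3.9, and stayer proportions (0.37, 0.31, 0.29) inverted
to intercepts through the marginal link. Randomness is split per patient and
per area via `SeedSequence.spawn` in a documented order, so replicate r
depends only on (master seed, r) and results are stable under by-replicate
parallelism.

What the generator does *not* emulate about real clinic data: irregular and
patient-specific visit spacing, informative observation or dropout, active
-joint covariates (optionally simulated as independent noise processes for
fixture variety, off by default), pre-clinic damage, and measurement error
in joint counts. Passing recovery tests therefore demonstrates correctness
of the likelihood and estimation machinery under the model, not robustness
to these real-data features.

## Problem sizes and study settings

The recovery studies fit the full 19-parameter model. The packaged
acceptance script uses 30 replicates per cohort size (200, 500, 800) —
enough that the Monte-Carlo standard error of each replicate mean is well
below the sampling standard deviation of a single estimate — and the test
suite uses 30/105/30 replicates, the n = 500 block also serving the Wald
coverage check (nominal 95%, accepted range [0.90, 0.99] over ≥ 100
replicates). Replicates whose fits fail to converge or hit the working-scale
boundary are excluded and counted; a study errors out if more than 20% fail.
At these sizes failures are rare (0–3%); they occur on a genuine ridge of
the likelihood where α and γ grow together, a known small-sample pathology
of frailty mover-stayer models.

## Known limitations

* Likelihood-ratio tests on the stayer boundary are out of scope
  (non-standard asymptotics); the package reports log-likelihoods and
  parameter counts only.
* The signed expansion can lose relative precision when a never-damaged
  area's path probability is extremely small together with a tiny ω
  (cancellation of order machine-epsilon / P); this regime is far from any
  realistic fit and bounded by the quadrature-equivalence tests.
* Baseline intensities are constant in time; time-varying baselines and
  alternative count kernels are not goals.
* The rate-based model for *becoming* a clinic-induced stayer during
  follow-up (as opposed to at entry) is not implemented.
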