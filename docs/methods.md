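# Methods

## Model and likelihood

The process model is a time-homogeneous continuous-time Markov chain on a
finite state space with a user-declared set of allowed instantaneous
transitions. The breast-cancer instance has four states — initial treatment
(1), recovery (2), metastasis (3), death (4) — with transitions
1→{2,3,4}, 2↔3, 2→4, 3→4, and death absorbing. Time homogeneity means the
generator `Q` is constant over follow-up, so `P(t) = exp(Qt)` and
`P(kt) = P(t)^k`; there is no dependence on time since entry beyond the
current state (no semi-Markov holding-time effects, no calendar trends).

Covariates enter log-linearly per transition, `q_rs(z) = exp(log q_rs⁰ +
β_rs·z)`, with time-fixed covariate values per subject. Optimizing on the
(log-intensity, β) scale enforces positivity without constraints.

The data are panel observations: the state is known only at visit times,
except death, which registries record exactly. Each consecutive pair
contributes `log P(Δt)[r,s]`; an exactly observed death at the end of an
interval contributes `log Σ_k P(Δt)[r,k]·q_{k,death}(z)` over living states
`k`. Whether the hospital cohort's deaths were treated this way is not
documented; we default to the exact-death contribution because death dates
are known exactly in practice, and `FitConfig(exact_death=False)` switches
every record to the plain panel contribution for sensitivity analysis. The
log-likelihood is additive over subjects and intervals; observation pairs
that are impossible under the declared structure yield −∞ with a diagnostic
naming the subject and interval.

## Numerics

- **Matrix exponential.** `transition_probability` uses scipy's
  Padé/scaling-and-squaring `expm`. The likelihood path instead
  eigendecomposes each distinct generator once and evaluates `P(Δt)` for all
  interval lengths by `V·diag(e^{λΔt})·V⁻¹`, falling back to the Padé route
  when the eigenvector matrix is ill-conditioned (condition number > 1e10)
  or eigenvalues nearly coincide (relative gap < 1e-6). A truncated power
  series implementation exists only in the test suite, as an independent
  oracle; generators in the calibrated model span three orders of magnitude
  (≈0.005/yr to ≈23/yr), for which naive series summation is not trustworthy.
- **Analytic gradient.** Every partial derivative of `Q` is a scalar multiple
  of one elementary direction per allowed transition, `q_a·(E_{rs}−E_{rr})`,
  so the Fréchet derivative of the matrix exponential is needed in only
  `n_transitions` directions per distinct covariate pattern regardless of the
  number of covariates. It is evaluated from the same eigendecomposition via
  the divided-difference (Loewner) formula, with `expm_frechet` as the
  ill-conditioned fallback. Gradients were verified against central finite
  differences (relative error ~1e-7).
- **Optimizer.** BFGS, gradient tolerance 1e-8, at most 500 iterations,
  started from crude initial rates `n_rs/T_r` (observed pair count over
  exposure time with the left endpoint in `r`), floored at 1e-3/yr for
  unobserved transitions so the start is interior. BFGS endings flagged as
  "precision loss" are accepted as converged when the remaining gradient is
  below 1e-4 relative to the likelihood magnitude; anything else is flagged
  unconverged, reported, and never silently accepted.
- **Covariance.** Inverse of the observed information, computed by central
  differences of the analytic gradient (relative step 1e-5, symmetrized). A
  singular or indefinite information matrix leaves the covariance `None`
  with a warning; point estimates are still returned.
- **Covariate standardization** (optional, off by default): covariates are
  centered/scaled for conditioning and estimates and covariance are mapped
  back to the original scale through the constant Jacobian.
- **Bootstrap probability intervals.** The published point estimates come
  with intervals whose method is undocumented (and which sometimes exclude
  their own point estimate), so no attempt is made to match them; the
  package's intervals are a parametric bootstrap — draw parameters from the
  normal approximation at the MLE, map through `exp(Qt)`, take entrywise
  quantiles (default 1,000 draws). Log-intensity draws are capped at
  [−20, 10] (rates between e⁻²⁰/yr and e¹⁰/yr): near-flat likelihood
  directions otherwise produce draws whose exponential overflows, and both
  caps are far outside any biologically attainable rate, so the envelope is
  unaffected.
- **Sojourn intervals.** Delta method on the log sojourn time for the
  no-covariate model. For the with-covariate model, sojourns are reported at
  reference covariate values (cohort means by default) without intervals.

## Synthetic cohorts

The generator produces exactly the data structure the likelihood assumes:
competing-exponential trajectories over the declared structure (holding time
`Exponential(−q_rr(z))`, next state with probability `q_rs/−q_rr`), observed
at schedule-driven visit times, with death recorded at its exact time and
administrative censoring at the end of follow-up. Everything is reproducible
from a single integer seed via spawned per-subject substreams.

Default conditions mirror the published cohort where the publication pins
them down, and are otherwise fixed, once, at values a registry cohort would
plausibly show:

- **Baseline intensities** (1/yr): 1→2 0.10275, 1→3 0.35843, 1→4 0.00728,
  2→3 0.64170, 2→4 0.00500, 3→2 22.84395, 3→4 1.54705. These were obtained
  by a one-time least-squares calibration (intensity floor 0.005/yr) against
  the published one-year transition matrix *and* mean sojourn times jointly,
  then frozen as package constants; the implied `P(1)` entries agree with the
  published ones within ~0.002 and the sojourns within 0.001 yr. The exact
  generator is not identifiable from the publication alone, so these
  constants are a representative, not unique, choice. The calibrated
  metastasis state is a fast transit state (mean stay ≈15 days).
- **Covariates**: age ~ Normal(47.19, 10.77) truncated to [23, 75]
  (published mean/SD/range); tumor size ~ Normal(2.5, 1.2) cm truncated to
  [0.3, 10]; involved/removed lymph-node ratio ~ Beta(1.2, 4); PR+ 60%,
  ER+ 70%, HER2+ 25%, P53 50% (typical hospital-cohort prevalences; the
  publication reports none). Defaults set every β to 0; the
  `paper-flavored` preset plants a few published hazard-ratio magnitudes
  (tumor size on 1→2 and 1→4, age on 3→4) for power experiments.
- **Visit schedule**: annual visits with ±1 month Gaussian jitter, 11 years
  of follow-up with administrative censoring — consistent with a 1999–2006
  recruitment window followed to 2017, but explicitly a package choice since
  the publication does not state the schedule.

What the generator does **not** emulate: informative dropout (the study
excluded 60 of 633 enrollees for unstated reasons), state misclassification,
screening-driven detection, time-varying covariates, and calendar-time
trends. Passing tests therefore demonstrate correctness of the estimator
under the model's own assumptions, not robustness to these real-data
features.

## Validation design

The raw cohort is not deposited, so data-dependent published numbers
(per-path hazard ratios, the with-covariate sojourn column, the reported
p-value) are not reproducible; validation instead rests on:

1. **Desk identities** among the published tables: the fifth matrix power of
   the one-year matrix against the five-year table (entries within ±0.005,
   the slack induced by 3-decimal rounding; the printed metastasis→recovery
   five-year entry is excluded — its row sums to 0.900 and is inconsistent
   with the one-year matrix, almost certainly a misprint), and
   `P(1)[1,1] = exp(−1/sojourn₁)`, exact because state 1 is never re-entered.
2. **Oracle equivalence**: likelihood and transition probabilities against an
   independent truncated-series matrix exponential (1e-10).
3. **Closed forms**: two-state chains (exponential survival MLE `n/Σt`,
   alive–alive and exact-death likelihood contributions).
4. **Parameter recovery**: 50 replicates of 2,000-subject cohorts under a
   moderate-rate test model (all intensities 0.08–0.3/yr, annual visits,
   8-year follow-up); pooled 95% Wald coverage of the generating
   log-intensities is required to fall in [0.91, 0.99]. The moderate-rate
   model, not the calibrated default, is used here deliberately: a ≈24/yr
   intensity is nearly unidentifiable from annual panel data, so Wald
   coverage for it measures the observation design rather than the
   estimator.
5. **Null calibration of the LRT**: 200 replicates of 300-subject cohorts
   with one balanced binary covariate and β = 0; the statistic's mean must be
   within 15% of its 7 degrees of freedom.

The replicate counts and cohort sizes above are the package's validation
design, chosen to make Monte-Carlo error small relative to each tolerance
while keeping the default test run fast.

## Known limitations

- Time-homogeneous intensities only; no piecewise-constant or semi-Markov
  extensions, no hidden-state misclassification model.
- Wald/delta-method uncertainty throughout; profile-likelihood or
  refit-bootstrap intervals are not implemented (the bootstrap is over the
  asymptotic normal approximation, which inherits its small-sample defects).
- Covariates are time-fixed; the exact-death contribution assumes death
  intensities constant over the final interval, as the model prescribes.
- With annual panels, intensities much faster than the visit interval (the
  calibrated metastasis state) are weakly identified at realistic cohort
  sizes; fitted sojourn times for such states carry very wide uncertainty.
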