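# Methods

## Model and procedure

The package implements sequential optimal risk-set matching for a
time-dependent binary treatment (kidney transplantation during
maintenance dialysis) and the downstream matched survival analysis.

**Treatment propensity.** For a time-dependent exposure the propensity is
the treatment hazard `h_m(t) = h0(t) exp(β'x_m)`, fitted as a Cox model
for time from dialysis initiation to transplant; death and administrative
censoring censor the treatment process. All covariates here are
time-fixed (age, sex, dialysis modality, insurance program, nine
comorbidity flags, Charlson index), so the model is fitted once and each
subject's score is the constant linear predictor `β'x`. The baseline
hazard is omitted from the score deliberately: within a risk set at a
common time it is a shared factor and cancels from every pairwise
distance comparison. No probability transform is applied — matching only
uses ranks of |score differences|.

**Sequential matching.** Distinct transplant days are visited in order.
At day *t* the treated are the subjects transplanted that day and not
already matched; eligible controls are alive and uncensored strictly
beyond *t* (half-open convention), not yet transplanted at *t*, and not
already matched. The within-risk-set 1:1 assignment minimizes total
absolute score difference (scipy `linear_sum_assignment`; rectangular
when controls are scarce). Matched subjects leave all later risk sets; a
control transplanted later anchors no new pair (reported with reason
`previously_matched_as_control`, alongside `no_eligible_controls`,
`insufficient_controls` and `caliper`). A greedy nearest-neighbour mode
exists for comparison; the optimal mode is the default and is verified
against factorial enumeration in the tests.

**Outcome analysis.** Each matched subject's clock restarts at the pair's
match day. Death records end at min(death, censoring); cardiac-event
(MACE) records are additionally censored by event-free death. Under the
default `censor_at_crossover` policy a control is censored at its own
later transplant; `itt` ignores crossover. Analyses: Kaplan–Meier
product-limit curves per arm; the Peto–Peto modified Gehan–Wilcoxon test
with weights `w(t_i) = S̃(t_i) = Π_{t_j ≤ t_i} (1 − d_j/(n_j+1))` on the
pooled sample and statistic `[Σ w_i(d_1i − e_1i)]² / Σ w_i² v_i` against
χ²(1); crude event rates (events / arm size, half-up to one decimal); and
Cox models — univariate (arm only) and multivariate (arm + age + sex +
modality + insurance + nine comorbidity flags; the Charlson index is
excluded from outcome adjustment because it is a near-deterministic
function of the flags and age already in the model). Subgroup analyses
refit the multivariate model within each level (dropping the subgroup's
own variable); the interaction p-value is a Wald block test of the
arm×level product terms in the pooled model.

**Naive comparator.** `naive_ever_treated_cox` codes ever-transplanted as
a time-fixed covariate with time measured from dialysis initiation. It is
deliberately biased (the pre-transplant waiting time is misclassified as
exposed) and exists to quantify the immortal-time artifact that the
matching removes.

## Numerical choices

- **Cox solver.** Newton ascent of the partial likelihood with
  step-halving; Breslow tie handling by default (claims data tie at day
  resolution; Breslow also keeps the brute-force oracles simple), Efron
  optional. Covariates are standardized internally for conditioning and
  results mapped back. Iterations stop when the score norm drops below
  1e-8 (at most 50 iterations). A standardized coefficient beyond ±10
  flags a monotone likelihood (separation); the coefficient is capped and
  the fit marked non-converged. A near-singular information matrix (the
  Charlson index is almost collinear with its components) falls back to a
  lightly ridged solve (ridge 1e-10 × mean eigenvalue).
- **Assignment tie-breaks.** An infinitesimal cost (1e-12 per id rank)
  prefers the smaller control id among equidistant controls, making runs
  deterministic.
- **Calipers.** Optional, expressed in standard deviations of the score
  distribution; pairs beyond the caliper are voided and the treated
  reported unmatched. No caliper by default.
- **Confidence intervals** are Wald on the log-hazard scale; plain
  (unpaired) standard errors by default, matching an unpaired Cox on the
  matched set.
- **Age subgroup bins**: 18–39, 40–49, 50–59, ≥60 inclusive integer years.
- **Degenerate inputs**: covariates constant within the matched subset are
  dropped from adjustment (logged); subgroup levels without events are
  flagged, not dropped; an outcome with zero events skips the hazard model
  but still reports curves and crude rates.

## Synthetic registry generator

The generator emulates an incident-dialysis claims registry in which
transplantation is a confounded, time-dependent treatment:

- **Covariates.** Age ~ Normal(55, 13) clipped to [18, 90] (integer
  years); male 60%; peritoneal dialysis 25%; Medical Aid coverage 13%;
  comorbidity prevalences dm 0.35, chf 0.15, cvd 0.10, pud 0.10, liver
  0.10, mi/pvd/copd/cancer 0.05. The Charlson index is computed from the
  nine flags (standard weights: 1 point each, cancer 2) plus one age
  point per decade from 50, capped at 4.
- **Transplant hazard** `λ_tx exp(α'x)` with λ_tx = 4e-4/day at the
  reference profile (age 50, female, HD, NHI, no comorbidity). The
  default α makes younger, less comorbid, nationally insured patients
  reach transplant sooner. The age coefficient (−0.13/year) was set by
  forward simulation so the transplanted-vs-dialysis age gap reproduces
  the ~16-year gap reported for the motivating registry, and the
  comorbidity/insurance coefficients so the confounded scenario is
  unambiguous (mean |SMD| ≈ 0.33 across the 14 covariates, Charlson gap
  ≈ 0.9 vs 2.5). These values are frozen; they are the package's study
  conditions, not tuning knobs.
- **Event times** are piecewise-exponential: each subject's death (and
  MACE) hazard is `λ exp(γ'x)` before the latent transplant time and
  jumps multiplicatively by `exp(θ)` after it; the unit-exponential
  cumulative-hazard equation is inverted across the jump. Defaults:
  λ_death = 2.5e-4/day, λ_mace = 1.5e-4/day, θ_death = θ_mace = log 0.5.
  Censoring is uniform on (0, 1825] days, giving a median follow-up near
  the ~2.2 years of the motivating registry. A transplant is observed
  only if it precedes death and censoring.
- **Day grid.** All times are reported as whole days (ceiling), which
  produces heavy day-level ties as in real claims. When rounding lands a
  transplant on its own terminal day, the terminal time is pushed one day
  out to preserve `tx < min(death, censor)`.
- **Eligibility filter.** Subjects with observed follow-up under 90 days
  are excluded (inclusive boundary: exactly 90 days is retained). The
  filter is defined on survival, not transplant timing, so an early
  transplant with long follow-up is retained.

**What the generator does not emulate:** claims-code noise (diagnoses are
error-free), competing risks beyond censoring, donor type or graft
failure, secular trends in transplant access, or within-subject
comorbidity progression. Passing tests therefore demonstrate the
statistical machinery — bias removal, balance restoration, calibration —
under a clean proportional-hazards world, not robustness to
claims-coding artifacts.

## Design decisions on genuinely open points

- **Prevalent-at-match cardiac events.** MACE is not terminal, so a
  control can carry an event from before its match day while satisfying
  risk-set eligibility. Only incident events strictly after the match day
  count; prevalent subjects contribute censored follow-up. (Death cannot
  occur before a valid match by construction.)
- **Crossover.** Whether matched controls should be censored at their own
  later transplant or followed intention-to-treat is analysis-dependent;
  both policies are implemented, with `censor_at_crossover` the default.
- **"Before" balance groups** are ever- vs never-transplanted subjects,
  matching the usual pre-match table layout. SMDs are reported as signed
  proportions with the binary-variance formula for flags.
- **Unmatched accounting.** Transplant recipients can end unmatched for
  four distinct reasons (exhausted controls, scarce controls within a
  risk set, caliper, prior consumption as a control); the matcher reports
  the reason per subject rather than a single count.
- **Seeding.** One global pipeline seed; per-stage streams are derived by
  hashing the stage name, so adding or reordering unrelated stages leaves
  other stages' draws untouched.

## Problem sizes

Simulation-based tests and the acceptance script use cohorts of n = 5000
(≈ 4500 after the eligibility filter, ≈ 600 matched pairs), 10–20
replicates for averaged quantities, and 1000–2000 replicates for test
calibration; matcher-vs-brute-force checks run on risk sets up to 6×6 and
full cohorts up to 12 subjects, the range where factorial enumeration is
exact and fast. These sizes make the full suite and the acceptance script
each complete in a few minutes on one CPU.

## Known limitations

- The propensity model assumes proportional treatment hazards with
  time-fixed covariates; time-varying comorbidity is out of scope.
- Matching quality is judged on the propensity distance only; no explicit
  prognostic-balance constraints are imposed beyond the propensity score.
- Plain standard errors (the default) ignore within-pair correlation;
  pair-clustered sandwich errors are available via
  `fit_cox(..., cluster_col="pair_id")` but are not the default, to
  mirror the common unpaired analysis of matched sets.
- The Peto–Peto test and Cox models assume independent censoring within
  arms; the crossover-censoring policy makes control censoring depend on
  (matched-on) covariates, which is standard but not innocuous when
  residual confounding remains.
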