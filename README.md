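# obmatch

Optimal balanced risk-set matching (OBM) for time-dependent treatments in
survival cohorts, with matched outcome analysis.

## The problem

Comparing kidney transplantation against remaining on maintenance dialysis
from registry or claims data runs into two classic biases. First,
**immortal time bias**: a patient only counts as "transplanted" if they
survived long enough on dialysis to receive a graft, so coding
ever-transplanted as a baseline covariate credits the waiting time —
during which they could not die as a "transplant patient" — to the
treatment. Second, **confounding by indication**: transplant candidates
are younger and carry fewer comorbidities than the dialysis population at
large.

Risk-set matching addresses both at once. Treatment propensity for a
time-dependent exposure is the *treatment hazard*

    h_m(t) = h_0(t) · exp(β'x_m),

estimated by a Cox model for time-to-transplant (death and administrative
censoring censor the treatment process). At each transplant day *t* the
risk set consists of patients still alive, uncensored, and not yet
transplanted; each newly transplanted patient is paired 1:1 with the
eligible control closest on the linear predictor β'x, solving the
within-risk-set assignment problem exactly (minimum total |score
difference|, via min-cost bipartite assignment). Matched subjects — both
roles — leave all later risk sets, so a patient transplanted later may
first serve as a control; their own transplant then anchors no new pair.
Each pair's outcome clock restarts at the match day, which is what removes
the immortal person-time from the contrast.

The matched cohort is then analysed with Kaplan–Meier curves, the
Peto–Peto modification of the Gehan–Wilcoxon test, and Cox hazard models
(arm + baseline covariates; Breslow tie handling for day-resolution data),
with optional subgroup and interaction analyses. Because real dialysis
claims registries cannot be redistributed, the package ships a synthetic
registry generator with confounded treatment assignment and a
proportional, time-varying treatment effect, so every property of the
method is testable end to end.

## Worked example

```sh
obm simulate --n 5000 --seed 1 --out cohort.csv
obm match    --cohort cohort.csv --out matched.csv
obm balance  --cohort cohort.csv --out balance.csv
obm analyze  --cohort cohort.csv --outcome death --out death.csv
```

prints

```
wrote 4473 subjects to cohort.csv
596 pairs (216 treated unmatched) -> matched.csv
mean |SMD| before=0.327 after=0.048 -> balance.csv
HR(arm) = 0.485 [0.337, 0.699], Peto-Peto p = 5.21e-06 -> death.csv
```

Reading those numbers: of 5000 simulated incident-dialysis patients, 4473
survive the 90-day eligibility window. Sequential matching forms 596
transplant–control pairs (unmatched transplants are mostly patients
already consumed as controls for an earlier pair). Mean absolute
standardized difference across the 14 baseline covariates drops from 0.33
(heavily confounded: the transplanted are ~16 years younger) to 0.05,
under the conventional 0.1 adequacy threshold. The matched, adjusted
death hazard ratio is 0.49 [0.34, 0.70] — the generator's true
post-transplant hazard ratio is 0.5 — and the weighted log-rank test
rejects equality of the matched survival curves. The same cohort analysed
naively (ever-transplanted as a time-fixed covariate) returns an HR of
0.23: the gap between the two is the immortal-time artifact the matching
removes.

The same steps are available as a library (`simulate_cohort`,
`fit_treatment_hazard` / `TreatmentHazardModel`, `RiskSetMatcher` /
`run_obm`, `balance_report`, `fit_cox`, `peto_peto_test`,
`subgroup_analysis`), and `obm run-all --seed 1 --out bundle/` writes the
full report bundle (tables, figures, manifest) in one call.

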