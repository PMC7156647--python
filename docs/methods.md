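# Methods

## The composite response model

In AL amyloidosis, treatment targets the plasma-cell clone, but morbidity
and mortality are driven by amyloid organ damage — most often heart,
kidney, and liver. Early treatment benefit is therefore poorly captured by
either hematologic response (HR) or organ response (OR) alone. The package
implements a composite score that evaluates both at a fixed landmark
(6 or 12 months after starting first-line therapy) in patients alive at
that landmark, and partitions patients into two prognostic groups.

**Hematologic response.** Depth of clonal response is graded from the
difference between involved and uninvolved serum free light chains (dFLC,
mg/dL), immunofixation, and the free light-chain ratio:

| category | criterion |
|---|---|
| CR | negative serum + urine immunofixation and normal FLC ratio |
| VGPR | landmark dFLC < 4 mg/dL |
| PR | landmark dFLC ≤ 50% of baseline |
| NR | none of the above (progression is absorbed into NR) |

Patients with baseline dFLC < 5 mg/dL lack measurable disease for the
graded criteria and are assessed for CR only. They carry category CR or NR,
but for scoring a low-dFLC non-CR contributes 1 point (its survival
resembles VGPR), not the 3 points of a standard-pathway NR.

**Organ response.** Per organ, at the landmark:

- *cardiac* — NT-proBNP decrease strictly > 30% **and** > 300 pg/mL;
  evaluable only when baseline NT-proBNP ≥ 650 pg/mL;
- *renal* — 24-h proteinuria decrease ≥ 30% (or landmark proteinuria
  < 500 mg/24 h) **without** a ≥ 25% eGFR decline; patients on dialysis at
  baseline are not evaluable;
- *liver* — alkaline phosphatase decrease ≥ 50% (inclusive).

Uninvolved organs, and involved organs with missing markers, are
NOT_EVALUABLE. Relative thresholds written "≥" are inclusive; the cardiac
">" thresholds are strict. All cutoffs live in a single
`ResponseThresholds` object so they can be audited or overridden.

**Combined OR and the score.** Among involved-and-evaluable major organs:
AOR = response in all, MOR = response in some, NOR = response in none;
patients with no evaluable organ are excluded from scoring (consort
accounting keeps them visible). Points: HR 0/1/2/3 for CR/VGPR/PR/NR
(low-dFLC: 0/1), OR 0/1/2 for AOR/MOR/NOR; total 0–5. The published
partition is group 1 = scores 0–3, group 2 = scores 4–5.

**Grouping construction.** `build_grouping` reproduces how such a
partition is derived: a Cox model with the score as a 6-level categorical
exposes per-score hazard ratios against the best score, and each of the
five contiguous cuts of {0..5} is evaluated by a two-group log-rank
statistic; the maximizing cut is returned (ties break toward the lower
cut), with a `separating` flag when even the best cut is not significant
at α = 0.05. Choosing the cut by a deterministic statistic, while
reporting the per-score hazard ratios alongside, keeps the construction
reproducible and auditable; the published 0–3 | 4–5 partition remains the
scoring default regardless.

## Survival statistics

Overall survival runs from treatment start, with the analysis cohort
restricted to patients alive at the landmark. Kaplan–Meier estimation,
the log-rank test, and Cox models (Efron tie handling, Wald intervals)
are delegated to lifelines. Median survival is the first time the curve
reaches 0.5 ("not reached" is represented as null), with a log-log
(Brookmeyer–Crowley-type) 95% interval.

Harrell's concordance is implemented in-package by vectorized pairwise
counting: ordered pair (i, j) is comparable when subject i's event is
known to precede j's follow-up (tied event times are not comparable; an
event tied with a censoring time precedes it), and risk ties count 0.5.
Two risk scores on the same cohort are compared with a paired
leave-one-out jackknife of the concordance difference — leave-one-out
values are obtained in O(n²) by subtracting each subject's row/column
contributions — giving a normal-approximation CI and two-sided p.
Likelihood-ratio p-values for nested models use χ²(2Δℓ, Δdf).

Dialysis-free survival (renally involved patients not on dialysis at
baseline) treats dialysis initiation as the event and death as censoring,
reporting survival at 60 months by renal-response status. Treating death
as a competing risk would lower both curves; under the simulator's
independent hazards the censoring treatment is unbiased, but on real data
the 5-year probabilities should be read as cause-specific.

## The synthetic cohort generator

No patient-level data accompany the model, so the generator emulates the
*structure* the analysis assumes, with two frozen configurations encoding
the published Mayo and Pavia cohort marginals:

- **Involvement** — independent Bernoulli draws per organ, rejected until
  ≥ 1 major organ is involved. Because conditioning inflates marginals,
  the unconditional parameters are solved by fixed point so the
  *conditional* marginals (heart 70%, kidney 70%, liver 14% for the
  Mayo configuration) are matched exactly.
- **Baseline biomarkers** — log-normal for right-skewed markers (dFLC,
  NT-proBNP, proteinuria, ALP), parameterized by the printed median
  (matched exactly) and IQR (matched as log-scale width; the individual
  quartiles are matched only when log-symmetric). Age and eGFR are
  clamped normals. Biomarkers are drawn independently of involvement;
  in real cohorts NT-proBNP is higher in cardiac-involved patients, so
  the generator's cardiac-evaluability fraction (~68% of heart-involved)
  undershoots the published ~88%.
- **Hematologic depth** — category probabilities among
  standard-pathway patients and a CR probability for the low-dFLC
  pathway, both from the printed rates. A PR draw is infeasible when
  baseline dFLC < 8 mg/dL (no landmark value is both ≥ 4 mg/dL and a
  ≥ 50% reduction); such draws are swapped with feasible non-PR draws,
  preserving the category histogram exactly at the cost of a mild
  category–baseline dependence.
- **Organ responses** — conditionally independent Bernoulli per
  involved-and-evaluable organ, with a per-depth probability *solved*
  (Brent root-finding on E[p^K], K the analytically derived
  evaluable-organ-count distribution) so the expected AOR fraction per
  depth matches the printed conditional rates (e.g. AOR 38% given CR,
  Mayo). The no-response depth is calibrated to the printed
  any-organ-response rate instead.
- **Landmark biomarkers** — drawn uniformly inside (responders) or
  outside (non-responders) the response region, with margins larger than
  the CSV rounding error, so classifying a generated cohort reproduces
  the latent statuses for 100% of patients. This round-trip is the
  generator's main self-consistency oracle.
- **Survival** — exponential by default (Weibull selectable) with a
  proportional-hazards multiplier per composite group, left-truncated at
  the landmark by resampling, and uniform administrative censoring over
  (6, 120) months — chosen to give roughly 40% observed deaths in the
  Mayo configuration. An exponential proportional-hazards model cannot
  reproduce both printed group medians and the printed hazard ratio at
  once (Pavia median ratio 3.78 vs HR 2.8); the group multiplier is kept
  at the printed hazard ratio — it is the quantity the validation
  analyses recover — and the baseline rate is set from the one median
  that pins it (Mayo group 2: 34 months; Pavia group 1: 87 months).
- **Dialysis** — exponential hazards calibrated so 5-year dialysis-free
  survival is 0.88 for renal responders and 0.65 for non-responders,
  censored by death and end of follow-up.

What passing tests on generated cohorts therefore show: the classifiers,
scorer, and survival machinery are internally consistent and recover the
structural parameters they are pointed at. What they do not show:
robustness to missingness, correlated organ involvement, non-proportional
hazards, or measurement error — none of which the generator models.

## Numerical and design choices

- Percentages in reports are round-half-away-from-zero integers with the
  numerator/denominator always attached (45/119 renders as 38%).
- dFLC is mg/dL internally; the reader converts mg/L inputs (÷10) only
  when a units sidecar explicitly declares them — no magnitude heuristics.
- Assessments dated more than ±2 months from the landmark are flagged
  ineligible by the reader rather than interpolated.
- Cox with one eventless arm returns a flagged non-finite estimate rather
  than raising; eventless scores in `build_grouping` get NaN hazard
  ratios and are listed.
- `compare_c` with identical inputs returns Δ = 0 with p = 1 (zero
  jackknife variance is treated as exact equality).
- Simulation sizes used by the test suite (cohorts of 400–12000, 100–200
  replicates for recovery checks) were chosen so that Monte-Carlo noise
  is small against each check's tolerance; stochastic recovery checks
  that would be dominated by single-draw luck (the 5-year dialysis-free
  round trip, the pooled marginal-fidelity check) average a handful of
  seeded cohorts instead of using one draw.

## Known limitations

- Progression is not distinguished from no response (both score as NR),
  and NYHA-class cardiac criteria are not implemented.
- Organ involvement correlation is not modeled; the >1-organ fraction
  (~49% generated vs 46% printed for Mayo) is an emergent check, not a
  constraint.
- The generator emits complete data; missingness and evaluability-floor
  patterns of real registries are not emulated.
- Cohort-level survival constants (medians, C-indexes) of the source
  cohorts are not reproducible without patient-level data; the package
  validates structure and parameter recovery instead.
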