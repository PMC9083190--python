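# Methods

## Scoring model

An instrument is a set of diseases *D*, questions with answer options, an
integer weight map *w(option, disease)*, and per-disease cut-offs
T1_d ≤ T2_d. A participant's disease score is the plain sum of the
selected options' weights for that disease; the total score is the sum of
the disease scores. "Built from the individual scores" admits several
aggregations; the plain sum is the committed interpretation here, pinned
by tests. Two further interpretation choices are fixed and documented:

* **Threshold passage uses ≥**: a score equal to the cut-off passes it.
* **Any-disease trigger**: the overall recommendation is the maximum
  level reached by any single disease (`none` < `primary_care` <
  `rheumatology`); it is not based on the total score.

Unanswered questions contribute 0. `required` questions are enforced
during response validation, never inside the scoring sum, so scoring is a
pure function of the selections. Each selected option counts exactly
once, including options selected under a multi-choice question. Weights
are integers; the schema permits negative weights, but the shipped
default uses non-negative ones, under which scoring is monotone: adding a
selection can never lower any score or the triage level (a property test
pins this).

The configuration schema supports `single_choice`, `multi_choice` and
`boolean` questions. Banded scoring of free numeric entries (e.g. symptom
duration in weeks) is not part of the committed schema; a band can be
expressed today as a `single_choice` over intervals.

## Evaluation statistics

Let S⁺, S⁻ be total scores in the outcome-positive/negative groups.

**Group summaries.** Mean, median (midpoint convention for even n),
minimum and maximum per group (all / outcome=1 / outcome=0); an empty
group is omitted with a logged note rather than an error.

**Wilcoxon rank-sum.** Two-sided, on the total score. The exact null
distribution is used when n₁+n₂ ≤ 20 and there are no ties; otherwise
the normal approximation with tie-corrected variance and continuity
correction. The method actually used is always reported in the result,
since at these cohort sizes the choice is visible in the third decimal of
P. The computation is delegated to `scipy.stats.mannwhitneyu`; an
independent full-permutation enumeration oracle in the test suite pins
the exact path for all shapes with n₁+n₂ ≤ 10, and a 2000-replicate null
simulation checks the type-I error rate at α = 0.05 stays in
[0.03, 0.07]. When every value in both groups is identical the result is
flagged degenerate with U = n₁n₂/2 and p = 1.

**AUC-ROC.** Computed from midranks as the Mann–Whitney concordance
probability (ties count ½), which equals the trapezoidal area under the
empirical ROC curve on every input — an equivalence asserted on 200
random cohorts against scikit-learn's trapezoidal implementation. The
95% CI uses the DeLong variance estimator on the per-observation
structural components V₁₀, V₀₁ (sample variances with ddof = 1, variance
S₁₀/m + S₀₁/n), truncated to [0, 1]. DeLong was chosen because it is the
default of the standard ROC software in this field's literature; it is
hand-implemented here (no maintained Python implementation exists) and
cross-checked against a 2000-replicate stratified bootstrap percentile
interval (agreement within 0.02 at n = 100 per class). With perfect
separation the variance collapses and the interval degenerates to the
point estimate.

**Threshold accuracy.** At each triage level, the cohort is
cross-tabulated into TP/FN/FP/TN against the outcome; sensitivity =
TP/(TP+FN), specificity = TN/(FP+TN). Confidence intervals are exact
Clopper–Pearson from beta quantiles, with the conventional closed
endpoints 0 at x = 0 and 1 at x = n. Clopper–Pearson was adopted because
it regenerates the printed intervals of the three-center validation
study from its 2×2 counts after integer rounding (27 of 28 printed
numbers exactly; the 28th, one upper bound whose exact value 26.255%
rounds to 26 while the printed table shows 25, is a transcription slip in
the source table — no standard binomial interval produces 25 there while
matching the other seven intervals). Percent renderings round half away
from zero, the rule that reproduces all printed point estimates
(14/21 → 67, 1/21 → 5, 22/23 → 96, 20/22 → 91).

No multiplicity correction is applied: the three cohorts are analysed
and reported separately. Predictive values are deliberately out of scope
because the validation cohorts were enriched by design and do not
reflect population prevalences.

## Synthetic cohorts

The generator draws each participant's answers independently per
question from a group-specific profile: a categorical draw over the
options of a single-choice/boolean question (unassigned probability mass
= no selection) and independent Bernoulli draws per option of a
multi-choice question. Answers are independent across questions. This is
deliberately the simplest model that exercises every branch of the
pipeline; it does **not** emulate symptom co-occurrence, question-order
effects, or item nonresponse bias, so passing tests demonstrate the
correctness of scoring and statistics, not clinical realism of any
particular operating point.

Sampling is vectorised question-by-question from a single
`numpy.random.Generator` seeded by the root seed, making cohorts exactly
reproducible from that one integer; the positive fraction is
n₊/(n₊+n₋) by construction.

**Separation control.** The positive group's profile is an interpolation
between the negative and positive base profiles: category probabilities
(including the no-selection mass) are mixed geometrically and
renormalised — for two categories this is linear interpolation of the
log-odds — with coefficient λ ∈ [0, 1]. `calibrate_separation` finds λ by
bisection on a Monte-Carlo estimate of the expected total-score AUC
(4000 simulated participants per group per evaluation, common random
numbers across λ so the bisection sees a smooth monotone curve,
tolerance 0.005). If even λ = 1 cannot reach the target the error
reports the achievable maximum. Calibrated targets {0.55, 0.65, 0.75,
0.85} are recovered within ±0.03 empirical AUC at n = 1000 per group,
the binomial sampling-error bound at that size.

**Presets.** `dataset_A` (21 positive + 29 negative, target AUC 0.753),
`dataset_B` (28 + 23, 0.790) and `dataset_C` (51 + 22, 0.536) reproduce
the cohort sizes, outcome prevalences and total-score discrimination of
the three validation centers — their statistical shape only, not their
clinical content. The shipped base profiles give the positive group
higher selection probabilities for inflammatory-pattern answers; their
maximal separation is AUC ≈ 0.97, comfortably above every preset target.
The default thresholds were set once from score quantiles under these
profiles so that threshold 1 is moderately sensitive/specific and
threshold 2 is highly specific but insensitive, mirroring the
operating-characteristic pattern reported for expert-set triage
cut-offs.

## Numerical and design choices

* **Config formats**: JSON and YAML accepted (by extension; raw text
  tries JSON first). JSON is canonical for bit-exact round trips.
  Validation collects *all* violations before raising, and
  `validate_config` itself never raises on structurally parseable input.
* **CSV dialect**: comma, UTF-8, mandatory header, `.` decimal, booleans
  as 0/1 — pinned so outputs are diffable and byte-reproducible.
* **Determinism**: all result artifacts (cohort, scored table, report
  CSVs/JSON/text) are byte-identical across reruns with the same seed;
  the wall-clock timestamp appears only in `run_manifest.json`.
* **Problem sizes** used by the test-suite and acceptance computations
  (200 random cohorts for the AUC equivalence, 500 draws for interval
  inversion, 2000 null replicates for the type-I check, 1000 per group
  for preset AUC recovery) are the package's chosen precision/runtime
  trade-off: at these sizes every stochastic check has a comfortable
  margin relative to its tolerance.

## Known limitations

* The shipped weights/thresholds are illustrative; conclusions about any
  deployed instrument require its real configuration in the same schema.
* The simulator's independence assumption means simulated cohorts are
  "easier" than real ones for a fixed AUC target: real symptom
  correlation concentrates score variance. Calibration targets are on
  the AUC scale precisely so this difference is absorbed.
* The exact Wilcoxon path is limited to n₁+n₂ ≤ 20 without ties; larger
  tie-free cohorts use the approximation even where exact computation
  would be feasible.
* DeLong intervals are asymptotic; at very small n (a handful per class)
  they can undercover, which is why the report prints the CI next to the
  group sizes rather than hiding them.
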