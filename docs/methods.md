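# Methods

## The screening rule

The SCOFF questionnaire has five binary items in fixed order — Sick
(self-induced vomiting), Control (loss of control over eating), One
stone (loss of more than 6.35 kg in three months), Fat (feeling fat when
others disagree), Food (food dominates life). A screen is positive with
at least two positive answers; 26 of the 32 answer patterns qualify.
BMI (kg/m²) is classed by the WHO cutoffs with half-open intervals:
[0, 18.5) underweight, [18.5, 25) normal, [25, 30) overweight,
[30, ∞) obese. The original cutoff text leaves the points 25.0 and 30.0
formally unassigned ("between 25.0 and 29.9", "> 30"); we adopt the
half-open convention so classing is total and monotone, and say so
rather than infer it from data. BMI values outside (0, 100] are rejected
as presumptive unit errors.

The algorithm itself is pure data: a table mapping each of the
26 × 4 = 104 (pattern, BMI class) combinations to one of the four broad
categories RD, BD, HD, OED. Classification is a lookup; screen-negative
respondents get a distinct status, never a fifth category.

## The default table is a constrained reconstruction

Only three facts about the original table are public: the per-class
marginal counts (underweight 26/0/0/0, normal 3/18/1/4, overweight and
obese each 0/8/7/11, category totals 29/34/15/26), three worked
assignments ((One stone+Fat, underweight) → RD; (Sick+Control, normal)
→ BD; (Control+Food, obese) → HD), and the fact that the two expert
physicians agreed on all 104 cells. The shipped table pins all of the
above and fills the remaining 75 cells deterministically: within each
BMI class, categories are filled to their marginal quota greedily
(RD, then HD, then BD, OED taking the remainder) with candidate patterns
ranked by a clinical-affinity score — One stone and Fat favour
restriction, Sick and Control favour bulimic behaviour, Control plus
Food without Sick favours hyperphagia — ties broken by lexicographic
pattern order. Every published constraint is matched exactly; the other
cells should be treated as plausible placeholders, and any user-supplied
104-row CSV can replace them.

## Validation statistics

Physician diagnosis (DSM-5 labels collapsed to the four categories:
AN/ARFID/atypical-AN → RD, BN and low-frequency BN → BD, BED and
low-frequency BED → HD, purging disorder/night eating/other → OED) is
the gold standard. With the 4×4 confusion matrix C (rows truth, columns
algorithm, n = ΣC):

- sensitivity_k = C_kk / row_k, specificity_k = TN_k / (n − row_k) with
  TN_k = n − row_k − col_k + C_kk, Youden J_k = sens_k + spec_k − 1
  (computed unrounded; J_k is undefined when a margin is empty and an
  error is raised rather than a NaN returned);
- proportion CIs default to the continuity-corrected Wald interval
  p ± (z·√(p(1−p)/n) + 1/(2n)) truncated to [0, 1]. This is the method
  that reproduces all eight published 95% intervals of the reference
  validation table to the printed decimal; plain Wald, Wilson and
  Clopper–Pearson (delegated to statsmodels) do not, and are offered as
  options;
- Cohen's κ = (p_o − p_e)/(1 − p_e) with p_o = tr(C)/n and
  p_e = Σ_k row_k·col_k / n², with the common asymptotic standard error
  se = √(p_o(1−p_o)/n)/(1−p_e). On the reference matrix this gives
  κ = 0.591 with 95% CI (0.50, 0.68). The original publication prints
  "(0.51–67)"; no standard formula we are aware of reproduces that
  interval exactly, so it is documented here and not asserted anywhere.

### Reproduction tolerance

The published percentages were not rounded by one consistent rule:
67/84 = 79.76% and 136/141 = 96.45% are printed as 79.7 and 96.4
(truncation), while 3/18 = 16.67% is printed as 16.7 (half-up). The
`reproduce` check therefore compares each recomputed value to its
published counterpart within one unit in the last printed digit (0.1
percentage points; 0.01 for Youden and kappa). Display rendering uses
round-half-up, so two rendered cells (79.8, 96.5) differ from the
publication in the last digit while the underlying fractions are
identical. Internal values are never rounded.

## The synthetic cohort generator

The generator exists so the full pipeline — classification plus
validation — is testable with no access to the study data. Defaults are
the reference cohort's structure: n = 206; prevalences 65/39/84/18 over
(RD, BD, HD, OED); per-category BMI-class mixes (RD 78.5/18.5/1.5/1.5%,
BD 10.2/48.7/10.2/30.7%, HD 0/2.4/2.4/95.2%, OED 5.6/22.2/11.1/61.1%,
renormalized); female fractions 98.4/100/91.7/94.4%; ages normal with
means (SD) 30.4 (12.1), 28.5 (9.8), 43.9 (13.9), 37.1 (15.6), truncated
at the adult-inclusion floor of 18. DSM-5 labels are drawn uniformly
from the category's member diagnoses. BMI values default to uniform
within the sampled class interval ([12, 18.5), [18.5, 25), [25, 30),
[30, 60]) because class membership, not the exact value, drives the
algorithm; a truncated-normal option uses the per-category BMI mean/SD
above. The published per-category class percentages and BMI mean/SD
pairs are mildly inconsistent as a joint distribution; the percentages
are authoritative here.

The response model is this package's construction (the study was
observational and published none): given true category and sampled BMI
class, the answer pattern is uniform over the rule table's compatible
patterns with probability 1 − ε, uniform over the other eligible
patterns with probability ε, and uniform over all 26 when no compatible
pattern exists (e.g. any non-RD truth at underweight, where every cell
is restrictive). ε defaults to 0.1, a modest questionnaire-noise level
chosen once for realism; ε is in [0, 1] and kappa degrades monotonically
in it. Two anchors follow by construction: ε = 0 with the BMI mix
restricted to compatible classes yields perfect agreement (κ = 1), and
structural misclassification alone (underweight BD/OED patients forced
to RD) produces discordance of the kind the real cohort shows.

What the generator does *not* emulate: item-level psychometrics
(inter-item correlations, wording effects), the empirical DSM-5 label
frequencies within categories, comorbidity, and any dependence of
answers on age or sex. Passing recovery tests therefore shows the
pipeline's statistics are internally correct under the stated model,
not that the algorithm performs at any particular level on real
patients.

## Numerical and design choices

- Category order (RD, BD, HD, OED) and the five-item order are fixed
  everywhere: tables, matrices, reports.
- Rule-table CSV: header `sick,control,one_stone,fat,food,bmi_class,
  category`, bits 0/1, exactly 104 rows; order irrelevant on load,
  lexicographic on write, so files diff cleanly.
- Degenerate inputs raise errors rather than propagate NaNs: empty
  cohorts, missing diagnoses, screen-negative records in validation,
  zero one-vs-rest margins, p_e = 1 in kappa.
- Reproducibility: the generator is a pure function of (config, table);
  the config seed feeds a single `numpy` Generator; repeated runs are
  byte-identical. The recovery harness derives replicate seeds as
  seed + rep (mod 2³¹).
- Problem sizes in the test-suite recovery checks (noise grid at
  n = 5,000; goodness-of-fit at n = 10,000; 1,000 cohorts of n = 50 for
  the metric-equivalence oracle) were chosen to make sampling noise
  negligible relative to the tested effects while keeping the default
  suite fast.

## Known limitations

- 75 of the 104 default cells are reconstruction; conclusions about the
  original algorithm's cell-level behaviour must use a user-supplied
  table.
- The published kappa CI is not reproducible (see above).
- One-vs-rest metrics ignore the multiclass dependence between
  categories; no ROC analysis is possible because the classifier has no
  threshold.
- Display rounding of percentages is best-effort against an
  inconsistently rounded source table.
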