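# Methods

## The estimand and the probabilistic confusion matrix

For a candidate case definition *D* (a monotone AND/OR expression over
code predicates) evaluated on a test population, the quantities of
interest are the classical sensitivity, specificity, PPV, NPV and F-score
of *D* against true disease status. True status is unobserved at test
time; instead each patient *i* carries a model probability
`p_i = P(case | features_i)`. Summing `p_i` over definition-positive
patients gives the cumulative true-positive mass TPs, and `1−p_i` the
false-positive mass FPs; the definition-negative side gives FNs and TNs.
The five indexes are the usual ratios on these real-valued cells.

The estimator is unbiased exactly when the scores are calibrated
conditional on a σ-algebra that contains the definition: if
`p_i = P(case | X_i)` and *D* is a function of `X_i`, then
`E[Σ_pos p] = E[#(pos ∧ case)]` by iterated expectation. This is why
calibration is the load-bearing assumption, why the leakage rules below
matter (a leaked label feature produces overconfident, *mis*-calibrated
probabilities on the test period), and why the pipeline computes a
logistic recalibration slope on scored data and warns when it leaves
[0.8, 1.2]. No recalibration is applied by default.

Degenerate check: when every `p_i ∈ {0, 1}` the probabilistic cells equal
classical counts and all five indexes coincide with the 2×2 confusion —
asserted exactly in the tests against an independent brute-force oracle.

## Confidence intervals

Percentile bootstrap, default 1000 replicates at the 95% level. The unit
of resampling is the test patient: (score, definition-status) pairs are
drawn with replacement and all five indexes are recomputed per replicate.
Replicates where an index is undefined (zero denominator) are dropped for
that index with a logged count; an index undefined in *every* replicate
gets no interval rather than a fabricated one. Replicate streams are
seeded, so intervals are bit-reproducible. Measured coverage of the
nominal 95% interval for sensitivity and PPV of the basal-insulin
definition, over 200 simulated test sets of n=5000, is 94–95%.

## Gold-standard cohort

Possible cases are patients matching ≥1 of five screening criteria:

1. confirmed T1D / insulin-dependent-diabetes diagnosis (default code set
   {E10}, prefix match, so E10x subcodes count);
2. insulin prescription AND minimum serum CPR < 0.6 ng/ml AND a
   ketoacidosis diagnosis;
3. positive GAD or IA2 autoantibody;
4. diabetologist referral flag;
5. minimum serum CPR < 0.2 ng/ml.

CPR thresholds use strict `<`, as stated clinically ("less than"). The
temporal order of the ketoacidosis diagnosis relative to the CPR
measurement is ignored (dates carry no within-period meaning here).
Screened patients are adjudicated; adjudication is modelled as latent
truth XOR a Bernoulli error (default error rate 0 — chart review is the
reference standard; a nonzero rate supports sensitivity analyses). Cases
then lose patients with a pancreas-transplant procedure or any confirmed
or suspected T2D code (default 3-digit E11, applied to cases only, as the
exclusion is about case purity). Controls are sampled without replacement
from never-reviewed patients carrying no confirmed or suspected T1D code,
at a default 233 controls per case (the ratio implied by a 296-case /
69 023-control training cohort); the ratio is a config parameter.

## Features and screening

One binary dummy per observed (namespace, code): `confirmed:`/
`suspected:` ICD-10 codes truncated to three characters, `med:` generic
names (a user-supplied code→generic map; unmapped codes are used verbatim
with a warning), `proc:` procedure codes — value 1 iff the patient has ≥1
matching event in the period. Age (window-start year minus birth year) and
sex are numeric/binary columns that always bypass screening. Leakage
patterns removed before modelling: confirmed E10/E11/E87x, suspected
E10/E11/E13/E14, all insulin medications, and the CPR and
insulin-receptor-autoantibody test procedure codes — everything the gold
standard was built from.

Relative risk of case status is computed per feature from the 2×2 table
as `[a/(a+b)] / [c/(c+d)]`. A 0.5 continuity correction on all four cells
is applied whenever any cell is zero; a feature with no variation (all
present or all absent) is defined to have RR = 1, since it carries no
discrimination. Features are ranked by RR descending (protective features
rank low — no absolute-value ranking), ties broken lexicographically, and
the top 500 retained.

## Probability model

LightGBM binary classifier: 500 trees, depth 4 (15 leaves), learning rate
0.05, `min_child_samples` 10, early stopping (50 rounds) on a 10%
stratified validation split, single-threaded and deterministic given the
seed. Ten-fold stratified cross-validation inside the training cohort
reports fold-wise AUC; the final model is refit on all rows. Variable
importance is total gain normalised to sum to 1. Scoring aligns columns
to the training set: unseen columns are dropped with a warning, missing
ones filled with zeros.

On the default synthetic population the trained model reaches mean CV AUC
≈ 0.99 with the injector-needle code, glucometer/HbA1c test codes and age
dominating the importances, and a test-period calibration slope ≈ 0.75 —
slightly overconfident, duly flagged by the pipeline warning. The exact
posterior scorer (below) has slope ≈ 1.0 by construction.

## Synthetic data generator

Three mutually exclusive latent classes — background, T1D (default
prevalence 0.004, the middle of the 0.3–0.5% range such hospital
populations imply), hemophilia (0.002). Every code is an independent
Bernoulli draw per patient per period from a class-specific emission
table; event dates are uniform within the period (downstream features use
presence only). Training-period and test-period patients are disjoint
groups, matching the study rule that test patients must be unseen during
training years (2009–2014 vs 2015–2019, half-open windows).

The emission defaults are anchored to published single-code operating
characteristics: P(confirmed E10 | T1D) = 0.33 (only about a third of true
T1D patients carry the confirmed code), P(needle | T1D) = 0.33,
P(any basal insulin | T1D) = 0.40, P(any CSII code | T1D) = 0.04;
hemophilia patients emit the needle code at 0.36 (the shared-code PPV
confounder), and background rates are back-solved from the published
single-code PPVs (≈33% E10, ≈65% needle, ≈9% basal, ≈86% CSII) at those
prevalences. Around 1200 class-independent noise codes (per-code
probabilities ~Beta(0.3, 30)) exercise the feature screen. CPR values are
lognormal — median 0.15 ng/ml (σ=0.8) for T1D, 1.8 ng/ml (σ=0.5)
otherwise — attached to a CPR-test procedure code; GAD/IA2 positivity,
diabetologist referral, class-specific age distributions and a 44.5% male
fraction complete the tables. Same seed and config ⇒ byte-identical
output files.

What the generator does *not* emulate: within-class code correlation
(conditional independence makes the E10∧needle joint rate the product of
the marginals, so combined definitions come out *cleaner* here than in
real claims, where the codes co-occur), longitudinal trajectories,
multi-visit structure, care received at other institutions, and coding
drift over time. Passing tests therefore demonstrate that the estimator
machinery is correct under the stated statistical structure, not that any
particular real-world definition has these operating characteristics.

Conditional independence buys two exact oracles used throughout the
tests: `calibrated_scores` (the closed-form Bayes posterior
P(T1D | class-dependent codes) — a perfectly calibrated scorer that makes
parameter-recovery checks exact in expectation) and
`analytic_definition_performance` (large-sample sensitivity/PPV of any
definition by enumerating the joint distribution of its leaf codes).

## Numerical and reporting choices

* Undefined ratios (0/0) are reported as `None`/"undefined", never silent
  NaN; an all-zero confusion matrix is an error.
* Report formatting: percentages at 1 dp, F-score at 3 dp; indexes are
  carried on the proportion scale internally and per-column on the
  percentage scale in the report table.
* Stage seeds in the pipeline are master seed + fixed offsets
  (simulate 0, cohort +1, train +2, evaluate +3), recorded in the run
  manifest together with SHA-256 hashes of every output.
* Problem sizes used by the test suite — n=50 000 test patients for
  recovery/ordering checks, 200×n=5000 for bootstrap coverage, n=20 000
  for the model-pipeline checks — were chosen as the smallest populations
  at which the binomial noise of a 0.4% prevalence still leaves the
  checked contrasts identifiable.

## Known limitations

* With ~0.4% prevalence, definitions built on rare codes (the CSII pump
  codes match ~0.02% of patients) yield single-digit positive counts even
  at n=50 000; their PPV estimates — probabilistic *and* classical — carry
  sampling noise of ±0.1 or more, and their bootstrap intervals are wide.
  This mirrors real validation studies, where the corresponding published
  CI spans ~30 percentage points.
* Sensitivity contrasts of ~0.07 between definitions (basal insulin vs
  confirmed diagnosis) are real but not CI-separable at these case counts;
  their 95% intervals overlap, as they do in comparable published tables.
* The trained-model route inherits whatever miscalibration LightGBM has
  at extreme class imbalance; the calibration-slope warning is the guard
  rail, and an isotonic recalibration step would be the natural extension.
* Boolean definitions only: no negation, no temporal logic ("two codes
  ≥30 days apart"), no visit-count thresholds.
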