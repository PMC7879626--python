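# phenoval

Probabilistic validation of claims-code case definitions for type 1
diabetes (T1D), with a synthetic claims/EHR generator for end-to-end
verification.

## The problem

Epidemiological studies on health-insurance claims need a *case
definition* — a boolean rule over diagnosis, medication and procedure
codes — to identify patients with a target disease. Validating such a rule
normally requires chart review, which is expensive and, when only
rule-positive patients are reviewed, yields PPV but never sensitivity.

The PheValuator approach replaces exhaustive review with a *probabilistic
gold standard*: a gradient-boosted model is trained on a small,
rigorously adjudicated case/control cohort, every test-period patient
receives a predicted probability `p` of being a true case, and a
real-valued confusion matrix is accumulated for each candidate definition:

```
TPs = Σ p       over definition-positive patients
FPs = Σ (1−p)   over definition-positive patients
FNs = Σ p       over definition-negative patients
TNs = Σ (1−p)   over definition-negative patients

sensitivity = TPs/(TPs+FNs)    specificity = TNs/(FPs+TNs)
PPV         = TPs/(TPs+FPs)    NPV         = TNs/(FNs+TNs)
F           = 2·sensitivity·PPV/(sensitivity+PPV)
```

Confidence intervals come from patient-level bootstrap resampling.

The package implements this pipeline for the Japanese-claims T1D setting:
eleven candidate definitions combining the confirmed E10 diagnosis, the
injector-needle procedure code 114010970 (shared with hemophilia
patients), a configurable basal-insulin medication list, and the CSII
syringe-pump codes 114004810/114022010; a five-criterion gold-standard
screen (confirmed diagnosis; insulin + serum CPR < 0.6 ng/ml +
ketoacidosis; positive GAD/IA2 autoantibody; diabetologist referral;
CPR < 0.2 ng/ml); leakage-safe feature construction with relative-risk
top-500 screening; and LightGBM with ten-fold cross-validated AUC.

Because no real hospital data ship with the package, a synthetic
generator (`phenoval.simulate`) produces populations with known latent
T1D/hemophilia status and the statistical structure the study assumes —
including an exact closed-form posterior `P(T1D | codes)` that serves as a
perfectly calibrated scorer in tests.

## Worked example

```python
import pandas as pd
from phenoval import probabilistic_confusion, performance_indexes

scores = pd.DataFrame({"patient_id": ["A", "B", "C", "D"],
                       "p_case":     [0.7,  0.4,  0.9,  0.3]})
conf = probabilistic_confusion(scores, positives={"A", "C"})
print(conf)        # TPs=1.6  FPs=0.4  FNs=0.7  TNs=1.3
est = performance_indexes(conf)
print(f"sens={est.sensitivity:.3f} spec={est.specificity:.3f} "
      f"ppv={est.ppv:.3f} npv={est.npv:.3f} f={est.f_score:.3f}")
```

prints

```
ProbabilisticConfusion(tps=1.6, fps=0.4, fns=0.7, tns=1.2999999999999998)
sens=0.696 spec=0.765 ppv=0.800 npv=0.650 f=0.744
```

i.e. with four test patients — two definition-positive with case
probabilities 0.7 and 0.9, two definition-negative with 0.4 and 0.3 — the
definition's estimated sensitivity is 69.6% and its PPV 80.0%.

## The analysis

The full study is a sequence of numbered drivers over the library:

```bash
python analysis/01_simulate.py             # synthetic train/test populations
python analysis/02_build_cohort.py         # gold-standard cases + controls
python analysis/03_train_model.py          # features, screening, LightGBM, CV AUC
python analysis/04_evaluate_definitions.py # 11 definitions, bootstrap CIs
```

Bulky intermediates go to `scratch/run/`; each step writes its summary
tables under `results/`. The final table mirrors the standard reporting
layout (N, prevalence %, sensitivity, PPV, F-score with 95% CIs, plus
specificity and NPV, which are ≈100% for all definitions at realistic
prevalence). The same pipeline is available as one command
(`phenoval run-all --seed 1 --out run/`) or stage by stage via the
`phenoval` CLI.

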