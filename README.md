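# ctgcompress

Compression-based complexity analysis of simultaneous maternal–fetal
heart-rate signals.

During labor, a fetus with intrapartum oxygen deficit develops acidemia (low
umbilical arterial pH). Fetal heart rate (FHR) is complex and partly
unpredictable, and acidemic fetuses tend to show *less* complex fast
fluctuations and an *altered coupling* to the maternal heart rate (MHR).
`ctgcompress` implements a pipeline that turns paired 4 Hz FHR/MHR recordings
into compression indices and asks which of them discriminate acidemic
(pH < 7.15) from non-acidemic cases. It is aimed at researchers in
physiological signal analysis who want a reproducible, fully synthetic-data–
testable implementation of this family of methods.

## The measures

For a segment `x` (10 minutes of one channel's trend or residual component):

- **Compression ratio** `CR(x) = |x| / |x*|`, the serialized byte length
  over its zlib (DEFLATE) compressed length — high ratio ⇔ high redundancy ⇔
  low information content.
- **Normalized relative compression**
  `NRC(x‖y) = C(x‖y) / (|x|·log2|A|)`, where `C(x‖y)` is the ideal code
  length of `x` under an extended-alphabet finite-context model trained
  exclusively on `y` (the model predicts the next `d = 6` symbols from the
  preceding `k = 6`, over a 20-letter Lloyd-Max alphabet). NRC ∈ [0, 1] is a
  *directional* measure of how much of `x` cannot be described by `y`; the
  pipeline uses `x` = fetal, `y` = maternal.
- **Normalized compression distance**
  `NCD(x, y) = (C(xy) − min{C(x), C(y)}) / max{C(x), C(y)}` with zlib code
  lengths — near 0 for similar, near 1 for unrelated series.

Nine index families (fetal / maternal / maternal-fetal × CR / NRC / NCD) are
computed per segment and per component; the acidemic minority is balanced by
SMOTE (7 originals × 6 replicas → 49 vs 54); classifiers (SVM-RBF by default)
are evaluated with a replica-aware cross-validation that holds out each
original acidemic case *together with all its replicas*; predictions are
pooled over the 7 folds into accuracy, sensitivity, specificity, precision,
F1 and AUC, for nine feature-set tests A–I.

Because no public dataset with simultaneous FHR/MHR and pH labels exists, the
package ships a synthetic cohort generator (slow sinusoid trends, AR(1) fast
noise, acceleration/deceleration bumps, lagged maternal→fetal coupling, and a
tunable acidemia effect) that defines the conditions under which everything
is tested. See `docs/methods.md` for the model, all defaults, and known
limitations — including an augmentation-leakage caveat that matters when
reading absolute performance numbers.

## Worked example

```python
from ctgcompress import (CohortConfig, AugmentationPlan, generate_cohort,
                         cohort_feature_table, augment_table, run_tests)

cfg = CohortConfig(n_nonacidemic=54, n_acidemic=7, effect_size=2.0, seed=7)
cohort = generate_cohort(cfg)                     # 61 paired ~2 h recordings
table = cohort_feature_table(cohort)              # compression indices
table = table.drop(columns=[c for c in table.columns if table[c].isna().any()])
print("feature table:", table.shape)
augmented = augment_table(table, "acidemic", AugmentationPlan(seed=8))
print("after SMOTE:", augmented["group"].value_counts().to_dict())
results, _ = run_tests(augmented, test_ids=["E", "G", "I"], seed=9, cv="custom")
print(results.round(3).to_string())
```

prints

```
feature table: (61, 156)
after SMOTE: {'nonacidemic': 54, 'acidemic': 49}
test              E                                                G                                               I
           accuracy  auc    f1 precision recall specificity accuracy  auc   f1 precision recall specificity accuracy  auc    f1 precision recall specificity
classifier
svm_rbf        0.99  1.0  0.99      0.98    1.0        0.98      1.0  1.0  1.0       1.0    1.0         1.0     0.99  1.0  0.99      0.98    1.0        0.98
```

The feature table has 61 rows (subjects) and 154 index columns plus group and
pH-derived labels; SMOTE grows the acidemic class to 49 against 54. With a
strong planted effect (`effect_size=2`: acidemic fetal fast-noise variance
reduced, maternal→fetal coupling increased), the maternal-fetal feature sets
separate the groups almost perfectly under the replica-aware CV. With
`effect_size=0` the groups are exchangeable by construction — though the
pooled scores stay optimistic because SMOTE runs before cross-validation (see
the leakage note in `docs/methods.md`).

A command-line interface wraps the same stages:

```
ctgcompress simulate --seed 1 --out runs/cohort
ctgcompress run-all --seed 1 --tests E,G,I --classifier svm --out runs/demo
```

`run-all` leaves `features.csv`, `features_augmented.csv`, `metrics.csv`,
per-test ROC points and a checksummed `manifest.json` in the run directory;
identical config and seed reproduce identical files.

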