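# t2select

Attention-based feature selection for small clinical tabular cohorts with a
class-imbalanced binary outcome, built around a differentiable Hotelling
T² objective — together with the evaluation machinery (feature-set ×
classifier benchmark, ROC/calibration/Youden analysis, agreement scoring
against a clinically established feature list) needed to judge a selection.

The motivating application is risk stratification of new-onset persistent
left bundle branch block (NOP-LBBB) after transcatheter aortic valve
replacement (TAVR): a few hundred patients, ~21% event rate, and ~70
mixed-type clinical/echo/ECG/CT variables whose interactions conventional
per-variable statistics miss.  Because such registries are rarely public,
the package ships a synthetic-cohort generator with planted effects so the
entire pipeline is exercisable — and testable — with no data download.

## The method

Every feature becomes a learned d-dimensional token (numeric x ↦ x·wⱼ+bⱼ,
categorical ↦ embedding row); a shared CLS token is prepended and the
sequence runs through a single pre-norm multi-head self-attention block, so
each feature's representation is contextualized by all others.  Training
jointly minimizes

    L_total = L_cls + λ₁·L_stat + λ₂·R

with `L_cls` the binary cross-entropy of a linear head on the encoded CLS
token, `L_stat = −(1/p)·Σⱼ T²ᵣᵢ𝒹ℊₑ(j)` the negative mean per-feature
two-sample Hotelling statistic on the encoded tokens (driving the two
outcome groups apart in representation space), and `R` a token-norm
penalty.  After training, each feature's encoded tokens are tested between
outcome groups with the exact T² and its F-transform,

    T² = (n₀n₁/(n₀+n₁)) δᵀS⁻¹δ,   F = (n₀+n₁−d−1)/(d(n₀+n₁−2))·T²,

and features with p < α (default 5%, per-feature, uncorrected) form the
learned ("OURS") feature set.  The model and its training loop are
implemented on a compact in-package reverse-mode autodiff engine over
numpy; every gradient is validated against finite differences in the test
suite.  See `docs/methods.md` for the full model description, design
choices and limitations.

## Worked example

```python
from t2select import (SelectorHyperparams, generate, study_config,
                      train, compare_selection, agreement_metrics)
from t2select.cohort import apply_preprocessor
from t2select.hotelling import feature_significance

# a study-shaped cohort: 242 patients, 21% events, 69 features,
# 5 of them carrying a standardized shift of 1.0
cohort, truth = generate(study_config(seed=7, effect=1.0))

selector = train(cohort, SelectorHyperparams(epochs=200, seed=7))
prepped = apply_preprocessor(selector.preprocessor, cohort)
report = feature_significance(selector, prepped, alpha=0.05)

planted = {cohort.schema.names[i] for i in truth.informative_indices}
m = compare_selection(set(report.selected),
                      set(cohort.schema.domain_knowledge),
                      set(cohort.schema.names))
```

Output (exact values for these seeds):

```
cohort: n=242, p=69, prevalence=0.21
L_cls 0.6935 -> 0.5075, L_stat -4.12 -> -393.24
selected 69/69 features; top-5 by T2: ['bin_050', 'bin_057', 'bin_053', 'bin_059', 'cat_065']
planted features recovered: 5/5
agreement vs DK: tp=26 fp=43 fn=0 tn=0 (accuracy 37.68%, recall 100.00%)
```

Reading this: training reduces the classification loss while driving the
mean per-feature T² (−L_stat) up by two orders of magnitude, and all five
planted features are recovered.  Two caveats are deliberately visible.
First, with a strong planted signal, attention mixing spreads group
separation into *every* token, so thresholding p-values alone saturates the
selection (69/69) — on null cohorts the same test selects ≈5% of features,
as it should (see the calibration study below).  Second, prolonged
optimization of the separability objective inflates T² for the easiest
tokens to separate (here the discrete-valued binary features), so the
ranking should be read early in training or via the planted-vs-null
contrast the recovery study reports.

The same pipeline is available from the shell:

```bash
t2select simulate --out run/ --seed 7
t2select train    --cohort run/cohort.csv --schema run/schema.yaml \
                  --out run/ --seed 7 --epochs 3500
t2select select   --selector run/selector.npz --cohort run/cohort.csv \
                  --schema run/schema.yaml --out run/
t2select benchmark --cohort run/cohort.csv --schema run/schema.yaml \
                  --ours run/ours_features.txt --out run/
t2select compare  --selected run/ours_features.txt --schema run/schema.yaml \
                  --cohort run/cohort.csv --out run/
```

`benchmark` writes a per-(model × feature-set) table of accuracy / recall /
precision / F1 means ± sd over five stratified 70/30 splits (inner 5-fold
CV for hyperparameters), pooled ROC points, calibration bins, and the
Youden-J operating point; `compare` writes the 2×2 agreement matrix of the
selection against the schema's domain-knowledge flags plus an unpenalized
logistic-regression comparator with Wald tests.

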