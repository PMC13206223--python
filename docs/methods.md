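# Methods

## Problem setting

`t2select` addresses feature selection for a class-imbalanced binary
clinical outcome — concretely, new-onset persistent left bundle branch
block (NOP-LBBB) after transcatheter aortic valve replacement (TAVR) — from
a small tabular cohort of mixed-type clinical, echocardiographic,
electrocardiographic and CT-derived variables.  The premise is that
pairwise and higher-order interactions among anatomical and procedural
variables matter, so per-feature relevance is judged not on the raw column
but on a learned, context-enriched representation of it.

## Model

Each preprocessed feature j is mapped to a d-dimensional token:

* numeric / binary feature with value x:  `t_j = x · w_j + b_j`
* categorical feature with code c:  `t_j = E_j[c]` (per-category embedding)

A shared learned CLS token is prepended and the sequence of p+1 tokens
passes through `n_layers` pre-norm transformer blocks (multi-head
self-attention, feed-forward expansion 4, residual connections, no
dropout).  There are **no positional encodings**: features are nominal and
each token carries its identity through its own parameters, which makes the
encoder exactly equivariant under feature permutations — a property the
test suite checks both at the encoder level and end-to-end (permuting the
schema permutes per-feature statistics and leaves logits unchanged).

Training minimizes

```
L_total = L_cls + λ1·L_stat + λ2·R
```

* `L_cls`: binary cross-entropy of a linear head on the encoded CLS token.
* `L_stat = −(1/p) Σ_j T²_ridge(j)`: the negative mean per-feature
  Hotelling T² between outcome groups, computed on the encoded feature
  tokens with a ridge-regularized pooled covariance
  `(S_j + ε I)⁻¹`, ε = `ridge` = 1e-3.  Descent on `L_stat` *increases*
  group separability of the representations.
* `R`: the mean squared L2 norm of the encoded tokens.  The exact T² is
  scale-invariant, but the ridge-regularized version grows as
  representations are inflated (scaling tokens by c turns ε into ε/c²), so
  without `R` the optimizer could buy separability by blowing up the
  representation scale.

The two named coefficients are assigned as λ1 → statistical loss and
λ2 → norm regularizer, with the classification loss unit-weighted (the
conventional reading when a task loss is combined with auxiliary terms);
both default to 1e-5 and are independently configurable, so the alternative
reading (λ-weighting the classification loss) is reproducible by rescaling.

Optimization is full-batch Adam (β = 0.9/0.999, eps 1e-8) at learning rate
1e-4 for 3500 epochs by default.  All parameter initialization
(normal, sd 0.02; LayerNorm gains 1, biases 0) is drawn from a single
seeded generator, so training is deterministic given (cohort,
hyperparameters, seed).

### Post-training selection

After training, the full cohort is encoded once and each feature's n
d-dimensional token vectors are split by outcome and tested with the exact
two-sample Hotelling T²:

```
T² = (n0·n1/(n0+n1)) · δᵀ S⁻¹ δ,   S = pooled covariance (n0+n1−2 denominator)
F  = (n0+n1−d−1)/(d·(n0+n1−2)) · T²  ~  F(d, n0+n1−d−1) under H0
```

The post-hoc test uses ε = 0 (pseudo-inverse fallback when the covariance
is numerically singular, dropping singular values below 1e-10 of the
largest, with the result flagged).  Selection is at a per-feature
significance level α = 0.05 with **no multiplicity correction** — this is
the headline selection rule; Bonferroni and Benjamini–Hochberg adjusted
p-values are reported alongside for transparency.  When the F degrees of
freedom are invalid (n0+n1−d−1 < 1) a seeded permutation p-value
`(1 + #{T²_perm ≥ T²_obs})/(n_perm+1)` is the documented fallback.
Selection is performed on the single full-cohort fit (one learned feature
set, even though the classifier benchmark uses five resampling splits);
per-split selection stability can be obtained by rerunning `select` on
split subsets.

### Numerical engine

No deep-learning framework is used: the package carries a compact
reverse-mode automatic-differentiation engine over numpy arrays
(`t2select._autodiff`) implementing exactly the operations the model needs,
including a batched inverse quadratic form `δᵀ(S+εI)⁻¹δ` with analytic
gradients (`∂/∂δ = 2(S+εI)⁻¹δ`, `∂/∂S = −yyᵀ` for symmetric S).  Every
vector-Jacobian product is validated against central finite differences,
and the joint loss gradient is checked end-to-end to 1e-4 relative error.
Training runs in float32 by default (float64 available via
`SelectorHyperparams.dtype`, and used for all gradient-check tests); the
engine is careful to keep python-float constants from upcasting a float32
graph.  `train()` also raises glibc's malloc mmap threshold so the large
attention buffers are recycled rather than re-faulted every epoch — on a
single CPU this roughly halves the epoch time.

## Synthetic cohorts

The generator emulates the shape of the study population, since the
clinical registry itself is not publicly deposited: 242 patients, 21%
event rate, 69 candidate features (45 numeric, 18 binary, 6 three-level
categorical) spread over clinical / echo / ecg / ct / procedural groups,
with a designated 26-member domain-knowledge (DK) subset.  The total of 69
candidates is the unique count consistent with the published agreement
metrics of the reference analysis (12+8+14+35).

Generation is outcome-first: `y ~ Bernoulli(0.21)`, then features drawn
class-conditionally.  Numeric features are multivariate normal with block
equicorrelation (blocks of 5 at ρ = 0.3, loosely mimicking correlated CT
anatomy measures) and receive a standardized mean shift `effect · y` where
informative; binary and categorical features receive a log-odds shift of
their baseline rates in the event class.  The default planted set is 5
numeric features at effect 1.0, overlapping the DK subset.  A `logistic`
mode instead draws the outcome from a linear predictor over the planted
features (intercept bisected to hit the target prevalence), which is the
more realistic setting for classifier benchmarking.

What the generator does **not** emulate: missingness (the loader rejects
missing cells; real registries require imputation), site/batch effects,
non-linear or interaction-only effects, measurement error correlated with
outcome, and the marginal distributions of the real variables.  Passing
tests on these cohorts therefore demonstrate internal statistical
correctness and recovery behavior under known signal, not clinical
performance.

## Evaluation harness

Three feature sets — ALL (every candidate), DK (schema-flagged), OURS (the
learned selection) — are compared through seven conventional classifiers
(logistic regression, decision tree, random forest, SVM with probability
outputs, LDA, QDA, gradient boosting) under five fixed-seed stratified
70/30 splits.  Preprocessing (sample-sd z-scoring, label encoding) is
fitted on each training split only; a leakage-guard test verifies that
perturbing held-out rows leaves fitted coefficients unchanged.  Per-model
hyperparameters are tuned by inner stratified 5-fold cross-validation
maximizing positive-class F1 — accuracy would select degenerate
majority-class models at 21% prevalence.  Metrics are positive-class
accuracy/recall/precision/F1 in percentage points, means ± sd over
repeats, with the per-seed raw table retained so the aggregation is
recomputable.  ROC/AUC (trapezoidal, equal to the Mann–Whitney
concordance), equal-width calibration bins, and the Youden-J optimal
threshold (candidates at midpoints of sorted unique scores; lowest
maximizer on ties) are computed on test scores pooled across seeds.

The agreement analysis scores any selection against the DK set over the
candidate universe as a 2×2 matrix and the standard four metrics.  The DK
membership is schema data, not code: for synthetic cohorts it is the
generator's `dk_indices`.  The conventional comparator is a single
unpenalized all-features logistic regression with Wald per-coefficient
tests; with p = 69 close to n = 242 and correlated blocks this fit is
typically unstable (quasi-separation, inflated standard errors) and is
returned flagged — the mechanism by which such a baseline selects nothing.

## Validation studies and problem sizes

* **Type-I calibration**: null cohorts (242×69, zero effects) encoded by
  randomly initialized selectors; fraction of features selected at
  α = 0.05, averaged over 200 replicates, compared against the binomial
  95% band `0.05 ± 1.96·√(0.05·0.95/200)`.  Replicates — not features —
  are the independent trials, because per-feature decisions within one
  replicate share an encoding and are strongly correlated.  The observed
  rate sits slightly below α (mild conservatism from non-normal encoded
  coordinates), inside the band.
* **Planted recovery**: cohorts with 5 informative of 69 features at
  standardized effect 1.0; the selector is trained (40 epochs per
  replicate, 20 replicates in `scripts/acceptance.py` — sizes chosen to
  keep the full study in the minutes range on one CPU; the training
  dynamics at the default 3500 epochs are available through the CLI) and
  the learned set scored against ground truth.  Mean per-feature T² is
  strictly larger for planted than for non-planted features in essentially
  every replicate; recall of the planted set is reported.
* A caveat worth knowing: attention deliberately mixes features, so when a
  strong low-dimensional signal is present, *every* encoded token carries
  some group separation and per-feature selection can saturate (high
  recall, low specificity against the planted set).  The planted-vs-null
  T² ordering remains informative; users who need a sparser set should
  rank by T² rather than threshold on p alone.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| `d_token` | 32 | token embedding width |
| `n_layers` / `n_heads` | 1 / 8 | encoder depth / attention heads |
| `lr`, `epochs` | 1e-4, 3500 | full-batch Adam schedule |
| `lambda1`, `lambda2` | 1e-5, 1e-5 | statistical loss / norm penalty weights |
| `ridge` | 1e-3 | covariance ridge inside the differentiable T² |
| `posthoc_ridge` | 0 | ridge of the post-training exact test |
| α | 0.05 | per-feature selection level, uncorrected |
| sd convention | n−1 | matches the pooled-covariance denominator |

Degenerate inputs are rejected loudly rather than patched: constant numeric
columns, single-class outcomes, groups smaller than 2, missing cells,
unknown category labels, non-finite values.  Ties in the selection ordering
break by feature name; ties in the Youden scan by the lowest threshold.

## Known limitations

* The F-based p-values assume approximate multivariate normality of the
  encoded tokens; calibration is verified empirically on the synthetic
  nulls but not guaranteed for arbitrary real data.
* The single full-cohort selection fit maximizes data use but cannot
  quantify selection stability by itself.
* No missing-data handling, no multi-site harmonization, no image
  ingestion — CT/echo variables must arrive as precomputed numbers.
* Class imbalance is handled only through metric choice (F1 selection),
  not through reweighting or resampling.
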