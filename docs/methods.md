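# Methods

## Problem and model

The package predicts miRNA–disease associations as a supervised bipartite
link-prediction task. The observed network is a binary adjacency matrix
A (nm × nd); row i is the interaction profile of miRNA mᵢ, column j that of
disease dⱼ. The modelling assumption throughout is *guilt by association*:
miRNAs with similar disease profiles (and similar curated function), and
diseases with similar miRNA profiles (and nearby ontology terms), tend to
share associations.

## Similarity stage

**Semantic similarity.** Each disease is represented by its ancestor
closure G(d) in a child→parent ontology DAG, with induced edges E(d). Two
contribution weightings are combined:

- decay scheme: the disease's own term contributes 1 and each ancestor k
  contributes `μ · max{C1(k′) : k′ child of k within E(d)}` with μ = 0.5.
  The max over children restricted to the closure's induced DAG makes
  C1(k) = μ^(shortest ancestor-path length d→k), which the test suite
  verifies against an independent shortest-path oracle.
- information-content scheme: `C2(k) = −log(NG(k)/nd)` where NG(k) counts
  the disease closures containing k; shared across diseases, so common
  ancestors near the root contribute little. The logarithm base defaults
  to e and is configurable (the similarity ratio is base-invariant only
  when numerator and denominator use the same base, which the code
  guarantees).

A pair score is `Σ_{k ∈ G(di) ∩ G(dj)} (C_di(k) + C_dj(k)) / (DS(di) +
DS(dj))` with DS the per-disease contribution sum; the final semantic
similarity is the mean of the two schemes. Diseases absent from the
ontology get *missing* rows rather than zeros, so the integration step can
distinguish "no shared ancestry" (0) from "unknown" (fallback to GIP). A
degenerate information-content denominator (every closure term present in
all closures) is resolved as 1 on the diagonal and 0 off it.

**GIP kernels.** `KS(i,j) = exp(−α‖IP_i − IP_j‖²)` with bandwidth
`α = α′ / mean‖IP‖²` and α′ = 1 for both sides. The kernel is computed
from whichever adjacency matrix is passed in; leave-one-disease-out
protocols recompute it after masking (see below). GIP similarities are by
default computed once from the full training network rather than per CV
fold; the stricter per-fold protocol can be wired by the caller since the
similarity stage is a pure function of the adjacency matrix.

**Integration.** MS = (MFS + KSM)/2 where functional similarity exists,
KSM otherwise; DS likewise from semantic and disease-GIP similarity.

## Feature and sampling stage

Pair (i, j) → `[MS_i | A·j | DS_j | A_i·]`, 2·nm + 2·nd columns; block
extents are recorded in the feature-set layout. Note the pair's own entry
A(i,j) appears in blocks 2 and 4: with `mask_target=False` (default) the
construction is reproduced literally, which leaks the label into its own
feature vector; with `mask_target=True` both occurrences are zeroed. All
recovery benchmarks and case studies in this package run with masking ON —
unmasked scores measure little beyond the leak. Negatives are sampled
uniformly without replacement from the zero entries, one per positive.
Splits are stratified: 8:2 train/test, then 4-fold CV on the training part.

## Compression stage

Three greedy autoencoders (tanh encoder, linear decoder) with code widths
1024/512/256 for the canonical 1756-column input; each layer is trained by
Adam (β₁ 0.9, β₂ 0.999, lr 1e-3, batch 128) on the summed squared
reconstruction error, then frozen, and the next layer fits its codes.
Numerical choices that matter:

- **Input standardization.** Features are z-scored with training-set
  statistics before the autoencoder. Without it the reconstruction
  objective is dominated by the high-variance similarity blocks and the
  codes discard the low-variance adjacency structure carrying most of the
  association signal (measured: held-out AUC 0.79 unstandardized vs 0.97
  standardized on the recovery benchmark).
- **Width capping, not proportional shrinking.** For inputs narrower than
  1024 columns each code width is capped at the input width, so the final
  code keeps its absolute 256 dimensions whenever the input affords it.
  Shrinking codes proportionally to the input (e.g. 400 → 58) provably
  destroys the signal at benchmark scale: even an optimal 58-dimensional
  linear compression (PCA) loses ~0.2 AUC, while 256 components are nearly
  lossless.
- **Epochs.** Default 100; at 50 the reconstruction loss has not plateaued
  on benchmark-scale data and downstream AUC drops by ~0.18. The per-layer
  loss trajectory is kept in the stack's training log.
- The decoder is linear: inputs are standardized (unbounded), codes are in
  (−1,1); a linear readout reconstructs both. Training is plain numpy,
  single-threaded, bit-reproducible given (data, seed, hyperparameters).

The standardizer and stack are fitted on training features only; test data
is transformed with the frozen pair.

## Cascade stage

Each level: random forest, completely random tree forest (extra-trees with
single-feature splits), XGBoost and LightGBM, 100 trees each. Every
estimator is fitted as 5 stratified fold-models; training samples receive
the class-probability pair from the fold-model that excluded them
(out-of-fold), giving 8 augmented columns (estimator order fixed, class
order [P(0), P(1)]). New data receives the mean over the 5 fold-models.
Level t consumes `[codes | level t−1's 8 columns]`.

Growth control: 20% of the training data is carved off (stratified) as a
validation set; a level is kept if its averaging-predictor validation AUC
beats the best by > 1e-3 (tol), growth stops after 1 non-improving level
(patience) or 10 levels, and the model rolls back to the best depth. These
three constants are exposed in the config; the recorded validation metric
of the returned model is the maximum over trained levels by construction.

Predictors: the default head is an SVM with the inhomogeneous cubic
polynomial kernel `(γ⟨x,x′⟩ + 1)³` (C = 1, γ = 'scale', probabilities via
internal cross-validated sigmoid calibration) fitted on `[codes | 8
augmented columns]`, using OOF augments for growth rows and fold-averaged
augments for validation rows. coef0 = 1 rather than 0 because the
homogeneous kernel is nearly constant on small-scale codes and underfits
(measured ~0.05 AUC difference on codes alone). `svm_input:
augmented_only` restricts the SVM to the 8 augmented columns. Ablation
modes: `model2` replaces the SVM by the mean of the four positive-class
probabilities; `model1` additionally swaps the estimator bank for the
classic two random forests + two completely random forests.

All fold assignments, estimator seeds and the SVM seed derive from the one
config seed, so a full run is bit-reproducible single-threaded.

## Evaluation

Threshold metrics at 0.5 (accuracy, precision, sensitivity, specificity,
MCC with the 0/0 → 0 convention, F1), ROC AUC (tie-aware trapezoidal,
equal to Mann–Whitney with ties counted ½) and AUPR (step-wise summation /
average precision). The protocol reports four fold rows, their mean and
one test row. The case study zeroes the held-out disease's column, drops
its pairs from the labeled pool (they are scoring targets, not training
negatives), recomputes GIP/MS/DS from the masked matrix, retrains, scores
all nm candidate pairs and returns the top k with ties broken by miRNA id.
Because the column is zeroed before any similarity or feature computation,
the scores provably contain no information from the held-out column (the
test suite verifies this by permuting the column and checking the ranking
is unchanged).

This strictness has a measurable consequence on synthetic data: once its
column is zeroed, the held-out disease is identifiable only through its
semantic-similarity row, and the synthetic ontology is generated
independently of the planted latent factors — so under the strict protocol
the top-k candidates are *not* enriched for true associations (enrichment
≈ 1× base rate, as information theory demands). The
`reuse_global_similarity` option reproduces the laxer protocol that
computes similarities once from the unmasked network; the held-out disease
then keeps its label-derived GIP profile and enrichment rises to ~1.6–1.9×
base rate at benchmark scale. Published case-study hit counts obtained
under global-similarity protocols should be read with this leak in mind;
on real data the ontology row is genuinely informative (disease ancestry
correlates with shared miRNA involvement), which the random synthetic
ontology deliberately does not model.

## Synthetic data and what it shows

The generator emulates: a random ontology forest (each term takes 1–2
parents among earlier terms, ~10% extra roots); associations
`A(i,j) ~ Bernoulli(σ(s·U_iᵀV_j + b))` with latent factors of per-entry
variance 1/rank (unit-variance latent dot products) and b calibrated by
bisection to the target density; functional similarity
`(1 + cos(U_i,U_j))/2` with a symmetric random subset of off-diagonal
pairs masked missing.

The recovery benchmark uses 120 miRNAs × 80 diseases, rank 5, density
0.10, signal 6, 20% missing functional entries, masking on — sizes chosen
so a complete 4-fold CV plus test evaluation runs in minutes on one CPU
while the planted signal stays clearly recoverable (the Bayes-optimal AUC
on the balanced sample under these conditions is ≈ 0.93). Under these
conditions the pipeline reaches ≈ 0.86 mean CV AUC and ≈ 0.97 test AUC,
the SVM head beats the classic averaging cascade by ≈ 0.2 AUC, and
permuted labels land at chance.

What passing these benchmarks does *not* show: real miRNA/disease data has
heavy-tailed degree distributions, correlated curation bias (well-studied
diseases have denser rows), and an ontology whose depth and fan-out differ
from the synthetic forest; absolute metric values on real data will
differ. The benchmarks validate the machinery (similarity math, masking
hygiene, compression, cascade growth, calibration), not clinical
performance.

## Known limitations

- The unmasked feature construction (default off in benchmarks, available
  for literal reproduction) contains the target entry; metrics computed
  with it are optimistic.
- The SAE sees only the training split of each fit; across CV folds the
  smaller fits can be slightly undertrained at fixed epoch count, which is
  visible as fold-to-fold AUC spread.
- MeSH XML / OBO parsing is out of scope; ontologies arrive as TSV edge
  lists, and the disease-name → term mapping is caller-provided.
- GIP-per-fold recomputation inside cross-validation is not wired into
  `run_protocol` (global-GIP default); the case-study path does recompute
  after masking.
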