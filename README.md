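# cfsaemda

Prediction of miRNA–disease associations from a known-association network,
a disease ontology and miRNA functional similarity.

MicroRNAs regulate gene expression and their dysregulation is implicated in
many diseases, but experimentally validating individual miRNA–disease links
is slow and expensive. Given a verified-association matrix **A** (nm miRNAs ×
nd diseases), this package ranks the unverified pairs so that laboratory
effort can be focused on the most plausible candidates.

## Method

1. **Similarity fusion.** Disease semantic similarity is computed over each
   disease's ancestor closure in the ontology DAG with two schemes — a
   decay-based contribution `C1_d(d)=1`, `C1_d(k)=μ·max{C1_d(k′): k′ child of
   k}` (μ=0.5), and an information-content contribution
   `C2(k)=−log(NG(k)/nd)` — scoring a pair by the shared-term contribution
   sum normalised by the two semantic values, then averaging the schemes.
   Both miRNAs and diseases additionally get Gaussian interaction-profile
   (GIP) kernel similarity `KS(i,j)=exp(−α‖IP_i−IP_j‖²)` with
   `α = α′ / mean‖IP‖²`, α′=1. Integrated similarities **MS** / **DS** are
   the mean of functional/semantic and GIP similarity where the former
   exists, and the GIP kernel alone where it is missing.
2. **Pair features.** A pair (mᵢ, dⱼ) is the concatenation
   `[MS row i | A column j | DS row j | A row i]` — 2·nm + 2·nd values
   (1756 at the canonical 495 × 383 scale). All 5430 known pairs are
   positives; an equal number of unknown pairs is sampled as negatives
   (10,860 samples).
3. **Compression.** A greedy stacked autoencoder (tanh encoders, linear
   decoders, Adam on summed squared reconstruction error) maps the features
   through codes of width 1024 → 512 → 256.
4. **Classification.** A cascade forest: each level holds a random forest,
   a completely random tree forest, XGBoost and LightGBM (100 trees each,
   400 per level), producing out-of-fold class-probability vectors (8 per
   level) that augment the features of the next level. Depth is chosen by
   validation AUC with rollback. The final predictor is a polynomial-kernel
   SVM on `[codes | augmented block]` with calibrated probabilities.

Evaluation follows an 8:2 train/test split with stratified 4-fold
cross-validation on the training part (accuracy, precision, sensitivity,
specificity, MCC, F1, AUC, AUPR), and a leave-one-disease-out case-study
mode that retrains without a disease's column and ranks its candidate
miRNAs.

A synthetic-data module generates all three inputs (random ontology forest,
planted low-rank Bernoulli associations, latent-factor functional
similarity with missing entries), so the pipeline is fully testable without
any database access.

## Worked example

```bash
cfsaemda simulate --nm 30 --nd 20 --rank 3 --density 0.25 --signal 4 --seed 0 --out-dir demo
cfsaemda similarity --assoc demo/associations.tsv --ontology demo/ontology.tsv \
    --mfs demo/mfs.sim.tsv --out-dir demo
```

```
wrote 151 associations over 30 x 20 to demo
wrote MS (30 x 30) and DS (20 x 20) to demo
```

```bash
cat > demo/eval.yaml <<'YAML'
seed: 0
synthetic: {nm: 30, nd: 20, rank: 3, density: 0.25, signal: 4.0}
mask_target: true
sae_epochs: 20
trees: 20
YAML
cfsaemda evaluate --config demo/eval.yaml --out-dir demo/eval
```

```
mean CV AUC 0.7125, test AUC 0.8756
```

The mean CV AUC is averaged over the four training folds; the test AUC is
from the single fit on the full training split scored on the held-out 20%.
At this miniature scale (151 positives) the scores are modest; at the
default benchmark scale (120 × 80, signal 6) the pipeline reaches a test
AUC around 0.97 (see below). `demo/eval/metrics.json` holds the full
per-fold table and `run_log.json` the resolved configuration and seeds.

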