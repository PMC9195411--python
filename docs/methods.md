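# Methods

## Feature construction

Input is a probe-level beta matrix (samples × probes, values in [0, 1],
missing allowed), a probe manifest with CpG-island assignments, and sample
metadata. Island membership is taken as given input; no annotation source
is bundled. Internally coordinates are 0-based; BED-like manifests are read
as 0-based half-open and CSV manifests as 1-based (shifted on read).

Probes not assigned to CpG islands are removed. Remaining probes are
chained per chromosome by single linkage on sorted positions: a chain
extends while the gap to the previous probe is at most `max_gap`
(default 100 bp, **inclusive** — a gap of exactly 100 joins). Single
linkage is the reading consistent with concatenating probes that map within
100 bp of each other; a complete-linkage reading (whole-span ≤ 100 bp) was
rejected because chaining, not bounded span, is what concatenation
produces. The implementation is verified in the test suite against an
O(n²) union-find transitive closure of the pairwise "same chromosome and
within `max_gap`" relation.

Chains with fewer than `min_probes = 4` members are eliminated (i.e.
clusters of 3 CpGs or less are dropped); the count is of member *probes*,
since per-probe CpG-site counts are not part of the manifest schema. Each
surviving cluster becomes one feature: the arithmetic mean of its members'
non-missing betas per sample, missing only if every member is missing.

On real 450K data this recipe yields on the order of 2.5 × 10⁴ cluster
features; the exact count depends on the manifest release and island
annotation and is treated as cohort-specific, not as a contract.

## Leakage-safe normalization

Normalization is strictly per-sample: values are clipped to [0, 1] (betas
are already fractions, so anything beyond clipping would be speculative)
and remaining missing entries are imputed with the sample's own mean over
non-missing features. No statistic crosses sample boundaries, so a sample's
feature vector is bit-identical whether it is processed alone or inside any
cohort — the property that makes train/validation/test isolation exact.
(Implementation note: column sub-matrix reductions are forced C-contiguous
so floating-point summation order cannot differ with cohort size.)

## Network and loss

Encoder: input → dense ReLU layer (`hidden_size`, default 1000) → two
activation-free projection heads giving the posterior mean μ and
log-variance log σ² of a diagonal Gaussian over the latent layer
(`latent_size`, default 100). The two heads are the only reading of a pair
of activation-free layers feeding a probabilistic latent layer that is
consistent with a VAE. Training samples z = μ + σ ⊙ ε (reparameterization);
inference uses z = μ, giving deterministic predictions.

Decoder: z → dense ReLU (`hidden_size`) → sigmoid output over the features,
clamped to [1e-7, 1 − 1e-7] for log safety. Classifier: z → dense ReLU
(`classifier_hidden`, default 100) → softmax over `n_classes` (default 34).

Per-sample loss:

    L = w_vae · (recon + β · KL) + w_clf · CE

* `recon` — element-wise binary cross-entropy between input and
  reconstruction, summed over features by default (`recon_reduction`
  switches to a per-feature mean, which rescales the effective VAE weight).
  Binary rather than per-vector softmax cross-entropy is the standard idiom
  for sigmoid-output VAEs on [0, 1] data.
* `KL` — closed form ½ Σ (μ² + σ² − 1 − log σ²) against N(0, I); β = 1 by
  default (β > 1 would give a disentangling regime; supported, untuned).
* `CE` — categorical cross-entropy on the softmax output.
* Weights default to w_vae = 0.01, w_clf = 1.

The batch loss is the mean of per-sample losses (batch-size-independent
learning rate). Parameters are initialized with seeded Glorot-uniform
draws, biases at zero. Forward and backward passes are hand-written numpy;
the analytic gradients are validated against central finite differences
(relative error ≤ 1e-4) in both the sampled and deterministic paths.

## Splitting, deduplication and training

Samples are split 80/10/10 by the largest-remainder method, stratified by
class label by default because rare classes would otherwise risk empty 10%
slices; an unstratified mode exists. Metastatic and recurrent samples are
excluded from splitting — they are evaluation-only. The training set is
then deduplicated so no patient contributes more than one sample: one of
each matched set is kept at random, and every removed sample is replaced by
a uniformly drawn unused same-class sample when one exists (otherwise the
slot stays unfilled).

Training uses Adam at learning rate 0.001, batch size 128 (unspecified
upstream; chosen to fit desk memory at full feature width), monitoring
plain multiclass validation accuracy with ties broken toward the earliest
epoch. Early stopping halts after `patience_epochs` (default 50)
consecutive epochs without improvement; with patience 0 the loop still
requires one non-improving epoch before stopping, so the epochs trained
past the best epoch never exceed max(patience, 1). A hard cap of 2000
epochs bounds non-converging runs. The returned parameters are those of the
best validation epoch, and the whole run — initialization, shuffling,
latent sampling, splits — is a deterministic function of the data and one
seed.

## Evaluation

Confusion matrices and per-class precision/recall/F1 are computed with
scikit-learn conventions (zero-division cases score 0 and are flagged).
The weighted F-measure Σ_c support_c · F1_c / Σ_c support_c is the headline
aggregate under class imbalance; macro F is the unweighted mean.
Misclassification profiles normalize off-diagonal confusion rows by class
support.

## Latent analysis

Embeddings are posterior means — a pure function of (trained state,
features). 2-D projections (t-SNE, default perplexity 30, or PCA as a
deterministic linear fallback) are for visualization only and never feed
metrics. Separability of a binary annotation is measured in the *full*
latent space by tenfold stratified cross-validated accuracy of a linear
SVM (C = 1.0, chosen as the standard default; the linear kernel is the
point — it tests linear separation, not flexible discrimination). Seeds fix
fold assignment and projections.

## Synthetic corpus

The generator emulates what the method assumes about real cohorts:

* **Manifest** — islands with within-island gaps of 10–100 bp and
  between-island gaps of 400–800 bp, so the expected cluster decomposition
  is known by construction; decoy non-island probes sit mid-gap (≥ 200 bp
  from any island) to exercise the island filter.
* **Cohort** — each cancer class hypermethylates a disjoint signature
  subset of islands (default 12.5% of islands per class); probe betas come
  from Beta(8, 2) (mean 0.8) on hypermethylated islands and Beta(3, 17)
  (mean 0.15) elsewhere — bounded, unimodal, moderately dispersed modes
  echoing the bimodality of real beta values, strong enough to be learnable
  without being degenerate. NORM carries no signature. 10% of samples form
  patient-matched pairs. An optional binary subtype hypermethylates an
  extra island set in the second half of every class, invisible to the
  class labels.
* **Variants** — metastasis-like samples keep their class signature but add
  N(0, 0.1) dispersion (clipped) and are flagged metastatic; age-drift
  subtracts 0.05 from NORM samples (clipped at 0), emulating global
  age-related hypomethylation.

What the generator does *not* emulate: array chemistry, batch effects,
probe cross-reactivity, realistic chromosomal structure, or the continuum
of tumor purity. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that its guarantees (leakage-freedom,
reproducibility, early stopping, separability measurement) hold — not that
the model reaches any particular accuracy on real tumors.

## Problem sizes and numerical choices

The standard test-scale study uses 8 classes × 100 samples over 400 islands
with a 400-feature, hidden-128, latent-16, classifier-hidden-32 network —
large enough for non-trivial structure, small enough that a full
generate → preprocess → train → evaluate cycle takes seconds on one CPU.
Reconstruction clamps use ε = 1e-7; the probe-chaining boundary is
inclusive; zero-division metrics return 0 with a flag; all-missing sample
vectors are rejected rather than silently imputed.

## Known limitations

* No GPU path; training is minibatch numpy on CPU, adequate at analysis
  scale but slow at the full 2.5 × 10⁴-feature width with large cohorts.
* The checkpoint format stores raw float64 arrays; no quantization or
  cross-version migration beyond a schema version field.
* t-SNE determinism holds for a fixed seed, library version and platform.
* The generator's disjoint signatures make classes easier to separate than
  real developmental-lineage-sharing tumors; hierarchical signature overlap
  is available (subtype islands) but misclassification structure is only
  qualitatively realistic.
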