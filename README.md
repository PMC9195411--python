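# methylnet

A hybrid variational-autoencoder / classifier for pan-cancer
tissue-of-origin prediction from Illumina-450K-style DNA methylation beta
values, together with the full surrounding pipeline: CpG-island probe
clustering, leakage-safe preprocessing, patient-aware dataset splitting,
evaluation, latent-space analysis and a synthetic-data generator that makes
every stage testable without any external download.

## Who this is for

Computational epigenomics groups who want a classifier of tumor tissue of
origin (33 TCGA cancer classes plus a normal class) that also produces a
structured latent representation of the samples — usable for subtype
exploration, separability testing and downstream integration — rather than
a bare prediction.

## The model

Input features are per-cluster average beta values: 450K probes outside CpG
islands are removed, the remaining probes are chained whenever consecutive
positions lie within 100 bp, chains with 3 or fewer probes are eliminated,
and each surviving cluster's betas are averaged.

The network is a VAE with a classifier head. The encoder maps a feature
vector *x* through a ReLU hidden layer to a diagonal-Gaussian posterior
*q(z|x) = N(μ(x), diag σ²(x))* over a latent layer; the decoder maps *z*
back to reconstructions *x̂* through a ReLU layer and a sigmoid output; the
classifier maps *z* through a ReLU layer to a softmax over classes. Training
draws *z* by the reparameterization trick and minimizes the joint loss

    L = w_vae · ( BCE(x, x̂) + β · KL(q(z|x) ‖ N(0, I)) ) + w_clf · CE(y, ŷ)

with β = 1, w_vae = 0.01, w_clf = 1, using Adam (learning rate 0.001) and
early stopping after 50 epochs without validation-accuracy improvement.
Inference classifies at the posterior mean *z = μ(x)*. The network, its
analytic gradients and the optimizer are implemented directly in numpy.

Performance is summarized by the weighted F-measure (support-weighted mean
of per-class F1 — the right aggregate under heavy class imbalance), with
macro F, per-class precision/recall/F1 and confusion matrices alongside.
Latent structure is quantified by tenfold cross-validated linear-SVM
accuracy in the full latent space.

## Worked example

```bash
python examples/02_train_and_evaluate.py
```

generates a synthetic cohort of 8 classes (7 cancers + NORM, 100 samples
each) whose classes hypermethylate disjoint sets of CpG islands, builds
400 cluster features, splits 80/10/10 with patient deduplication, trains a
latent-16 model and prints:

```
stopped at epoch 56, best epoch 6 (validation accuracy 1.000)
test weighted F-measure: 1.000
test macro F-measure:    1.000
```

Early stopping halted the run 50 epochs after the best validation epoch;
on the held-out 10% the classifier recovered every class label. The other
examples cover feature construction (`01`), latent-space subtype
separability with a permutation control (`03`), and robustness to
age-drift hypomethylation and metastasis-like dispersion (`04`).

The same stages are available from a shell via the `methylnet` CLI
(`synth`, `validate`, `preprocess`, `train`, `evaluate`, `latent`); see
`methylnet --help`.

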