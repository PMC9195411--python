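"""Latent-space extraction and analysis.

Samples are embedded at the encoder's posterior mean (a deterministic,
pure function of the trained state and the features).  Two complementary
views are offered:

* a seeded 2-D projection (t-SNE, or PCA as a deterministic linear
  fallback) for visualization-style exports — decorative only, never used
  for metrics;
* cross-validated linear-SVM accuracy on the *full* latent space, the
  quantitative separability measure for any binary sample annotation
  (subtype, body site, methylator phenotype, ...).  A linear kernel is
  deliberate: high accuracy means the two groups are linearly separated in
  the latent representation, not merely distinguishable by a flexible
  decision surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .io import BetaMatrix
from .model import NetworkState, encode
from .preprocess import ClusterFeatureMatrix


@dataclass
class LatentEmbedding:
    sample_ids: list[str]
    coords: np.ndarray  # n_samples x latent_size posterior means
    labels: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.coords,
            index=self.sample_ids,
            columns=[f"latent_{i}" for i in range(self.coords.shape[1])],
        )
        if self.labels is not None:
            frame.insert(0, "label", self.labels)
        return frame


def embed_samples(
    state: NetworkState,
    features: ClusterFeatureMatrix | BetaMatrix,
    labels: Sequence[str] | None = None,
) -> LatentEmbedding:
    """Posterior-mean embedding of every sample; deterministic."""
    beta = features.beta if isinstance(features, ClusterFeatureMatrix) else features
    mu = encode(state, beta.values).mu
    return LatentEmbedding(
        sample_ids=list(beta.sample_ids),
        coords=np.asarray(mu, dtype=np.float64),
        labels=list(labels) if labels is not None else None,
    )


def project_2d(
    embedding: LatentEmbedding,
    method: str = "tsne",
    seed: int = 0,
    perplexity: float = 30.0,
) -> np.ndarray:
    """Seeded 2-D projection of the embedding for plotting/export."""
    x = embedding.coords
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples to project")
    if method == "pca":
        return PCA(n_components=2, random_state=seed).fit_transform(x)
    if method == "tsne":
        perplexity = min(perplexity, (x.shape[0] - 1) / 3.0)
        return TSNE(
            n_components=2, random_state=seed, perplexity=perplexity, init="pca"
        ).fit_transform(x)
    raise ValueError(f"unknown projection method {method!r}")


def svm_separability(
    embedding: LatentEmbedding,
    binary_labels: Sequence[str | int],
    folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> float:
    """Mean stratified k-fold accuracy of a linear-kernel SVM on the full
    latent space for a binary annotation."""
    y = np.asarray(binary_labels)
    if len(y) != embedding.coords.shape[0]:
        raise ValueError("label count does not match embedding")
    values, counts = np.unique(y, return_counts=True)
    if len(values) != 2:
        raise ValueError(f"need exactly 2 label values, got {len(values)}")
    if counts.min() < folds:
        raise ValueError(
            f"smallest group has {counts.min()} members < {folds} folds; use a smaller k"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(
        SVC(kernel="linear", C=C), embedding.coords, y, cv=cv, scoring="accuracy"
    )
    return float(scores.mean())
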