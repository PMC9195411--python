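"""CpG-island feature construction and leakage-safe per-sample normalization.

The feature-construction recipe follows the CancerLocator-style CpG density
clustering: probes outside CpG islands are discarded; the remaining probes
are chained per chromosome whenever consecutive sorted positions lie within
``max_gap`` (default 100 bp, inclusive) of each other; chains with fewer
than ``min_probes`` members (default 4, i.e. eliminating clusters of three
probes or fewer) are dropped; each surviving cluster becomes one feature
whose value is the mean beta of its member probes.

Normalization is strictly per-sample: values are clipped to [0, 1] and any
remaining missing entries are imputed with the sample's own mean.  No
statistic crosses sample boundaries, so a sample's feature vector never
depends on which other samples are present — the leakage guarantee every
downstream split relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import BetaMatrix, ProbeRecord, ValidationError


@dataclass(frozen=True)
class ProbeCluster:
    """A contiguous chain of island probes collapsed into one feature."""

    cluster_id: str
    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"cluster {self.cluster_id}: start > end")
        if not self.probe_ids:
            raise ValidationError(f"cluster {self.cluster_id}: no member probes")


@dataclass
class ClusterFeatureMatrix:
    """A BetaMatrix over cluster features plus cluster -> probe provenance."""

    beta: BetaMatrix
    provenance: dict[str, tuple[str, ...]]


def filter_island_probes(probes: Sequence[ProbeRecord]) -> list[ProbeRecord]:
    """Keep exactly the CpG-island probes, preserving input order."""
    return [p for p in probes if p.in_island]


def cluster_probes(probes: Sequence[ProbeRecord], max_gap: int = 100) -> list[ProbeCluster]:
    """Chain probes per chromosome by single linkage on sorted positions.

    A new cluster starts whenever the gap to the previous probe exceeds
    ``max_gap``; a gap of exactly ``max_gap`` joins.  Every probe belongs to
    exactly one cluster and cluster ids are deterministic
    (``chrom:start-end`` on the 0-based member positions).  Clusters are
    returned sorted by (chrom, start).
    """
    by_chrom: dict[str, list[ProbeRecord]] = {}
    for p in probes:
        by_chrom.setdefault(p.chrom, []).append(p)
    clusters: list[ProbeCluster] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda p: (p.pos, p.probe_id))
        run: list[ProbeRecord] = [ordered[0]]
        for p in ordered[1:]:
            if p.pos - run[-1].pos <= max_gap:
                run.append(p)
            else:
                clusters.append(_make_cluster(chrom, run))
                run = [p]
        clusters.append(_make_cluster(chrom, run))
    return clusters


def _make_cluster(chrom: str, members: list[ProbeRecord]) -> ProbeCluster:
    start, end = members[0].pos, members[-1].pos
    return ProbeCluster(
        cluster_id=f"{chrom}:{start}-{end}",
        chrom=chrom,
        start=start,
        end=end,
        probe_ids=tuple(p.probe_id for p in members),
    )


def filter_clusters(clusters: Sequence[ProbeCluster], min_probes: int = 4) -> list[ProbeCluster]:
    """Drop clusters with fewer than ``min_probes`` members (default keeps >= 4)."""
    return [c for c in clusters if c.n_probes >= min_probes]


def average_beta(beta: BetaMatrix, clusters: Sequence[ProbeCluster]) -> ClusterFeatureMatrix:
    """Collapse a probe-level BetaMatrix into per-cluster mean betas.

    Cell (s, c) is the arithmetic mean over cluster members with a
    non-missing beta for sample s; it is missing only if every member is
    missing.  Output feature order follows cluster order.
    """
    probe_index = {p: j for j, p in enumerate(beta.feature_ids)}
    for c in clusters:
        for p in c.probe_ids:
            if p not in probe_index:
                raise ValidationError(
                    f"cluster {c.cluster_id} references probe {p!r} absent from the beta matrix"
                )
    n_samples = len(beta.sample_ids)
    out = np.empty((n_samples, len(clusters)), dtype=np.float64)
    for k, c in enumerate(clusters):
        # ascontiguousarray pins the reduction order so per-sample means are
        # bit-identical regardless of how many samples are in the matrix
        cols = np.ascontiguousarray(beta.values[:, [probe_index[p] for p in c.probe_ids]])
        counts = np.sum(~np.isnan(cols), axis=1)
        with np.errstate(invalid="ignore"):
            # all-member-missing cells legitimately stay NaN
            out[:, k] = np.where(counts > 0, np.nansum(cols, axis=1) / np.maximum(counts, 1), np.nan)
    matrix = BetaMatrix(list(beta.sample_ids), [c.cluster_id for c in clusters], out)
    return ClusterFeatureMatrix(beta=matrix, provenance={c.cluster_id: c.probe_ids for c in clusters})


def normalize_sample(vector: np.ndarray) -> np.ndarray:
    """Clip one sample's features to [0, 1] and impute missing with its own mean.

    Depends only on the input vector (no cross-sample statistics), which is
    what keeps train/validation/test preprocessing leakage-free.
    """
    v = np.asarray(vector, dtype=np.float64).copy()
    mask = np.isnan(v)
    if mask.all():
        raise ValidationError("all features missing for this sample; cannot normalize")
    v = np.clip(v, 0.0, 1.0)
    if mask.any():
        v[mask] = np.nanmean(np.where(mask, np.nan, v))
    return v


def normalize_matrix(beta: BetaMatrix) -> BetaMatrix:
    """Apply ``normalize_sample`` row by row."""
    values = np.vstack([normalize_sample(row) for row in beta.values])
    return BetaMatrix(list(beta.sample_ids), list(beta.feature_ids), values)


def build_features(
    probes: Sequence[ProbeRecord],
    beta: BetaMatrix,
    max_gap: int = 100,
    min_probes: int = 4,
    normalize: bool = True,
) -> ClusterFeatureMatrix:
    """Full feature pipeline: island filter -> chain -> size filter -> average
    -> per-sample normalization."""
    clusters = filter_clusters(cluster_probes(filter_island_probes(probes), max_gap), min_probes)
    features = average_beta(beta, clusters)
    if normalize:
        features = ClusterFeatureMatrix(
            beta=normalize_matrix(features.beta), provenance=features.provenance
        )
    return features


def write_provenance(features: ClusterFeatureMatrix, path: str | Path) -> None:
    """TSV mapping cluster_id -> comma-joined member probe ids."""
    pd.DataFrame(
        {
            "cluster_id": list(features.provenance),
            "probe_ids": [",".join(v) for v in features.provenance.values()],
        }
    ).to_csv(path, sep="\t", index=False)
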