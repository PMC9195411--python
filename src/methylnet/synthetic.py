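"""Synthetic 450K-style corpora with known ground truth.

The generator emulates the statistical structure the classifier relies on,
so the whole pipeline is testable without any external download:

* a probe manifest whose CpG islands are constructed with within-island
  gaps <= 100 bp and between-island gaps > 100 bp, so the expected cluster
  decomposition is known exactly by construction, plus a configurable
  admixture of non-island probes to exercise the island filter;
* a cohort in which each cancer class hypermethylates its own
  (by default disjoint) subset of islands — its signature — while the
  remaining islands, and every island of the NORM class, stay
  hypomethylated.  Probe-level betas are drawn from two bounded unimodal
  Beta distributions (high mode mean ~0.8, low mode mean ~0.15), echoing
  the bimodality of real beta values;
* patient-matched sample pairs (to exercise training-set deduplication)
  and optional binary subtypes within each cancer class (an extra island
  set hypermethylated in subtype "B") for latent-separability tests;
* variant cohorts: metastasis-like samples (class signature retained, extra
  dispersion, flagged metastatic) and age-drift normals (global
  hypomethylation shift applied to NORM samples, labels unchanged).

One seed fixes the entire corpus bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import CANCER_CODES, NORMAL_LABEL
from .io import BetaMatrix, ProbeRecord, SampleMetadata


@dataclass
class SyntheticSpec:
    """Knobs of the synthetic corpus; the defaults describe the standard
    desk-scale study conditions used throughout the tests."""

    n_classes: int = 8               # includes NORM (always the last class)
    samples_per_class: int = 100
    n_islands: int = 400
    probes_per_island: tuple[int, int] = (4, 8)   # inclusive range
    non_island_fraction: float = 0.1  # extra non-island probes per island probe
    signature_fraction: float = 0.125  # fraction of islands per cancer-class signature
    high_mode: tuple[float, float] = (8.0, 2.0)   # Beta(a, b), mean 0.8
    low_mode: tuple[float, float] = (3.0, 17.0)   # Beta(a, b), mean 0.15
    drift_shift: float = 0.05
    metastasis_noise: float = 0.1
    paired_sample_fraction: float = 0.1  # fraction of samples in patient-matched pairs
    subtype_islands: int = 0         # islands hypermethylated only in subtype B
    islands_per_chrom: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least one cancer class plus NORM")
        for name in ("non_island_fraction", "signature_fraction",
                     "paired_sample_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for a, b in (self.high_mode, self.low_mode):
            if a <= 0 or b <= 0:
                raise ValueError("Beta distribution parameters must be positive")

    @property
    def class_labels(self) -> list[str]:
        return list(CANCER_CODES[: self.n_classes - 1]) + [NORMAL_LABEL]

    @property
    def islands_per_signature(self) -> int:
        return int(round(self.signature_fraction * self.n_islands))


@dataclass
class _Island:
    chrom: str
    probe_ids: list[str]
    positions: list[int]


def _build_islands(spec: SyntheticSpec, rng: np.random.Generator) -> list[_Island]:
    """Deterministic island layout; within-island gaps in [10, 100], the
    between-island gap 400-800 bp so islands never chain together."""
    islands: list[_Island] = []
    lo, hi = spec.probes_per_island
    probe_counter = 0
    for i in range(spec.n_islands):
        chrom = f"chr{i // spec.islands_per_chrom + 1}"
        if i % spec.islands_per_chrom == 0:
            pos = 1000
        else:
            pos = islands[-1].positions[-1] + 400 + int(rng.integers(0, 401))
        n = int(rng.integers(lo, hi + 1))
        positions: list[int] = []
        probe_ids: list[str] = []
        for _ in range(n):
            positions.append(pos)
            probe_ids.append(f"cg{probe_counter:06d}")
            probe_counter += 1
            pos += int(rng.integers(10, 101))
        islands.append(_Island(chrom, probe_ids, positions))
    return islands


def generate_manifest(spec: SyntheticSpec) -> list[ProbeRecord]:
    """Probe manifest with island probes plus non-island decoys in the gaps."""
    rng = np.random.default_rng(spec.seed)
    islands = _build_islands(spec, rng)
    records: list[ProbeRecord] = []
    for isl in islands:
        for pid, pos in zip(isl.probe_ids, isl.positions):
            records.append(ProbeRecord(pid, isl.chrom, pos, True))
    n_island_probes = len(records)
    n_decoys = int(round(spec.non_island_fraction * n_island_probes))
    # decoys sit mid-gap, >= 200 bp from either island, so they could only
    # perturb clustering if the island filter failed to remove them
    gap_slots = [
        (islands[i].chrom, islands[i].positions[-1] + 200)
        for i in range(len(islands) - 1)
        if islands[i + 1].chrom == islands[i].chrom
    ]
    for k in range(n_decoys):
        chrom, pos = gap_slots[k % len(gap_slots)]
        records.append(ProbeRecord(f"ni{k:06d}", chrom, pos + k // len(gap_slots), False))
    return records


def _signature_islands(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    """Disjoint signature island indices per cancer class; NORM gets none."""
    k = spec.islands_per_signature
    cancers = spec.class_labels[:-1]
    if k * len(cancers) > spec.n_islands:
        raise ValueError(
            f"{len(cancers)} disjoint signatures of {k} islands need "
            f"{k * len(cancers)} islands, only {spec.n_islands} available"
        )
    # deterministic permutation independent of the manifest draw order
    perm = np.random.default_rng(spec.seed + 1).permutation(spec.n_islands)
    signatures = {label: perm[i * k:(i + 1) * k] for i, label in enumerate(cancers)}
    signatures[NORMAL_LABEL] = np.array([], dtype=int)
    return signatures


def _subtype_islands(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    """Per-class island sets flipped high only in subtype-B samples."""
    if spec.subtype_islands == 0:
        return {label: np.array([], dtype=int) for label in spec.class_labels}
    sigs = _signature_islands(spec)
    used = np.concatenate([v for v in sigs.values() if v.size]) if any(
        v.size for v in sigs.values()) else np.array([], dtype=int)
    free = np.setdiff1d(np.arange(spec.n_islands), used)
    if spec.subtype_islands > free.size:
        raise ValueError("not enough signature-free islands for subtypes")
    rng = np.random.default_rng(spec.seed + 2)
    picks = rng.choice(free, size=spec.subtype_islands, replace=False)
    return {label: picks for label in spec.class_labels}


def subtype_labels(metadata: Sequence[SampleMetadata], spec: SyntheticSpec) -> list[str]:
    """Binary subtype of each generated sample: the first half of every
    class is "A", the second half "B" (the order samples were generated)."""
    counters: dict[str, int] = {}
    out = []
    for m in metadata:
        i = counters.get(m.class_label, 0)
        counters[m.class_label] = i + 1
        out.append("A" if i < spec.samples_per_class // 2 else "B")
    return out


def generate_cohort(spec: SyntheticSpec) -> tuple[BetaMatrix, list[SampleMetadata]]:
    """Probe-level beta matrix plus metadata for the full synthetic cohort.

    Every cancer class hypermethylates its signature islands (high Beta
    mode) and leaves the rest at the low mode; NORM is low everywhere.  A
    ``paired_sample_fraction`` of samples share a patient with one other
    same-class sample.  With ``subtype_islands > 0`` the second half of
    each class additionally hypermethylates the class's subtype island set.
    """
    rng = np.random.default_rng(spec.seed)
    islands = _build_islands(spec, rng)  # same draws as generate_manifest
    sigs = _signature_islands(spec)
    subs = _subtype_islands(spec)

    probe_ids = [pid for isl in islands for pid in isl.probe_ids]
    island_of_probe = np.concatenate(
        [np.full(len(isl.probe_ids), i) for i, isl in enumerate(islands)]
    )
    n_probes = len(probe_ids)
    a_hi, b_hi = spec.high_mode
    a_lo, b_lo = spec.low_mode

    values_blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    metadata: list[SampleMetadata] = []
    n_pairs = int(round(spec.paired_sample_fraction * spec.samples_per_class / 2))
    cohort_rng = np.random.default_rng(spec.seed + 3)

    for label in spec.class_labels:
        high = np.zeros(spec.n_islands, dtype=bool)
        high[sigs[label]] = True
        base_high_probes = high[island_of_probe]

        sub_high = np.zeros(spec.n_islands, dtype=bool)
        sub_high[subs[label]] = True
        sub_probes = sub_high[island_of_probe]

        half = spec.samples_per_class // 2
        for i in range(spec.samples_per_class):
            hp = base_high_probes | (sub_probes if i >= half else False)
            a = np.where(hp, a_hi, a_lo)
            b = np.where(hp, b_hi, b_lo)
            values_blocks.append(cohort_rng.beta(a, b)[None, :])
            sid = f"{label}_s{i:03d}"
            if i < 2 * n_pairs:
                pid = f"{label}_p{i // 2:03d}"
            else:
                pid = f"{label}_p{n_pairs + (i - 2 * n_pairs):03d}"
            stype = "normal_tissue" if label == NORMAL_LABEL else "primary"
            sample_ids.append(sid)
            metadata.append(SampleMetadata(sid, pid, label, stype))

    beta = BetaMatrix(sample_ids, probe_ids, np.vstack(values_blocks))
    return beta, metadata


def generate_variants(
    beta: BetaMatrix,
    metadata: Sequence[SampleMetadata],
    spec: SyntheticSpec,
    kind: str,
) -> tuple[BetaMatrix, list[SampleMetadata]]:
    """Derived evaluation-only cohorts.

    ``metastasis_like``
        cancer samples keep their class signature, gain i.i.d. Gaussian
        dispersion of scale ``metastasis_noise`` (clipped to [0, 1]) and
        are re-flagged ``metastatic``;
    ``age_drift``
        NORM samples are globally hypomethylated by ``drift_shift``
        (clipped at 0), emulating age-related epigenetic drift; labels
        stay NORM.
    """
    rng = np.random.default_rng(spec.seed + 4)
    meta_by_id = {m.sample_id: m for m in metadata}
    if kind == "metastasis_like":
        keep = [s for s in beta.sample_ids if meta_by_id[s].class_label != NORMAL_LABEL]
        sub = beta.subset_samples(keep)
        noise = rng.normal(0.0, spec.metastasis_noise, size=sub.values.shape) \
            if spec.metastasis_noise > 0 else 0.0
        values = np.clip(sub.values + noise, 0.0, 1.0)
        new_meta = [
            SampleMetadata(f"{s}_met", meta_by_id[s].patient_id,
                           meta_by_id[s].class_label, "metastatic")
            for s in keep
        ]
    elif kind == "age_drift":
        keep = [s for s in beta.sample_ids if meta_by_id[s].class_label == NORMAL_LABEL]
        sub = beta.subset_samples(keep)
        values = np.clip(sub.values - spec.drift_shift, 0.0, 1.0)
        new_meta = [
            SampleMetadata(f"{s}_drift", meta_by_id[s].patient_id,
                           NORMAL_LABEL, "normal_tissue")
            for s in keep
        ]
    else:
        raise ValueError(f"unknown variant kind {kind!r}")
    return (
        BetaMatrix([m.sample_id for m in new_meta], list(beta.feature_ids), values),
        new_meta,
    )
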