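"""Readers, writers and validation for probe manifests, beta matrices and
sample metadata.

All downstream stages consume the three domain types defined here:

``ProbeRecord``
    one Illumina-450K-style array probe with its genomic position and
    CpG-island membership flag;
``BetaMatrix``
    a samples x features matrix of methylation fractions in [0, 1] with
    missing values allowed (NaN);
``SampleMetadata``
    one row per sample linking it to a patient, a class label from the
    34-label vocabulary and a sample type.

Coordinates are 0-based internally.  BED-like manifests are taken as
0-based half-open (the probe position is the interval start); CSV manifests
carry 1-based positions and are shifted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import CLASS_LABELS, NA_TOKENS, SAMPLE_TYPES


class SchemaError(ValueError):
    """A required column is absent or a file is structurally malformed."""


class ValidationError(ValueError):
    """Contents parse but violate an invariant (duplicates, range, vocabulary)."""


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    chrom: str
    pos: int  # 0-based genomic coordinate
    in_island: bool

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError(f"probe {self.probe_id!r}: empty chromosome")
        if self.pos < 0:
            raise ValidationError(f"probe {self.probe_id!r}: negative position {self.pos}")


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    patient_id: str
    class_label: str
    sample_type: str

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown class label {self.class_label!r}"
            )
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown sample type {self.sample_type!r}"
            )


@dataclass
class BetaMatrix:
    """Samples x features methylation fractions; NaN marks missing."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray  # float64, shape (n_samples, n_features)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        _check_unique(self.sample_ids, "sample_id")
        _check_unique(self.feature_ids, "feature_id")
        bad = (self.values < 0) | (self.values > 1)
        if np.any(bad & ~np.isnan(self.values)):
            i, j = np.argwhere(bad & ~np.isnan(self.values))[0]
            raise ValidationError(
                f"beta value {self.values[i, j]} out of [0, 1] at sample "
                f"{self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(
            sample_ids=[str(s) for s in frame.index],
            feature_ids=[str(f) for f in frame.columns],
            values=frame.to_numpy(dtype=np.float64),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return BetaMatrix(list(sample_ids), list(self.feature_ids), self.values[rows])


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    dupes: list[str] = []
    for x in ids:
        if x in seen:
            dupes.append(x)
        seen.add(x)
    if dupes:
        raise ValidationError(f"duplicate {what}(s): {sorted(set(dupes))[:10]}")


# ---------------------------------------------------------------------------
# manifest


_MANIFEST_COLUMNS = ("probe_id", "chrom", "pos", "in_island")
_TRUTHY = {"1", "true", "t", "yes", "y", "island"}
_FALSY = {"0", "false", "f", "no", "n", "", "na", "nan", "none", "."}


def _parse_flag(token: object) -> bool:
    if isinstance(token, bool):
        return token
    if isinstance(token, (int, np.integer)):
        return bool(token)
    if isinstance(token, float):
        return bool(token) and not math.isnan(token)
    s = str(token).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"cannot interpret island flag {token!r}")


def read_manifest(path: str | Path, dialect: str = "csv") -> list[ProbeRecord]:
    """Read a probe manifest.

    ``csv`` dialect: columns probe_id, chrom, pos, in_island with 1-based
    positions.  ``bed`` dialect: headerless tab-separated chrom, start, end,
    probe_id, island flag with 0-based half-open intervals.
    """
    path = Path(path)
    if dialect == "csv":
        table = pd.read_csv(path, dtype=str)
        missing = [c for c in _MANIFEST_COLUMNS if c not in table.columns]
        if missing:
            raise SchemaError(f"manifest {path} is missing column(s): {missing}")
        records = [
            ProbeRecord(
                probe_id=str(row.probe_id),
                chrom=str(row.chrom),
                pos=int(row.pos) - 1,  # 1-based on disk -> 0-based internal
                in_island=_parse_flag(row.in_island),
            )
            for row in table.itertuples(index=False)
        ]
    elif dialect in ("bed", "bed-like"):
        table = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "probe_id", "island"], dtype=str,
        )
        if table.shape[1] < 5 or table["island"].isna().any():
            raise SchemaError(f"BED-like manifest {path} needs 5 columns (island flag in column 5)")
        records = [
            ProbeRecord(
                probe_id=str(row.probe_id),
                chrom=str(row.chrom),
                pos=int(row.start),  # already 0-based
                in_island=_parse_flag(row.island),
            )
            for row in table.itertuples(index=False)
        ]
    else:
        raise ValueError(f"unknown manifest dialect {dialect!r}")
    _check_unique((r.probe_id for r in records), "probe_id")
    return records


def write_manifest(records: Sequence[ProbeRecord], path: str | Path) -> None:
    """Write a CSV-dialect manifest (positions back to 1-based)."""
    frame = pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos + 1 for r in records],
            "in_island": [int(r.in_island) for r in records],
        }
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# beta matrix


def read_beta_matrix(path: str | Path, sep: str = "\t") -> BetaMatrix:
    """Read a samples-as-rows, features-as-columns beta table.

    Cells may be numeric, empty, or an NA token ("NA", "NaN", "";
    case-insensitive); NA becomes missing.  Out-of-range or non-numeric
    cells raise ``ValidationError`` naming the offending cell.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                            keep_default_na=False, engine="python")
    except pd.errors.ParserError as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    sample_ids = [str(s) for s in table.index]
    feature_ids = [str(f) for f in table.columns]
    values = np.empty(table.shape, dtype=np.float64)
    raw = table.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell.lower() in NA_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError as exc:
                raise ValidationError(
                    f"non-numeric cell {cell!r} at row {sample_ids[i]!r}, "
                    f"column {feature_ids[j]!r}"
                ) from exc
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"beta value {v} out of [0, 1] at row {sample_ids[i]!r}, "
                    f"column {feature_ids[j]!r}"
                )
            values[i, j] = v
    return BetaMatrix(sample_ids, feature_ids, values)


def write_beta_matrix(beta: BetaMatrix, path: str | Path, sep: str = "\t") -> None:
    beta.to_frame().to_csv(path, sep=sep, na_rep="NA", index_label="sample_id")


# ---------------------------------------------------------------------------
# metadata


_METADATA_COLUMNS = ("sample_id", "patient_id", "class_label", "sample_type")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata CSV; validates labels against the 34-label vocabulary."""
    table = pd.read_csv(path, dtype=str)
    missing = [c for c in _METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"metadata {path} is missing column(s): {missing}")
    records = [
        SampleMetadata(
            sample_id=str(row.sample_id),
            patient_id=str(row.patient_id),
            class_label=str(row.class_label),
            sample_type=str(row.sample_type),
        )
        for row in table.itertuples(index=False)
    ]
    _check_unique((r.sample_id for r in records), "sample_id")
    return records


def write_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "class_label": [r.class_label for r in records],
            "sample_type": [r.sample_type for r in records],
        }
    ).to_csv(path, index=False)


def validate_inputs(
    probes: Sequence[ProbeRecord],
    beta: BetaMatrix,
    metadata: Sequence[SampleMetadata],
) -> None:
    """Cross-file consistency: every beta sample has exactly one metadata row."""
    meta_ids = {m.sample_id for m in metadata}
    orphans = [s for s in beta.sample_ids if s not in meta_ids]
    if orphans:
        raise ValidationError(f"samples without metadata: {orphans[:10]}")
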