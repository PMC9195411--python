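"""Dataset splitting, patient-level deduplication and the training loop.

Samples are split 80/10/10 into train/validation/test (stratified by class
by default, since several classes are small).  Metastatic and recurrent
samples are expected to have been excluded beforehand; they are
evaluation-only.  The training set is then deduplicated so no patient
contributes more than one sample: one of any matched pair is removed and
replaced, when possible, by a random unused sample of the same class.

Training minimizes the joint VAE/classifier loss with Adam, monitoring
plain multiclass accuracy on the validation split.  Early stopping halts
the run once validation accuracy has not improved for ``patience_epochs``
epochs, and the returned parameters are those of the best epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import BetaMatrix, SampleMetadata
from .model import ModelConfig, NetworkState, init_state, loss_and_grads, predict_proba


@dataclass
class DatasetSplit:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("train/val/test sets overlap")


@dataclass
class EpochRecord:
    epoch: int
    total: float
    recon: float
    kl: float
    clf_ce: float
    val_accuracy: float


@dataclass
class TrainingHistory:
    epochs: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer shares of ``n`` by the largest-remainder method."""
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    leftover = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainder first
    for k in order[:leftover]:
        counts[k] += 1
    return counts


def make_split(
    metadata: Sequence[SampleMetadata],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    stratify: bool = True,
) -> DatasetSplit:
    """Random train/validation/test split, reproducible under ``seed``.

    Stratified by class label by default so rare classes stay represented
    in the 10% slices; ``stratify=False`` gives a plain random split.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[str]]
    if stratify:
        groups = {}
        for m in metadata:
            groups.setdefault(m.class_label, []).append(m.sample_id)
        for label, ids in groups.items():
            if not ids:
                warnings.warn(f"class {label} has no samples")
    else:
        groups = {"__all__": [m.sample_id for m in metadata]}
    train: list[str] = []
    val: list[str] = []
    test: list[str] = []
    for label in sorted(groups):
        ids = list(groups[label])
        rng.shuffle(ids)
        n_train, n_val, n_test = _largest_remainder(len(ids), fractions)
        train.extend(ids[:n_train])
        val.extend(ids[n_train:n_train + n_val])
        test.extend(ids[n_train + n_val:])
    return DatasetSplit(train, val, test, seed)


def deduplicate_patients(
    split: DatasetSplit,
    metadata: Sequence[SampleMetadata],
    rng: np.random.Generator,
) -> DatasetSplit:
    """Enforce at most one training sample per patient.

    For every patient with multiple training samples, one is kept (chosen
    at random) and each removed sample is replaced by a uniformly drawn
    unused sample of the same class when one exists; otherwise the slot is
    left unfilled.  Validation and test sets are untouched.
    """
    by_id = {m.sample_id: m for m in metadata}
    used = set(split.train_ids) | set(split.val_ids) | set(split.test_ids)

    by_patient: dict[str, list[str]] = {}
    for s in split.train_ids:
        by_patient.setdefault(by_id[s].patient_id, []).append(s)

    keep: set[str] = set()
    removed: list[str] = []
    for patient in sorted(by_patient):
        ids = by_patient[patient]
        if len(ids) == 1:
            keep.add(ids[0])
        else:
            chosen = ids[int(rng.integers(len(ids)))]
            keep.add(chosen)
            removed.extend(s for s in ids if s != chosen)

    new_train = [s for s in split.train_ids if s in keep]
    train_patients = {by_id[s].patient_id for s in new_train}
    for s in removed:
        label = by_id[s].class_label
        pool = sorted(
            m.sample_id
            for m in metadata
            if m.class_label == label
            and m.sample_id not in used
            and m.patient_id not in train_patients
        )
        if pool:
            pick = pool[int(rng.integers(len(pool)))]
            new_train.append(pick)
            used.add(pick)
            train_patients.add(by_id[pick].patient_id)
    return DatasetSplit(new_train, list(split.val_ids), list(split.test_ids), split.seed)


def one_hot(labels: Sequence[str], label_order: Sequence[str]) -> np.ndarray:
    index = {label: i for i, label in enumerate(label_order)}
    unknown = [l for l in labels if l not in index]
    if unknown:
        raise ValueError(f"labels outside vocabulary: {sorted(set(unknown))[:5]}")
    out = np.zeros((len(labels), len(label_order)), dtype=np.float64)
    for i, l in enumerate(labels):
        out[i, index[l]] = 1.0
    return out


class _Adam:
    """Standard Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train_model(
    cfg: ModelConfig,
    train_x: np.ndarray,
    train_labels: Sequence[str],
    val_x: np.ndarray,
    val_labels: Sequence[str],
    label_order: Sequence[str],
) -> tuple[NetworkState, TrainingHistory]:
    """Minibatch Adam training of the joint objective with early stopping.

    Stops once validation accuracy has not improved for
    ``cfg.patience_epochs`` consecutive epochs (at least one), capped at
    ``cfg.max_epochs``; returns the parameters of the best epoch.  Fully
    reproducible from ``cfg.seed``: initialization, shuffling and latent
    sampling all derive from it.
    """
    if len(label_order) != cfg.n_classes:
        raise ValueError(f"label_order has {len(label_order)} labels, config expects {cfg.n_classes}")
    train_x = np.asarray(train_x, dtype=np.float64)
    val_x = np.asarray(val_x, dtype=np.float64)
    y_train = one_hot(train_labels, label_order)
    y_val_idx = np.argmax(one_hot(val_labels, label_order), axis=1)

    rng = np.random.default_rng(cfg.seed)
    state = init_state(cfg, rng)
    adam = _Adam(state.params, cfg.learning_rate)

    history = TrainingHistory()
    best_acc = -np.inf
    best_state = state.copy()
    patience = max(cfg.patience_epochs, 1)
    n = train_x.shape[0]
    batch = max(1, min(cfg.batch_size, n))

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        sums = {"total": 0.0, "recon": 0.0, "kl": 0.0, "clf_ce": 0.0}
        n_batches = 0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            xb, yb = train_x[idx], y_train[idx]
            eps_noise = rng.standard_normal((len(idx), cfg.latent_size))
            comp, grads = loss_and_grads(state, xb, yb, cfg, eps_noise)
            if not np.isfinite(comp["total"]):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: {comp}"
                )
            adam.step(state.params, grads)
            for k in sums:
                sums[k] += comp[k]
            n_batches += 1
        means = {k: v / n_batches for k, v in sums.items()}

        val_pred = np.argmax(predict_proba(state, val_x), axis=1)
        val_acc = float(np.mean(val_pred == y_val_idx))
        history.epochs.append(EpochRecord(epoch, means["total"], means["recon"],
                                          means["kl"], means["clf_ce"], val_acc))
        if val_acc > best_acc:  # strict: ties keep the earliest epoch
            best_acc = val_acc
            best_state = state.copy()
            history.best_epoch = epoch
        if epoch - history.best_epoch >= patience:
            break
    history.stopped_epoch = history.epochs[-1].epoch
    return best_state, history


def history_frame(history: TrainingHistory):
    import pandas as pd

    return pd.DataFrame(
        {
            "epoch": [e.epoch for e in history.epochs],
            "total": [e.total for e in history.epochs],
            "recon": [e.recon for e in history.epochs],
            "kl": [e.kl for e in history.epochs],
            "clf_ce": [e.clf_ce for e in history.epochs],
            "val_accuracy": [e.val_accuracy for e in history.epochs],
        }
    )
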