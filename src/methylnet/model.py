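"""The hybrid variational-autoencoder / classifier network.

Architecture, in order of data flow:

* **encoder** — input (``n_features``) -> dense ReLU layer (``hidden_size``)
  -> two activation-free projection heads producing the latent posterior
  mean ``mu`` and log-variance ``logvar`` (each ``latent_size``);
* **probabilistic latent layer** — during training a latent vector is drawn
  by the reparameterization trick, ``z = mu + exp(logvar/2) * eps`` with
  ``eps ~ N(0, I)``; at inference ``z = mu``;
* **decoder** — ``z`` -> dense ReLU layer (``hidden_size``) -> sigmoid
  output layer (``n_features``), reconstructing the beta-value vector;
* **classifier** — ``z`` -> dense ReLU layer (``classifier_hidden``) ->
  softmax output over ``n_classes``.

The joint objective is a weighted sum of a VAE loss and a classification
loss::

    L = vae_weight * (recon + vae_beta * KL) + clf_weight * clf_ce

where ``recon`` is element-wise binary cross-entropy between input and
reconstruction (summed over features by default), ``KL`` is the closed-form
Kullback-Leibler divergence between the diagonal-Gaussian posterior and a
standard normal, and ``clf_ce`` is categorical cross-entropy on the softmax
output.  Default weights are 0.01 (VAE) and 1 (classifier) with
``vae_beta = 1``.  Per-batch loss is the mean over samples.

Everything, including backpropagation, is implemented directly in numpy so
that gradients are available in closed form and can be verified against
finite differences.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

EPS = 1e-7  # clamps reconstructions away from {0, 1} inside logs

#: parameter names in canonical order
PARAM_NAMES = (
    "enc_w1", "enc_b1", "enc_wmu", "enc_bmu", "enc_wlv", "enc_blv",
    "dec_w1", "dec_b1", "dec_w2", "dec_b2",
    "clf_w1", "clf_b1", "clf_w2", "clf_b2",
)


@dataclass
class ModelConfig:
    """Architecture and loss hyperparameters.

    Defaults follow the full-scale pan-cancer setting: 24,565 cluster
    features, a 1,000-node hidden layer, a 100-node latent layer, 34
    classes, KL multiplier 1, loss weights 0.01/1, Adam learning rate
    0.001 and early-stopping patience of 50 epochs.
    """

    n_features: int = 24565
    hidden_size: int = 1000
    latent_size: int = 100
    n_classes: int = 34
    classifier_hidden: int = 100
    vae_beta: float = 1.0
    vae_weight: float = 0.01
    clf_weight: float = 1.0
    learning_rate: float = 0.001
    patience_epochs: int = 50
    seed: int = 0
    recon_reduction: str = "sum"  # "sum" or "mean" over features
    batch_size: int = 128
    max_epochs: int = 2000

    def __post_init__(self) -> None:
        for name in ("n_features", "hidden_size", "latent_size", "n_classes", "classifier_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("vae_beta", "vae_weight", "clf_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.recon_reduction not in ("sum", "mean"):
            raise ValueError("recon_reduction must be 'sum' or 'mean'")


@dataclass
class LatentPosterior:
    """Diagonal-Gaussian posterior: mean and log-variance per latent node."""

    mu: np.ndarray
    logvar: np.ndarray


@dataclass
class NetworkState:
    """All trainable parameters, keyed by name (see ``PARAM_NAMES``)."""

    params: dict[str, np.ndarray]

    def copy(self) -> "NetworkState":
        return NetworkState({k: v.copy() for k, v in self.params.items()})


def init_state(cfg: ModelConfig, rng: np.random.Generator | None = None) -> NetworkState:
    """Seeded Glorot-uniform initialization; biases start at zero."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    f, h, l, ch, c = (cfg.n_features, cfg.hidden_size, cfg.latent_size,
                      cfg.classifier_hidden, cfg.n_classes)
    params = {
        "enc_w1": glorot(f, h), "enc_b1": np.zeros(h),
        "enc_wmu": glorot(h, l), "enc_bmu": np.zeros(l),
        "enc_wlv": glorot(h, l), "enc_blv": np.zeros(l),
        "dec_w1": glorot(l, h), "dec_b1": np.zeros(h),
        "dec_w2": glorot(h, f), "dec_b2": np.zeros(f),
        "clf_w1": glorot(l, ch), "clf_b1": np.zeros(ch),
        "clf_w2": glorot(ch, c), "clf_b2": np.zeros(c),
    }
    return NetworkState(params)


def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    e = np.exp(a[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _softmax(a: np.ndarray) -> np.ndarray:
    shifted = a - a.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def encode(state: NetworkState, x: np.ndarray) -> LatentPosterior:
    """Map inputs to the latent posterior (deterministic given the state)."""
    xb, squeeze = _as_batch(x)
    p = state.params
    if xb.shape[1] != p["enc_w1"].shape[0]:
        raise ValueError(f"expected {p['enc_w1'].shape[0]} features, got {xb.shape[1]}")
    h = np.maximum(xb @ p["enc_w1"] + p["enc_b1"], 0.0)
    mu = h @ p["enc_wmu"] + p["enc_bmu"]
    logvar = h @ p["enc_wlv"] + p["enc_blv"]
    if squeeze:
        return LatentPosterior(mu[0], logvar[0])
    return LatentPosterior(mu, logvar)


def sample_latent(post: LatentPosterior, rng: np.random.Generator) -> np.ndarray:
    """Reparameterized draw ``z = mu + exp(logvar/2) * eps``."""
    eps = rng.standard_normal(post.mu.shape)
    return post.mu + np.exp(post.logvar / 2.0) * eps


def decode(state: NetworkState, z: np.ndarray) -> np.ndarray:
    """Reconstruct beta values from a latent vector; outputs strictly in (0, 1)."""
    zb, squeeze = _as_batch(z)
    p = state.params
    if zb.shape[1] != p["dec_w1"].shape[0]:
        raise ValueError(f"expected latent size {p['dec_w1'].shape[0]}, got {zb.shape[1]}")
    h = np.maximum(zb @ p["dec_w1"] + p["dec_b1"], 0.0)
    # clamp: float64 sigmoid saturates to exactly 0/1 for |a| > ~37
    xhat = np.clip(_sigmoid(h @ p["dec_w2"] + p["dec_b2"]), EPS, 1.0 - EPS)
    return xhat[0] if squeeze else xhat


def classify(state: NetworkState, z: np.ndarray) -> np.ndarray:
    """Class-probability vector(s) from a latent vector (softmax output)."""
    zb, squeeze = _as_batch(z)
    p = state.params
    if zb.shape[1] != p["clf_w1"].shape[0]:
        raise ValueError(f"expected latent size {p['clf_w1'].shape[0]}, got {zb.shape[1]}")
    h = np.maximum(zb @ p["clf_w1"] + p["clf_b1"], 0.0)
    probs = _softmax(h @ p["clf_w2"] + p["clf_b2"])
    return probs[0] if squeeze else probs


def predict_proba(state: NetworkState, x: np.ndarray) -> np.ndarray:
    """Inference path: classify at the posterior mean (no sampling)."""
    return classify(state, encode(state, x).mu)


def kl_divergence(post: LatentPosterior) -> float | np.ndarray:
    """Closed-form KL(q(z|x) || N(0, I)) = sum_i (mu_i^2 + sigma_i^2 - 1 - log sigma_i^2)/2.

    Nonnegative, zero exactly at the standard normal.  For a batched
    posterior, returns one value per sample.
    """
    mu, lv = np.asarray(post.mu), np.asarray(post.logvar)
    kl = 0.5 * np.sum(mu**2 + np.exp(lv) - 1.0 - lv, axis=-1)
    return float(kl) if kl.ndim == 0 else kl


def reconstruction_loss(x: np.ndarray, xhat: np.ndarray, reduction: str = "sum") -> float | np.ndarray:
    """Element-wise binary cross-entropy between input and reconstruction.

    ``-sum_j [x_j log xhat_j + (1 - x_j) log(1 - xhat_j)]`` with xhat
    clamped to [EPS, 1 - EPS]; ``reduction='mean'`` divides by the number
    of features.
    """
    x = np.asarray(x, dtype=np.float64)
    xh = np.clip(np.asarray(xhat, dtype=np.float64), EPS, 1.0 - EPS)
    ce = -(x * np.log(xh) + (1.0 - x) * np.log(1.0 - xh))
    loss = ce.mean(axis=-1) if reduction == "mean" else ce.sum(axis=-1)
    return float(loss) if np.ndim(loss) == 0 else loss


def classifier_loss(y_onehot: np.ndarray, probs: np.ndarray) -> float | np.ndarray:
    """Categorical cross-entropy between one-hot labels and softmax output."""
    p = np.clip(np.asarray(probs, dtype=np.float64), EPS, 1.0)
    loss = -np.sum(np.asarray(y_onehot) * np.log(p), axis=-1)
    return float(loss) if np.ndim(loss) == 0 else loss


def total_loss(recon: float, kl: float, clf_ce: float, cfg: ModelConfig) -> float:
    """Joint objective: ``vae_weight * (recon + vae_beta * kl) + clf_weight * clf_ce``."""
    return cfg.vae_weight * (recon + cfg.vae_beta * kl) + cfg.clf_weight * clf_ce


# ---------------------------------------------------------------------------
# joint forward/backward pass


def loss_and_grads(
    state: NetworkState,
    x: np.ndarray,
    y_onehot: np.ndarray,
    cfg: ModelConfig,
    eps_noise: np.ndarray | None = None,
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Batch-mean joint loss and its analytic gradients.

    ``eps_noise`` is the reparameterization noise (same shape as the latent
    batch); pass ``None`` for the deterministic path ``z = mu``.  Returns
    ``(components, grads)`` where components holds the batch means of
    ``total``, ``recon``, ``kl`` and ``clf_ce``.
    """
    p = state.params
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y_onehot, dtype=np.float64))
    n = x.shape[0]

    # forward
    h_pre = x @ p["enc_w1"] + p["enc_b1"]
    h = np.maximum(h_pre, 0.0)
    mu = h @ p["enc_wmu"] + p["enc_bmu"]
    lv = h @ p["enc_wlv"] + p["enc_blv"]
    z = mu if eps_noise is None else mu + np.exp(lv / 2.0) * eps_noise

    d_pre = z @ p["dec_w1"] + p["dec_b1"]
    hd = np.maximum(d_pre, 0.0)
    xhat = _sigmoid(hd @ p["dec_w2"] + p["dec_b2"])

    c_pre = z @ p["clf_w1"] + p["clf_b1"]
    hc = np.maximum(c_pre, 0.0)
    probs = _softmax(hc @ p["clf_w2"] + p["clf_b2"])

    recon = reconstruction_loss(x, xhat, cfg.recon_reduction)
    kl = kl_divergence(LatentPosterior(mu, lv))
    ce = classifier_loss(y, probs)
    comp = {
        "recon": float(np.mean(recon)),
        "kl": float(np.mean(kl)),
        "clf_ce": float(np.mean(ce)),
    }
    comp["total"] = total_loss(comp["recon"], comp["kl"], comp["clf_ce"], cfg)

    # backward (gradients of the batch-mean total loss)
    grads: dict[str, np.ndarray] = {}
    feat_scale = 1.0 / x.shape[1] if cfg.recon_reduction == "mean" else 1.0

    # decoder head: d recon / d (pre-sigmoid) = xhat - x (clamp ignored)
    g_dec_out = cfg.vae_weight * feat_scale * (xhat - x) / n
    grads["dec_w2"] = hd.T @ g_dec_out
    grads["dec_b2"] = g_dec_out.sum(axis=0)
    g_hd = (g_dec_out @ p["dec_w2"].T) * (d_pre > 0)
    grads["dec_w1"] = z.T @ g_hd
    grads["dec_b1"] = g_hd.sum(axis=0)

    # classifier head: d ce / d logits = probs - y
    g_logits = cfg.clf_weight * (probs - y) / n
    grads["clf_w2"] = hc.T @ g_logits
    grads["clf_b2"] = g_logits.sum(axis=0)
    g_hc = (g_logits @ p["clf_w2"].T) * (c_pre > 0)
    grads["clf_w1"] = z.T @ g_hc
    grads["clf_b1"] = g_hc.sum(axis=0)

    # into the latent sample
    g_z = g_hd @ p["dec_w1"].T + g_hc @ p["clf_w1"].T

    # KL terms plus reparameterization pathway
    kw = cfg.vae_weight * cfg.vae_beta / n
    g_mu = g_z + kw * mu
    g_lv = kw * 0.5 * (np.exp(lv) - 1.0)
    if eps_noise is not None:
        g_lv = g_lv + g_z * eps_noise * 0.5 * np.exp(lv / 2.0)

    grads["enc_wmu"] = h.T @ g_mu
    grads["enc_bmu"] = g_mu.sum(axis=0)
    grads["enc_wlv"] = h.T @ g_lv
    grads["enc_blv"] = g_lv.sum(axis=0)
    g_h = (g_mu @ p["enc_wmu"].T + g_lv @ p["enc_wlv"].T) * (h_pre > 0)
    grads["enc_w1"] = x.T @ g_h
    grads["enc_b1"] = g_h.sum(axis=0)
    return comp, grads


# ---------------------------------------------------------------------------
# checkpointing


CHECKPOINT_SCHEMA_VERSION = 1


def save_checkpoint(state: NetworkState, cfg: ModelConfig, path: str | Path) -> None:
    """Single-archive checkpoint: config as JSON plus raw parameter arrays."""
    meta = {"schema_version": CHECKPOINT_SCHEMA_VERSION, "config": asdict(cfg)}
    arrays = {f"param_{k}": v for k, v in state.params.items()}
    with open(path, "wb") as fh:  # file handle keeps the exact path (no .npz suffix)
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[NetworkState, ModelConfig]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta.get("schema_version") != CHECKPOINT_SCHEMA_VERSION:
            raise ValueError(f"unsupported checkpoint schema: {meta.get('schema_version')}")
        params = {k[len("param_"):]: archive[k] for k in archive.files if k.startswith("param_")}
    return NetworkState(params), ModelConfig(**meta["config"])
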