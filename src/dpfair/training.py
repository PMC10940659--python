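"""DP-SGD and non-private training of the residual CNNs.

The private loop is the canonical DP-SGD recipe: Poisson-sample a batch with
per-record probability q, compute exact per-sample gradients, clip each
record's whole flattened gradient to ℓ2-norm C, sum, add Normal(0, σ²C²)
noise, divide by the *expected* batch size qN, and hand the result to the
optimizer (NAdam by default; optimizer state is post-processing and does not
affect the guarantee).  The noise multiplier is calibrated beforehand so the
privacy budget is spent exactly on the last training step, and the accounted
spend is attached to the trained model.

The non-private loop is ordinary shuffled mini-batch training, optionally
with rotation/flip augmentation (augmentation is forbidden in DP mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.ndimage import rotate as nd_rotate

from .accounting import MechanismParams, PrivacySpend, account, calibrate_sigma
from .evaluation import PredictionTable
from .models import ModelConfig, Network, build_model

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "ArrayDataset",
    "poisson_sample",
    "clip_per_sample",
    "noisy_step",
    "weighted_bce_loss",
    "bce_loss_and_grad",
    "inverse_frequency_weights",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for one training run.

    ``mode`` is "dp" or "nonprivate".  DP mode requires ``epsilon_target``,
    ``delta`` and ``clip_norm`` and forbids augmentation; steps per epoch
    under Poisson sampling default to round(N / batch_size) (the ``n_over_b``
    rule), with ``one_over_q`` available.
    """

    mode: str = "nonprivate"
    learning_rate: float = 1e-3
    loss_weighting: str = "inverted_class_frequency"  # or "none"
    clip_norm: float = 1.5
    batch_size: int = 128
    epochs: int = 10
    epsilon_target: float | None = None
    delta: float | None = None
    sigma: float | None = None  # pre-calibrated; computed from target if None
    augment_rotate: bool = False
    augment_flip: bool = False
    optimizer: str = "nadam"  # or "sgd"
    steps_per_epoch_rule: str = "n_over_b"
    calibration_tolerance: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("dp", "nonprivate"):
            raise ValueError("mode must be 'dp' or 'nonprivate'")
        if self.loss_weighting not in ("inverted_class_frequency", "none"):
            raise ValueError("unknown loss_weighting")
        if self.optimizer not in ("nadam", "sgd"):
            raise ValueError("optimizer must be 'nadam' or 'sgd'")
        if self.mode == "dp":
            if self.augment_rotate or self.augment_flip:
                raise ValueError("data augmentation is forbidden in DP mode")
            if self.sigma is None and (
                self.epsilon_target is None or self.delta is None
            ):
                raise ValueError("dp mode needs epsilon_target+delta or sigma")
            if not self.clip_norm > 0:
                raise ValueError("dp mode needs clip_norm > 0")
            if self.delta is None:
                raise ValueError("dp mode needs delta")


@dataclass
class ArrayDataset:
    """Preprocessed tensors ready for training: images scaled to roughly
    [-0.5, 0.5], binary label matrix, and per-record metadata."""

    images: np.ndarray  # (N, *spatial) or (N, C, *spatial)
    labels: np.ndarray  # (N, n_labels) in {0, 1}
    metadata: pd.DataFrame  # record_id, patient_id, sex, age_group
    label_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.images.shape[0] != self.labels.shape[0]:
            raise ValueError("images and labels disagree on record count")
        if self.labels.shape[1] != len(self.label_names):
            raise ValueError("label matrix width != number of label names")

    def __len__(self) -> int:
        return self.images.shape[0]

    def model_input(self) -> np.ndarray:
        x = self.images
        if x.ndim == len(x.shape[1:]) + 1:  # no channel axis yet
            x = x[:, None]
        return np.ascontiguousarray(x, dtype=np.float64)


@dataclass
class TrainedModel:
    network: Network
    model_config: ModelConfig
    train_config: TrainConfig
    spend: PrivacySpend | None
    loss_trace: list[float]
    seed_manifest: dict

    def predict_table(self, ds: ArrayDataset) -> PredictionTable:
        scores = self.network.predict_proba(ds.model_input())
        frame = ds.metadata.reset_index(drop=True).copy()
        for j, label in enumerate(ds.label_names):
            frame[f"y_true_{label}"] = ds.labels[:, j]
            frame[f"y_score_{label}"] = scores[:, j]
        return PredictionTable(frame, ds.label_names)


# --------------------------------------------------------------------------
# DP-SGD primitives


def poisson_sample(
    n_records: int, q: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Indices of a Poisson-sampled batch: each record independently w.p. q."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return np.flatnonzero(rng.random(n_records) < q)


def clip_per_sample(g: np.ndarray, clip_norm: float) -> np.ndarray:
    """Rescale gradient rows to ℓ2-norm at most ``clip_norm``.

    Accepts a single flattened gradient (P,) or a batch (B, P); the norm is
    taken over the whole flattened parameter vector of each sample.
    """
    if not clip_norm > 0:
        raise ValueError("clip_norm must be > 0")
    g = np.asarray(g, dtype=float)
    if g.ndim == 1:
        norm = np.linalg.norm(g)
        return g * min(1.0, clip_norm / norm) if norm > 0 else g.copy()
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    scale = np.minimum(1.0, clip_norm / np.maximum(norms, 1e-300))
    return g * scale


def noisy_step(
    per_sample_grads: np.ndarray,
    clip_norm: float,
    sigma: float,
    expected_batch: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One DP-SGD aggregation: clip, sum, add N(0, σ²C²) noise, divide by qN.

    ``per_sample_grads`` is (B, P); B may be zero (an empty Poisson batch is a
    legal step that releases pure noise).  The denominator is the *expected*
    batch size, which is what the sampled-Gaussian-mechanism analysis
    requires.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not expected_batch > 0:
        raise ValueError("expected_batch must be > 0")
    g = np.asarray(per_sample_grads, dtype=float)
    if g.ndim != 2:
        raise ValueError("per_sample_grads must be (B, P)")
    total = clip_per_sample(g, clip_norm).sum(axis=0) if g.shape[0] else np.zeros(
        g.shape[1]
    )
    if sigma > 0:
        total = total + rng.normal(scale=sigma * clip_norm, size=total.shape)
    return total / expected_batch


# --------------------------------------------------------------------------
# loss


def inverse_frequency_weights(labels: np.ndarray) -> np.ndarray:
    """Per-label positive weights: (negative count) / (positive count).

    Computed on the training split; labels without positives fall back to 1.
    """
    labels = np.asarray(labels)
    pos = labels.sum(axis=0).astype(float)
    neg = labels.shape[0] - pos
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(pos > 0, neg / np.maximum(pos, 1e-300), 1.0)
    return w


def weighted_bce_loss(
    probabilities: np.ndarray, targets: np.ndarray, pos_weights: np.ndarray | None
) -> np.ndarray:
    """Per-sample loss: mean over labels of −[w·y·ln p + (1−y)·ln(1−p)]."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(targets, dtype=float)
    if not np.all(np.isfinite(p)) or np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must be finite and inside (0, 1)")
    w = np.ones(p.shape[-1]) if pos_weights is None else np.asarray(pos_weights)
    terms = -(w * y * np.log(p) + (1.0 - y) * np.log1p(-p))
    return terms.mean(axis=-1)


def bce_loss_and_grad(
    logits: np.ndarray, targets: np.ndarray, pos_weights: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Numerically stable per-sample weighted BCE and its logit gradient."""
    z = np.asarray(logits, dtype=float)
    y = np.asarray(targets, dtype=float)
    w = np.ones(z.shape[-1]) if pos_weights is None else np.asarray(pos_weights)
    with np.errstate(invalid="ignore"):  # non-finite logits surface as NaN loss
        log_p = -np.logaddexp(0.0, -z)
        log_1mp = -np.logaddexp(0.0, z)
    loss = (-(w * y * log_p + (1.0 - y) * log_1mp)).mean(axis=-1)
    p = expit(z)
    dz = (-(w * y) * (1.0 - p) + (1.0 - y) * p) / z.shape[-1]
    return loss, dz.astype(logits.dtype, copy=False)


# --------------------------------------------------------------------------
# optimizers


class _Sgd:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params, self.lr = params, lr

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g in zip(self.params, grads):
            p -= self.lr * g


class _Nadam:
    """Nesterov-momentum Adam (plain bias-corrected variant)."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.lr = params, lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, t = self.b1, self.b2, self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            m_hat = m / (1 - b1 ** (t + 1))
            g_hat = g / (1 - b1**t)
            v_hat = v / (1 - b2**t)
            p -= self.lr * (b1 * m_hat + (1 - b1) * g_hat) / (np.sqrt(v_hat) + self.eps)


def _make_optimizer(kind: str, params: list[np.ndarray], lr: float):
    return _Nadam(params, lr) if kind == "nadam" else _Sgd(params, lr)


# --------------------------------------------------------------------------
# augmentation


def _augment(x: np.ndarray, cfg: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    out = x
    if cfg.augment_flip:
        flip = rng.random(x.shape[0]) < 0.5
        out = out.copy()
        out[flip] = out[flip][..., ::-1]  # mediolateral flip (last axis)
    if cfg.augment_rotate:
        out = out.copy()
        angles = rng.uniform(-10.0, 10.0, size=x.shape[0])
        for i in range(x.shape[0]):
            out[i] = nd_rotate(
                out[i], angles[i], axes=(-2, -1), reshape=False, order=1,
                mode="nearest",
            )
    return out


# --------------------------------------------------------------------------
# training loops


def _per_sample_flat(net: Network) -> np.ndarray:
    grads = net.per_sample_grads()
    b = grads[0].shape[0]
    return np.concatenate([g.reshape(b, -1) for g in grads], axis=1)


def _unflatten_like(flat: np.ndarray, params: list[np.ndarray]) -> list[np.ndarray]:
    out, i = [], 0
    for p in params:
        out.append(flat[i: i + p.size].reshape(p.shape))
        i += p.size
    return out


def train(
    train_ds: ArrayDataset,
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    eval_ds: ArrayDataset | None = None,
) -> tuple[TrainedModel, PredictionTable | None]:
    """Train a model and score the held-out split.

    Returns the trained model (with accounted privacy spend in DP mode) and a
    :class:`PredictionTable` over ``eval_ds`` if given.  Deterministic for a
    fixed seed and thread count.
    """
    x = train_ds.model_input().astype(model_cfg.dtype)
    y = train_ds.labels.astype(float)
    n = x.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7472]))
    net = build_model(model_cfg, seed=cfg.seed)
    params = net.params()
    opt = _make_optimizer(cfg.optimizer, params, cfg.learning_rate)
    pos_w = (
        inverse_frequency_weights(train_ds.labels)
        if cfg.loss_weighting == "inverted_class_frequency"
        else None
    )
    loss_trace: list[float] = []
    spend: PrivacySpend | None = None
    sigma = cfg.sigma

    if cfg.mode == "dp":
        q = min(cfg.batch_size / n, 1.0)
        steps_per_epoch = (
            max(int(round(n / cfg.batch_size)), 1)
            if cfg.steps_per_epoch_rule == "n_over_b"
            else max(int(round(1.0 / q)), 1)
        )
        total_steps = cfg.epochs * steps_per_epoch
        if sigma is None:
            if total_steps > 0:
                sigma = calibrate_sigma(
                    cfg.epsilon_target, cfg.delta, q, total_steps,
                    tolerance=cfg.calibration_tolerance,
                )
            else:
                sigma = 1.0  # no steps taken; only the δ term is spent
        expected_batch = q * n
        for step in range(total_steps):
            idx = poisson_sample(n, q, rng)
            if idx.size:
                loss, dz = bce_loss_and_grad(net.forward(x[idx]), y[idx], pos_w)
                if not np.all(np.isfinite(loss)):
                    raise FloatingPointError(
                        f"non-finite loss at DP step {step}; lower the learning rate"
                    )
                net.backward(dz)
                flat = _per_sample_flat(net)
                loss_trace.append(float(loss.mean()))
            else:
                # empty Poisson batch: a legal step that releases pure noise
                flat = np.zeros((0, net.n_params()))
                loss_trace.append(float("nan"))
            update = noisy_step(flat, cfg.clip_norm, sigma, expected_batch, rng)
            opt.step(_unflatten_like(update, params))
        if sigma == 0.0:
            spend = None  # noiseless diagnostic run: no finite guarantee
        else:
            spend = account(MechanismParams(q, sigma, total_steps, cfg.delta))
        if spend is not None and total_steps > 0 and (
            cfg.epsilon_target is not None
        ) and spend.epsilon > (
            cfg.epsilon_target + cfg.calibration_tolerance
        ):
            raise RuntimeError(
                f"accounted epsilon {spend.epsilon:.4f} exceeds target "
                f"{cfg.epsilon_target}+tolerance"
            )
    else:
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start: start + cfg.batch_size]
                xb = _augment(x[idx], cfg, rng)
                loss, dz = bce_loss_and_grad(net.forward(xb), y[idx], pos_w)
                if not np.all(np.isfinite(loss)):
                    raise FloatingPointError(
                        f"NaN loss in epoch {epoch}; lower the learning rate"
                    )
                net.backward(dz)
                mean_grads = [g.mean(axis=0) for g in net.per_sample_grads()]
                opt.step(mean_grads)
                loss_trace.append(float(loss.mean()))

    manifest = {
        "seed": cfg.seed,
        "optimizer": cfg.optimizer,
        "mode": cfg.mode,
        "sigma": sigma,
        "numpy_version": np.__version__,
    }
    model = TrainedModel(net, model_cfg, cfg, spend, loss_trace, manifest)
    table = model.predict_table(eval_ds) if eval_ds is not None else None
    return model, table


# --------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: TrainedModel, path) -> None:
    """Single-file archive: weights + configs + spend + seed manifest."""
    import json

    payload = {
        f"param_{i}": p for i, p in enumerate(model.network.params())
    }
    meta = {
        "model_config": model.model_config.__dict__,
        "train_config": {
            k: v for k, v in model.train_config.__dict__.items()
        },
        "spend": None
        if model.spend is None
        else {
            "epsilon": model.spend.epsilon,
            "delta": model.spend.delta,
            "optimal_order": model.spend.optimal_order,
        },
        "seed_manifest": model.seed_manifest,
        "loss_trace": model.loss_trace,
    }
    np.savez(path, meta=json.dumps(meta, default=list), **payload)


def load_checkpoint(path) -> TrainedModel:
    import json

    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        mc = meta["model_config"]
        mc["widths"] = tuple(mc["widths"])
        model_cfg = ModelConfig(**mc)
        net = build_model(model_cfg, seed=meta["seed_manifest"]["seed"])
        net.set_params([f[f"param_{i}"] for i in range(len(net.params()))])
    spend = (
        PrivacySpend(**meta["spend"]) if meta["spend"] is not None else None
    )
    return TrainedModel(
        net,
        model_cfg,
        TrainConfig(**meta["train_config"]),
        spend,
        list(meta["loss_trace"]),
        meta["seed_manifest"],
    )
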