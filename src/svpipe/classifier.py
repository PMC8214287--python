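"""Informative-read classification with a small fully-connected network.

An "informative read" is a read the fast aligner maps contiguously but the
accurate, SV-sensitive aligner would split — exactly the reads worth paying
the accurate aligner's cost for. They are rare (well under 1% of a typical
PacBio run), so training weights classes by inverse frequency and the
decision threshold errs toward recall: a missed informative read costs
sensitivity, a false positive only costs re-alignment time.

The architecture is fixed: five tanh hidden layers of 18, 30, 18, 11 and 5
units over the standardized 21-feature input, with a single sigmoid output.
Training is plain mini-batch Adam on weighted binary cross-entropy with
early stopping; everything is seeded and reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment import SCHEMA_VERSION, FeatureVector, is_split
from .errors import SchemaError

log = logging.getLogger(__name__)

HIDDEN_DIMS = (18, 30, 18, 11, 5)
MODEL_FORMAT = "svpipe-mlp/1"

EXCLUDED = "excluded"


@dataclass
class MLPModel:
    """Weights, biases and input standardization of the trained network.

    ``weights[i]`` has shape ``(layer_dims[i], layer_dims[i+1])``; hidden
    activations are tanh, the output is a sigmoid probability. Inputs are
    z-scored with ``feature_means`` / ``feature_sds`` before the first layer
    (constant features carry sd 1).
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    schema_version: str = SCHEMA_VERSION
    threshold: float = 0.5

    @property
    def layer_dims(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def __post_init__(self) -> None:
        dims = self.layer_dims
        expected = [dims[0], *HIDDEN_DIMS, 1]
        if dims != expected:
            raise SchemaError(f"layer dims {dims} != required {expected}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if np.any(self.feature_sds <= 0):
            raise ValueError("feature_sds must be positive")


def _init_model(n_features: int, seed: int) -> MLPModel:
    # symmetric uniform scaled by fan-in, fully determined by the seed
    rng = np.random.default_rng(seed)
    dims = [n_features, *HIDDEN_DIMS, 1]
    weights = []
    biases = []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPModel(
        weights=weights,
        biases=biases,
        feature_means=np.zeros(n_features),
        feature_sds=np.ones(n_features),
    )


def _standardize(model: MLPModel, X: np.ndarray) -> np.ndarray:
    return (X - model.feature_means) / model.feature_sds


def forward_batch(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Class-1 probabilities for a feature matrix (rows = reads)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.weights[0].shape[0]:
        raise SchemaError(
            f"input width {X.shape[1]} != model input {model.weights[0].shape[0]}"
        )
    a = _standardize(model, X)
    last = len(model.weights) - 1
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W + b
        a = 1.0 / (1.0 + np.exp(-z)) if i == last else np.tanh(z)
    return a[:, 0]


def forward(model: MLPModel, fv: FeatureVector) -> float:
    """Probability that one read is informative."""
    if fv.schema_version != model.schema_version:
        raise SchemaError(
            f"feature schema {fv.schema_version!r} != model schema "
            f"{model.schema_version!r}"
        )
    return float(forward_batch(model, fv.values[None, :])[0])


def classify(model: MLPModel, fvs: Sequence[FeatureVector] | np.ndarray) -> np.ndarray:
    """Binary labels: 1 iff the forward probability reaches the threshold.

    The boundary is inclusive (p == threshold → 1), preferring recall.
    """
    if isinstance(fvs, np.ndarray):
        X = fvs
    else:
        for fv in fvs:
            if fv.schema_version != model.schema_version:
                raise SchemaError("feature/model schema version mismatch")
        X = np.array([fv.values for fv in fvs])
    if X.shape[0] == 0:
        return np.zeros(0, dtype=int)
    p = forward_batch(model, X)
    return (p >= model.threshold).astype(int)


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults suit rare-positive read data."""

    learning_rate: float = 3e-3
    epochs: int = 400
    batch_size: int = 128
    l2: float = 1e-5
    val_fraction: float = 0.1
    patience: int = 40
    class_weighting: bool = True
    threshold: float = 0.5


@dataclass
class TrainReport:
    final_loss: float
    epochs_run: int
    accuracy_class0: float
    accuracy_class1: float
    history: list[float] = field(default_factory=list)


def _bce_grad(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    return w * (p - y)


def _weighted_bce(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    eps = 1e-12
    return float(
        np.mean(-w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    )


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[MLPModel, TrainReport]:
    """Fit the fixed-architecture network on a labeled feature matrix.

    Both classes must be present. Class imbalance is handled by weighting
    each example inversely to its class frequency; a stratified validation
    split drives early stopping. Identical inputs and seed give identical
    weights.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y shapes disagree")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("training set must contain both classes (labels 0 and 1)")

    model = _init_model(X.shape[1], seed)
    model.threshold = config.threshold
    model.feature_means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds[sds == 0] = 1.0
    model.feature_sds = sds

    n = X.shape[0]
    n_pos = int(y.sum())
    if config.class_weighting:
        w_pos = n / (2.0 * n_pos)
        w_neg = n / (2.0 * (n - n_pos))
    else:
        w_pos = w_neg = 1.0
    sample_w = np.where(y == 1, w_pos, w_neg)

    # stratified validation split for early stopping
    rng = np.random.default_rng(seed + 1)
    idx_pos = rng.permutation(np.flatnonzero(y == 1))
    idx_neg = rng.permutation(np.flatnonzero(y == 0))
    n_vp = max(1, int(len(idx_pos) * config.val_fraction))
    n_vn = max(1, int(len(idx_neg) * config.val_fraction))
    val_idx = np.concatenate([idx_pos[:n_vp], idx_neg[:n_vn]])
    tr_idx = np.concatenate([idx_pos[n_vp:], idx_neg[n_vn:]])
    if len(tr_idx) == 0:
        tr_idx = val_idx

    Xs = _standardize(model, X)
    Xtr, ytr, wtr = Xs[tr_idx], y[tr_idx], sample_w[tr_idx]
    Xval, yval, wval = Xs[val_idx], y[val_idx], sample_w[val_idx]

    W = [w.copy() for w in model.weights]
    B = [b.copy() for b in model.biases]
    mW = [np.zeros_like(w) for w in W]
    vW = [np.zeros_like(w) for w in W]
    mB = [np.zeros_like(b) for b in B]
    vB = [np.zeros_like(b) for b in B]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    best_val = np.inf
    best = None
    stale = 0
    history: list[float] = []
    shuffle_rng = np.random.default_rng(seed + 2)
    last = len(W) - 1

    def fwd(Xb: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        acts = [Xb]
        a = Xb
        for i in range(len(W)):
            z = a @ W[i] + B[i]
            a = 1.0 / (1.0 + np.exp(-z)) if i == last else np.tanh(z)
            acts.append(a)
        return acts, acts[-1][:, 0]

    epochs_run = 0
    for epoch in range(config.epochs):
        epochs_run = epoch + 1
        order = shuffle_rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), config.batch_size):
            sel = order[start : start + config.batch_size]
            Xb, yb, wb = Xtr[sel], ytr[sel], wtr[sel]
            acts, p = fwd(Xb)
            t += 1
            delta = (_bce_grad(p, yb, wb) / len(Xb))[:, None]
            for i in range(last, -1, -1):
                gW = acts[i].T @ delta + config.l2 * W[i]
                gB = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ W[i].T) * (1.0 - acts[i] ** 2)
                mW[i] = beta1 * mW[i] + (1 - beta1) * gW
                vW[i] = beta2 * vW[i] + (1 - beta2) * gW**2
                mB[i] = beta1 * mB[i] + (1 - beta1) * gB
                vB[i] = beta2 * vB[i] + (1 - beta2) * gB**2
                lr_t = config.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
                W[i] -= lr_t * mW[i] / (np.sqrt(vW[i]) + eps)
                B[i] -= lr_t * mB[i] / (np.sqrt(vB[i]) + eps)

        _, pval = fwd(Xval)
        val_loss = _weighted_bce(pval, yval, wval)
        history.append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best = ([w.copy() for w in W], [b.copy() for b in B])
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    if best is not None:
        W, B = best
    model.weights = W
    model.biases = B

    _, p_all = fwd(Xs)
    final_loss = _weighted_bce(p_all, y, sample_w)
    pred = (p_all >= model.threshold).astype(int)
    acc0 = float(np.mean(pred[y == 0] == 0)) if (y == 0).any() else float("nan")
    acc1 = float(np.mean(pred[y == 1] == 1)) if (y == 1).any() else float("nan")
    report = TrainReport(
        final_loss=final_loss,
        epochs_run=epochs_run,
        accuracy_class0=acc0,
        accuracy_class1=acc1,
        history=history,
    )
    log.info(
        "training done: loss=%.4f epochs=%d acc0=%.3f acc1=%.3f",
        final_loss,
        epochs_run,
        acc0,
        acc1,
    )
    return model, report


# ---------------------------------------------------------------------------
# Labeling from paired aligner outputs
# ---------------------------------------------------------------------------


def label_reads(
    fast_alignments: Mapping[str, Sequence],
    accurate_alignments: Mapping[str, Sequence],
) -> dict[str, object]:
    """Derive training labels by comparing the two aligners' split decisions.

    A read split by the fast aligner is excluded (it is re-aligned
    unconditionally, so the classifier never sees it). A read the fast
    aligner kept whole but the accurate aligner split is informative (1);
    a read split by neither is background (0). Reads present in only one
    output are excluded and counted.
    """
    common = set(fast_alignments) & set(accurate_alignments)
    if not common:
        raise ValueError("no read names shared between the two alignment sets")
    missing = (set(fast_alignments) | set(accurate_alignments)) - common
    if missing:
        log.info("label_reads: %d reads absent from one aligner, excluded", len(missing))
    labels: dict[str, object] = {name: EXCLUDED for name in missing}
    for name in common:
        if is_split(fast_alignments[name]):
            labels[name] = EXCLUDED
        elif is_split(accurate_alignments[name]):
            labels[name] = 1
        else:
            labels[name] = 0
    return labels


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: MLPModel, path: str) -> None:
    """Write the model as versioned JSON (row-major weight arrays)."""
    payload = {
        "format": MODEL_FORMAT,
        "schema_version": model.schema_version,
        "layer_dims": model.layer_dims,
        "threshold": model.threshold,
        "feature_means": model.feature_means.tolist(),
        "feature_sds": model.feature_sds.tolist(),
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str) -> MLPModel:
    """Load a model written by :func:`save_model`; refuses foreign formats."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise SchemaError(f"unreadable model file {path}: {exc}") from exc
    if payload.get("format") != MODEL_FORMAT:
        raise SchemaError(
            f"model format {payload.get('format')!r} unsupported "
            f"(expected {MODEL_FORMAT!r})"
        )
    try:
        model = MLPModel(
            weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
            biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
            feature_means=np.asarray(payload["feature_means"], dtype=float),
            feature_sds=np.asarray(payload["feature_sds"], dtype=float),
            schema_version=payload["schema_version"],
            threshold=float(payload["threshold"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed model file {path}: {exc}") from exc
    if model.layer_dims != payload["layer_dims"]:
        raise SchemaError("stored layer_dims disagree with weight shapes")
    return model
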