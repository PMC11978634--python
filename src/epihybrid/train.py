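"""Desk-scale training of the CNN feature extractor and the SVM classifier.

The CNN stack is trained with a temporary logistic head: mini-batch
gradient descent with Adam-style per-parameter step normalisation on the
binary cross-entropy, gradients clipped by global norm, everything in
double precision for stability. The head is discarded
and the convolution weights are rounded to float32 at export so inference
sees the same single-precision bundle the hardware would. The SVM is then
trained by SMO on features produced by the *inference* extractor (the
float32 path), so there is no train/serve skew in the feature pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cnn import (
    CNNModel,
    ConvLayerSpec,
    FEATURE_LENGTH,
    extract_features,
)
from .errors import ConfigError, TrainingError
from .fft import fft256
from .frames import EEGFrame
from .metrics import ConfusionCounts, accumulate
from .smo import median_sq_distance, rbf_kernel_matrix, smo_train
from .svm import SVMModel, decision_function

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "PipelineTrainResult",
    "train_cnn",
    "train_svm",
    "train_pipeline",
    "frames_to_inputs",
    "extract_feature_matrix",
    "kkt_diagnostics",
]

_KERNEL_SIZES = (5, 3, 1)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the desk-scale trainer."""

    epochs: int = 12
    learning_rate: float = 0.01
    batch_size: int = 32
    seed: int = 0
    momentum: float = 0.9
    grad_clip: float = 5.0
    smo_C: float = 10.0
    smo_tol: float = 1e-3
    smo_max_passes: int = 10
    sigma: float | None = None  # None -> median pairwise distance heuristic
    holdout_fraction: float = 0.2

    def validate(self) -> None:
        if self.epochs < 0:
            raise ConfigError("epochs: must be nonnegative")
        if self.learning_rate < 0:
            raise ConfigError("learning_rate: must be nonnegative")
        if self.batch_size < 1:
            raise ConfigError("batch_size: must be positive")
        if not 0 <= self.momentum < 1:
            raise ConfigError("momentum: must lie in [0, 1)")
        if self.smo_C <= 0 or self.smo_tol <= 0 or self.smo_max_passes < 1:
            raise ConfigError("smo_C, smo_tol, smo_max_passes: must be positive")
        if self.sigma is not None and self.sigma <= 0:
            raise ConfigError("sigma: must be positive when given")
        if not 0 < self.holdout_fraction < 1:
            raise ConfigError("holdout_fraction: must lie in (0, 1)")


@dataclass
class TrainHistory:
    """Per-epoch loss and final temporary-head training accuracy."""

    losses: list[float] = field(default_factory=list)
    head_accuracy: float = 0.0
    feature_scale: float = 1.0
    smo_passes: int = 0
    smo_updates: int = 0


@dataclass
class PipelineTrainResult:
    cnn_model: CNNModel
    svm_model: SVMModel
    counts: ConfusionCounts
    history: TrainHistory
    train_indices: np.ndarray
    test_indices: np.ndarray


# ---------------------------------------------------------------------------
# Batched double-precision forward/backward for training
# ---------------------------------------------------------------------------

def _conv_fwd(x: np.ndarray, w: np.ndarray, b: float):
    k = w.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    y = np.einsum("nhwij,ij->nhw", win, w, optimize=True) + b
    return y, win


def _conv_bwd(win: np.ndarray, w: np.ndarray, dy: np.ndarray, in_shape):
    k = w.shape[0]
    dw = np.einsum("nhwij,nhw->ij", win, dy, optimize=True)
    db = float(dy.sum())
    pad = k - 1
    dyp = np.pad(dy, ((0, 0), (pad, pad), (pad, pad)))
    win_d = np.lib.stride_tricks.sliding_window_view(dyp, (k, k), axis=(1, 2))
    dx = np.einsum("nhwij,ij->nhw", win_d, w[::-1, ::-1], optimize=True)
    return dw, db, dx[:, : in_shape[1], : in_shape[2]]


def _pool_fwd(x: np.ndarray):
    n, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, : 2 * h2, : 2 * w2].reshape(n, h2, 2, w2, 2)
    y = xc.max(axis=(2, 4))
    mask = xc == y[:, :, None, :, None]
    return y, (mask, x.shape)


def _pool_bwd(cache, dy: np.ndarray):
    mask, in_shape = cache
    n, h, w = in_shape
    h2, w2 = mask.shape[1], mask.shape[3]
    # split gradient evenly among tied maxima so it is conserved
    counts = mask.sum(axis=(2, 4), keepdims=True)
    g = mask * (dy[:, :, None, :, None] / counts)
    dx = np.zeros(in_shape)
    dx[:, : 2 * h2, : 2 * w2] = g.reshape(n, 2 * h2, 2 * w2)
    return dx


def _forward_stack(x: np.ndarray, params: dict):
    caches = []
    cur = x
    for li, k in enumerate(_KERNEL_SIZES):
        y, win = _conv_fwd(cur, params[f"W{li}"], params[f"b{li}"])
        relu_mask = y > 0
        y = y * relu_mask
        p, pcache = _pool_fwd(y)
        caches.append((win, cur.shape, relu_mask, pcache))
        cur = p
    feats = cur.reshape(cur.shape[0], -1)
    return feats, caches


def _backward_stack(dfeats: np.ndarray, caches, params: dict, final_shape):
    grads = {}
    dcur = dfeats.reshape(final_shape)
    for li in reversed(range(len(_KERNEL_SIZES))):
        win, in_shape, relu_mask, pcache = caches[li]
        dy = _pool_bwd(pcache, dcur)
        dy = dy * relu_mask
        dw, db, dcur = _conv_bwd(win, params[f"W{li}"], dy, in_shape)
        grads[f"W{li}"] = dw
        grads[f"b{li}"] = db
    return grads, dcur


def _init_params(rng: np.random.Generator) -> dict:
    params = {}
    for li, k in enumerate(_KERNEL_SIZES):
        params[f"W{li}"] = rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(k, k))
        # small positive bias keeps the ReLU chain alive on nonnegative
        # spectral inputs
        params[f"b{li}"] = 0.01
    params["wh"] = rng.normal(0.0, 1.0 / np.sqrt(FEATURE_LENGTH), size=FEATURE_LENGTH)
    params["bh"] = 0.0
    return params


def frames_to_inputs(frames: Sequence[EEGFrame], use_fft_frontend: bool = True) -> np.ndarray:
    """Stack frames into an (N, 20, 256) array, optionally through the FFT
    amplitude front-end (the default detector configuration)."""
    data = np.stack([f.data for f in frames])
    if use_fft_frontend:
        return np.abs(fft256(data)).astype(np.float32)
    return data


def _labels_of(frames: Sequence[EEGFrame]) -> np.ndarray:
    labels = np.array([-1 if f.label is None else int(f.label) for f in frames])
    if np.any(labels < 0):
        raise TrainingError("all training frames must be labeled")
    return labels


def train_cnn(
    frames: Sequence[EEGFrame],
    cfg: TrainConfig,
    use_fft_frontend: bool = True,
) -> tuple[CNNModel, TrainHistory]:
    """Fit the 3-layer conv stack with a discardable logistic head.

    Deterministic under ``cfg.seed``. Raises :class:`TrainingError` if only
    one class is present. With ``learning_rate == 0`` the returned weights
    equal the seeded initialization.
    """
    cfg.validate()
    y = _labels_of(frames)
    if len(np.unique(y)) < 2:
        raise TrainingError("training requires both ictal and interictal frames")
    X = frames_to_inputs(frames, use_fft_frontend).astype(np.float64)
    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed)
    params = _init_params(rng)
    # Adam moment estimates: the raw spectral magnitudes put the layers'
    # gradient scales orders of magnitude apart, which plain SGD cannot
    # survive without per-layer tuning; Adam normalises per parameter.
    m1 = {k: np.zeros_like(np.asarray(v, dtype=np.float64)) for k, v in params.items()}
    m2 = {k: np.zeros_like(np.asarray(v, dtype=np.float64)) for k, v in params.items()}
    beta1, beta2, adam_eps = cfg.momentum, 0.999, 1e-8
    step = 0

    # Freeze a head-input scale from the initial forward pass so the logits
    # start O(1) regardless of the raw spectral magnitudes.
    feats0, _ = _forward_stack(X[: min(n, 4 * cfg.batch_size)], params)
    scale = float(np.std(feats0)) or 1.0

    history = TrainHistory(feature_scale=scale)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx].astype(np.float64)
            feats, caches = _forward_stack(xb, params)
            fs = feats / scale
            logits = fs @ params["wh"] + params["bh"]
            p = 1.0 / (1.0 + np.exp(-logits))
            eps = 1e-12
            loss = -np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))
            epoch_loss += loss * len(idx)

            dlogit = (p - yb) / len(idx)
            grads = {
                "wh": fs.T @ dlogit,
                "bh": float(dlogit.sum()),
            }
            dfeats = np.outer(dlogit, params["wh"]) / scale
            final_shape = (len(idx), 1, FEATURE_LENGTH)
            conv_grads, _ = _backward_stack(dfeats, caches, params, final_shape)
            grads.update(conv_grads)

            gnorm = np.sqrt(
                sum(float(np.sum(np.asarray(g) ** 2)) for g in grads.values())
            )
            clip = min(1.0, cfg.grad_clip / (gnorm + 1e-12))
            step += 1
            for key in params:
                g = np.asarray(grads[key]) * clip
                m1[key] = beta1 * m1[key] + (1 - beta1) * g
                m2[key] = beta2 * m2[key] + (1 - beta2) * g * g
                mhat = m1[key] / (1 - beta1**step)
                vhat = m2[key] / (1 - beta2**step)
                update = cfg.learning_rate * mhat / (np.sqrt(vhat) + adam_eps)
                params[key] = np.asarray(params[key], dtype=np.float64) - update
        history.losses.append(epoch_loss / n)

    feats, _ = _forward_stack(X, params)
    logits = (feats / scale) @ params["wh"] + params["bh"]
    history.head_accuracy = float(np.mean((logits >= 0).astype(int) == y))

    layers = tuple(
        ConvLayerSpec(
            weights=np.asarray(params[f"W{li}"], dtype=np.float32),
            bias=np.float32(np.asarray(params[f"b{li}"], dtype=np.float64)),
            activation="relu",
        )
        for li in range(3)
    )
    return CNNModel(layers=layers), history  # type: ignore[arg-type]


def extract_feature_matrix(
    inputs: np.ndarray, model: CNNModel
) -> np.ndarray:
    """Run the float32 inference extractor over (N, 20, 256) inputs."""
    feats = np.empty((inputs.shape[0], FEATURE_LENGTH), dtype=np.float32)
    for i in range(inputs.shape[0]):
        fv, _ = extract_features(inputs[i], model)
        feats[i] = fv.values
    return feats


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
) -> tuple[SVMModel, dict]:
    """SMO training of the quasi-Gaussian-kernel SVM on extracted features.

    gamma_eff follows the min-max normalisation convention: at build time
    every training feature is a candidate support value, so the support and
    feature extrema coincide and gamma_eff = 1/sigma; sigma defaults to the
    median pairwise squared distance. The retained support vectors' extrema
    are recorded on the model but gamma_eff stays frozen at its training
    value so inference matches training exactly.
    """
    cfg.validate()
    F = np.asarray(features, dtype=np.float32)
    y01 = np.asarray(labels).astype(int)
    if F.ndim != 2 or F.shape[1] != FEATURE_LENGTH:
        raise TrainingError(f"features must be N x {FEATURE_LENGTH}, got {F.shape}")
    classes, counts = np.unique(y01, return_counts=True)
    if len(classes) < 2:
        raise TrainingError("SVM training requires both classes present")
    f_min, f_max = float(F.min()), float(F.max())
    if not f_max > f_min:
        raise TrainingError("degenerate features: all values identical")

    rng = np.random.default_rng(cfg.seed)
    sigma = cfg.sigma if cfg.sigma is not None else median_sq_distance(F, rng)
    f_range = f_max - f_min
    gamma = (f_range**2) / (sigma * f_range**2)  # = 1/sigma; extrema coincide at build
    y = np.where(y01 == 1, 1.0, -1.0)
    K = rbf_kernel_matrix(F, gamma)
    result = smo_train(
        K,
        y,
        C=cfg.smo_C,
        tol=cfg.smo_tol,
        max_passes=cfg.smo_max_passes,
        seed=cfg.seed,
    )
    mask = result.alpha > 1e-8
    if not np.any(mask):
        raise TrainingError("SMO retained no support vectors")
    sv = F[mask]
    model = SVMModel(
        support_vectors=sv,
        alphas=(result.alpha[mask] * y[mask]).astype(np.float32),
        b=np.float32(-result.b),
        sigma=float(sigma),
        s_max=float(sv.max()),
        s_min=float(sv.min()),
        f_max=f_max,
        f_min=f_min,
        gamma_eff=np.float32(gamma),
        log_transform=False,
    )
    diagnostics = {
        "n_support": int(mask.sum()),
        "smo_passes": result.n_passes,
        "smo_updates": result.n_updates,
        "converged": result.converged,
        "alpha": result.alpha,
        "y": y,
        "C": cfg.smo_C,
    }
    return model, diagnostics


def kkt_diagnostics(diag: dict) -> dict:
    """Box-constraint and equality-constraint residuals of an SMO solution."""
    alpha, y, C = diag["alpha"], diag["y"], diag["C"]
    return {
        "max_box_violation": float(
            max(np.max(-alpha, initial=0.0), np.max(alpha - C, initial=0.0))
        ),
        "sum_alpha_y": float(np.dot(alpha, y)),
    }


def _stratified_split(y: np.ndarray, holdout: float, rng: np.random.Generator):
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_test = max(1, int(round(len(idx) * holdout)))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def train_pipeline(
    frames: Sequence[EEGFrame],
    cfg: TrainConfig,
    use_fft_frontend: bool = True,
) -> PipelineTrainResult:
    """Chain train_cnn -> inference-path feature extraction -> train_svm,
    then evaluate on the stratified held-out split."""
    cfg.validate()
    y = _labels_of(frames)
    if len(np.unique(y)) < 2:
        raise TrainingError("training requires both ictal and interictal frames")
    rng = np.random.default_rng(cfg.seed)
    train_idx, test_idx = _stratified_split(y, cfg.holdout_fraction, rng)
    train_frames = [frames[i] for i in train_idx]
    test_frames = [frames[i] for i in test_idx]

    cnn_model, history = train_cnn(train_frames, cfg, use_fft_frontend)

    train_inputs = frames_to_inputs(train_frames, use_fft_frontend)
    F_train = extract_feature_matrix(train_inputs, cnn_model)
    svm_model, diag = train_svm(F_train, y[train_idx], cfg)
    history.smo_passes = diag["smo_passes"]
    history.smo_updates = diag["smo_updates"]

    test_inputs = frames_to_inputs(test_frames, use_fft_frontend)
    F_test = extract_feature_matrix(test_inputs, cnn_model)
    decisions = [
        (decision_function(F_test[i], svm_model), int(y[test_idx][i]))
        for i in range(len(test_frames))
    ]
    counts = accumulate(decisions)
    return PipelineTrainResult(
        cnn_model=cnn_model,
        svm_model=svm_model,
        counts=counts,
        history=history,
        train_indices=train_idx,
        test_indices=test_idx,
    )
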