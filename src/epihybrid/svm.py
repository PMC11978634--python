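"""Quasi-Gaussian-kernel SVM decision function and its DPU dataflow twin.

The decision function is the standard RBF-kernel score

    f(x) = sum_i alpha_i * exp(-gamma_eff * ||u(x) - u(sv_i)||^2) - b

where ``alpha_i`` carries the class label sign, ``gamma_eff`` folds the
kernel scale sigma together with the min-max normalisation constants of
the training features (f) and support values (s):

    gamma_eff = (s_max - s_min)^2 / (sigma * (f_max - f_min)^2)

and ``u`` is either the identity or an element-wise natural-log transform
(the hardware's normalisation path), selected by ``log_transform``.

Two evaluation routes exist. ``decision_function`` is the reference:
float32 arithmetic, support vectors visited in ascending index order.
``dpu_dataflow_eval`` emulates the hardware data processing unit --
subtraction as addition of the negation, squaring through the multiplier,
scaling, CORDIC exponential, sequential multiply-accumulate with alpha,
and a final addition of the negated offset b. Both routes perform the
same float32 operations in the same order, so their scores agree bit for
bit and their labels always coincide. The exponential in both routes is
``cordic_exp``; the log transform is ``cordic_ln``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cnn import FEATURE_LENGTH, FeatureVector
from .cordic import cordic_exp, cordic_ln
from .errors import BundleError, ConfigError, DomainError

__all__ = [
    "SVMModel",
    "Decision",
    "kernel_eval",
    "decision_function",
    "dpu_dataflow_eval",
    "SupportVectorROM",
    "save_svm_bundle",
    "load_svm_bundle",
]

#: Epsilon floor admitting zero-valued post-ReLU features under the ln
#: transform when enabled on the model.
DEFAULT_EPSILON_FLOOR = 1e-7


@dataclass(frozen=True)
class SVMModel:
    """Trained SVM parameters.

    ``alphas`` are the signed dual coefficients (label folded in); ``b``
    is subtracted from the accumulated kernel sum. ``s_max/s_min`` and
    ``f_max/f_min`` record the support-value and training-feature extrema
    entering the gamma_eff normalisation; ``gamma_eff`` itself is frozen
    at training time so inference never recomputes it.
    """

    support_vectors: np.ndarray
    alphas: np.ndarray
    b: float
    sigma: float
    s_max: float
    s_min: float
    f_max: float
    f_min: float
    gamma_eff: float
    log_transform: bool = False
    epsilon_floor: float | None = None

    def __post_init__(self) -> None:
        sv = np.asarray(self.support_vectors, dtype=np.float32)
        al = np.asarray(self.alphas, dtype=np.float32)
        if sv.ndim != 2 or sv.shape[1] != FEATURE_LENGTH:
            raise ConfigError(
                f"support_vectors must be L x {FEATURE_LENGTH}, got {sv.shape}"
            )
        if sv.shape[0] < 1:
            raise ConfigError("need at least one support vector")
        if al.shape != (sv.shape[0],):
            raise ConfigError("alphas must align with support_vectors rows")
        if not self.gamma_eff > 0:
            raise ConfigError("gamma_eff must be positive")
        if not self.f_max > self.f_min:
            raise ConfigError("f_max must exceed f_min")
        if self.s_max < self.s_min:
            raise ConfigError("s_max must be >= s_min")
        if not self.sigma > 0:
            raise ConfigError("sigma must be positive")
        object.__setattr__(self, "support_vectors", sv)
        object.__setattr__(self, "alphas", al)
        object.__setattr__(self, "b", np.float32(self.b))
        object.__setattr__(self, "gamma_eff", np.float32(self.gamma_eff))

    @property
    def n_support(self) -> int:
        return int(self.support_vectors.shape[0])

    @classmethod
    def from_components(
        cls,
        support_vectors: np.ndarray,
        alphas: np.ndarray,
        b: float,
        sigma: float,
        f_extrema: tuple[float, float],
        log_transform: bool = False,
        epsilon_floor: float | None = None,
    ) -> "SVMModel":
        """Build a model computing gamma_eff from the extrema and sigma."""
        sv = np.asarray(support_vectors, dtype=np.float32)
        f_min, f_max = (float(min(f_extrema)), float(max(f_extrema)))
        s_min, s_max = float(sv.min()), float(sv.max())
        gamma = (s_max - s_min) ** 2 / (sigma * (f_max - f_min) ** 2)
        return cls(
            support_vectors=sv,
            alphas=alphas,
            b=b,
            sigma=sigma,
            s_max=s_max,
            s_min=s_min,
            f_max=f_max,
            f_min=f_min,
            gamma_eff=gamma,
            log_transform=log_transform,
            epsilon_floor=epsilon_floor,
        )


@dataclass(frozen=True)
class Decision:
    """Classifier output: float32 score and its sign label
    (score >= 0 -> ictal)."""

    score: float
    label: int

    def __post_init__(self) -> None:
        expected = 1 if self.score >= 0 else 0
        if self.label != expected:
            raise ConfigError("label must equal the sign convention of score")

    @classmethod
    def from_score(cls, score) -> "Decision":
        s = np.float32(score)
        return cls(score=float(s), label=1 if s >= 0 else 0)


def _as_feature_array(x) -> np.ndarray:
    if isinstance(x, FeatureVector):
        return x.values
    arr = np.asarray(x, dtype=np.float32)
    if arr.shape != (FEATURE_LENGTH,):
        raise ConfigError(f"feature vector must have length {FEATURE_LENGTH}")
    return arr


def _transform(u: np.ndarray, model: SVMModel) -> np.ndarray:
    """Optional ln-normalisation of features/support values (CORDIC path)."""
    if not model.log_transform:
        return u
    if model.epsilon_floor is not None:
        u = np.maximum(u, np.float32(model.epsilon_floor))
    elif np.any(u <= 0):
        raise DomainError(
            "log_transform requires strictly positive values; enable the "
            "epsilon_floor option to admit zero-valued ReLU features"
        )
    return cordic_ln(u)


def _ssd_fp32(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Sum of squared differences in float32, accumulated element by
    element in ascending feature order (matches the sequential DPU)."""
    d = (u - v).astype(np.float32)
    acc = d[..., 0] * d[..., 0]
    for j in range(1, d.shape[-1]):
        acc = acc + d[..., j] * d[..., j]
    return np.asarray(acc, dtype=np.float32)


def kernel_eval(x, sv_row: np.ndarray, model: SVMModel):
    """Quasi-Gaussian kernel exp(-gamma_eff * ||u - v||^2) in (0, 1]."""
    u = _transform(_as_feature_array(x), model)
    v = _transform(np.asarray(sv_row, dtype=np.float32), model)
    acc = _ssd_fp32(u, v)
    arg = -(model.gamma_eff * acc)
    # saturate at 1: the CORDIC exponential carries ~1e-5 relative error, and
    # a kernel value above 1 would be outside the Gaussian kernel's range
    return np.minimum(cordic_exp(arg), np.float32(1.0))


def decision_function(x, model: SVMModel) -> Decision:
    """Reference evaluation of the decision score, support vectors in
    ascending index order, float32 accumulation."""
    u = _transform(_as_feature_array(x), model)
    sv = _transform(model.support_vectors, model)
    acc = _ssd_fp32(u[None, :], sv)  # (L,)
    kern = np.minimum(cordic_exp(-(model.gamma_eff * acc)), np.float32(1.0))
    score = np.float32(0.0)
    for i in range(model.n_support):
        score = np.float32(score + model.alphas[i] * kern[i])
    score = np.float32(score - model.b)
    return Decision.from_score(score)


class SupportVectorROM:
    """Sequential-access emulation of the off-chip support-vector ROM/FIFO.

    Rows are served strictly in storage order; every access is counted so
    tests can assert the access pattern. No timing is modelled.
    """

    def __init__(self, model: SVMModel):
        self._sv = model.support_vectors
        self._alphas = model.alphas
        self._cursor = 0
        self.reads = 0

    def __iter__(self):
        self._cursor = 0
        return self

    def __next__(self) -> tuple[np.ndarray, np.float32]:
        if self._cursor >= self._sv.shape[0]:
            raise StopIteration
        row = self._sv[self._cursor]
        alpha = self._alphas[self._cursor]
        self._cursor += 1
        self.reads += 1
        return row, alpha


def dpu_dataflow_eval(x, model: SVMModel) -> Decision:
    """DPU-sequence evaluation of the decision function.

    Emulates the hardware order of operations per support vector read from
    the sequential ROM: add the negated support value, square through the
    multiplier, accumulate, scale by gamma_eff, CORDIC exponential,
    multiply by alpha and accumulate; finally add the negated offset b.
    Bit-identical in score to :func:`decision_function`.
    """
    u = _transform(_as_feature_array(x), model)
    rom = SupportVectorROM(model)
    mac = np.float32(0.0)
    for row, alpha in rom:
        v = _transform(row, model)
        neg_v = -v  # inverse code of the support vector
        diff = (u + neg_v).astype(np.float32)
        sq_acc = np.float32(diff[0] * diff[0])  # squaring via the multiplier
        for j in range(1, diff.shape[0]):
            sq_acc = np.float32(sq_acc + diff[j] * diff[j])
        scaled = np.float32(model.gamma_eff * sq_acc)
        kern = np.minimum(cordic_exp(-scaled), np.float32(1.0))
        mac = np.float32(mac + alpha * kern)
    score = np.float32(mac + (-model.b))
    return Decision.from_score(score)


# ---------------------------------------------------------------------------
# Bundle serialization
# ---------------------------------------------------------------------------

def save_svm_bundle(model: SVMModel, path: str | Path) -> None:
    payload = {
        "format": "epihybrid-svm-bundle",
        "version": 1,
        "support_vectors": model.support_vectors.astype(np.float64).tolist(),
        "alphas": model.alphas.astype(np.float64).tolist(),
        "b": float(model.b),
        "sigma": float(model.sigma),
        "s_max": float(model.s_max),
        "s_min": float(model.s_min),
        "f_max": float(model.f_max),
        "f_min": float(model.f_min),
        "gamma_eff": float(model.gamma_eff),
        "log_transform": bool(model.log_transform),
        "epsilon_floor": model.epsilon_floor,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_svm_bundle(path: str | Path) -> SVMModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise BundleError(f"{path}: not valid JSON: {exc}") from exc
    if payload.get("format") != "epihybrid-svm-bundle":
        raise BundleError(f"{path}: not an SVM bundle")
    try:
        return SVMModel(
            support_vectors=np.asarray(payload["support_vectors"], dtype=np.float32),
            alphas=np.asarray(payload["alphas"], dtype=np.float32),
            b=payload["b"],
            sigma=payload["sigma"],
            s_max=payload["s_max"],
            s_min=payload["s_min"],
            f_max=payload["f_max"],
            f_min=payload["f_min"],
            gamma_eff=payload["gamma_eff"],
            log_transform=payload.get("log_transform", False),
            epsilon_floor=payload.get("epsilon_floor"),
        )
    except (KeyError, ConfigError) as exc:
        raise BundleError(f"{path}: malformed SVM bundle: {exc}") from exc
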