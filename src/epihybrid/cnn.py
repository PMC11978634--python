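"""Configurable convolution + two-stage max-pooling feature extractor.

The stack is the fixed three-layer pipeline of the detection circuit:
valid cross-correlation with stride 1 and a single feature map per layer
(5x5 -> 3x3 -> 1x1 kernels), each convolution followed by non-overlapping
2x2 max pooling with stride 2 (odd trailing rows/columns dropped). Applied
to a 20x256 input the shapes run

    20x256 -conv5-> 16x252 -pool-> 8x126 -conv3-> 6x124 -pool-> 3x62
           -conv1-> 3x62  -pool-> 1x31

and the final map flattens row-major into the length-31 feature vector the
SVM consumes.

Two convolution paths are provided. ``conv2d_direct`` is the reference:
float32 arithmetic with a fixed summation order (bias first, then within
each kernel row left to right, rows combined top to bottom).
``conv2d_pipelined`` emulates the hardware dataflow -- K parallel row
units, each a chain of K multiply-add-register processing elements fed one
input column per cycle -- and is bit-identical to the direct path because
both realise the same fp32 operation order. Cycle counts follow the
documented fill + one-result-per-cycle model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import BundleError, ConfigError, ShapeError

__all__ = [
    "ConvLayerSpec",
    "CNNModel",
    "FeatureVector",
    "CycleReport",
    "conv2d_direct",
    "conv2d_pipelined",
    "maxpool_two_stage",
    "conv_cycles",
    "pool_cycles",
    "extract_features",
    "save_cnn_bundle",
    "load_cnn_bundle",
]

FEATURE_LENGTH = 31
VALID_KERNEL_SIZES = (1, 3, 5)

#: Cycles per support vector in the SVM stage of the latency model:
#: 3 sequential DPU ops (subtract, square, accumulate) per feature element,
#: 18 CORDIC micro-iterations for the exponential, 2 multiply-accumulate
#: cycles for the alpha weighting.
SVM_CYCLES_PER_SV = 3 * FEATURE_LENGTH + 18 + 2


@dataclass(frozen=True)
class ConvLayerSpec:
    """One convolution layer: K x K float32 weights, scalar bias, activation."""

    weights: np.ndarray
    bias: float = 0.0
    activation: str = "relu"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float32)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConfigError(f"weights must be square, got shape {w.shape}")
        if w.shape[0] not in VALID_KERNEL_SIZES:
            raise ConfigError(
                f"kernel_size must be one of {VALID_KERNEL_SIZES}, got {w.shape[0]}"
            )
        if not np.all(np.isfinite(w)):
            raise ConfigError("weights must be finite")
        if self.activation not in ("relu", "none"):
            raise ConfigError(f"activation must be 'relu' or 'none', got {self.activation!r}")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "bias", np.float32(self.bias))

    @property
    def kernel_size(self) -> int:
        return int(self.weights.shape[0])


@dataclass(frozen=True)
class CNNModel:
    """The ordered 5x5, 3x3, 1x1 convolution stack with 2x2/stride-2 pooling."""

    layers: tuple[ConvLayerSpec, ConvLayerSpec, ConvLayerSpec]
    pool_window: int = 2
    pool_stride: int = 2

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        if len(layers) != 3:
            raise ConfigError(f"CNNModel requires exactly 3 layers, got {len(layers)}")
        sizes = tuple(l.kernel_size for l in layers)
        if sizes != (5, 3, 1):
            raise ConfigError(f"layer kernel sizes must be (5, 3, 1), got {sizes}")
        if (self.pool_window, self.pool_stride) != (2, 2):
            raise ConfigError("pooling is fixed at 2x2 windows with stride 2")
        object.__setattr__(self, "layers", layers)


@dataclass(frozen=True)
class FeatureVector:
    """Length-31 float32 feature vector produced by the CNN stack."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float32)
        if v.shape != (FEATURE_LENGTH,):
            raise ShapeError(f"feature vector must have length {FEATURE_LENGTH}, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ShapeError("feature vector must be finite")
        object.__setattr__(self, "values", v)


_STAGE_ORDER = ("conv1", "pool1", "conv2", "pool2", "conv3", "pool3", "svm")


@dataclass
class CycleReport:
    """Per-stage cycle counts convertible to latency at a configured clock."""

    stage_cycles: dict[str, int] = field(default_factory=dict)
    clock_hz: float = 1e7

    def __post_init__(self) -> None:
        if not self.clock_hz > 0:
            raise ConfigError("clock_hz must be positive")
        for name, c in self.stage_cycles.items():
            if int(c) != c or c <= 0:
                raise ConfigError(f"stage {name!r}: cycle count must be a positive integer")

    @property
    def total_cycles(self) -> int:
        return int(sum(self.stage_cycles.values()))

    @property
    def latency_s(self) -> float:
        return self.total_cycles / self.clock_hz

    def ordered_stages(self) -> list[tuple[str, int]]:
        known = [(s, self.stage_cycles[s]) for s in _STAGE_ORDER if s in self.stage_cycles]
        extra = [(s, c) for s, c in self.stage_cycles.items() if s not in _STAGE_ORDER]
        return known + extra


def _check_conv_input(x: np.ndarray, k: int) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float32)
    if arr.ndim != 2:
        raise ShapeError(f"convolution input must be 2-D, got {arr.ndim}-D")
    h, w = arr.shape
    if h < k or w < k:
        raise ShapeError(f"input {h}x{w} smaller than {k}x{k} kernel")
    return arr


def conv2d_direct(x: np.ndarray, layer: ConvLayerSpec) -> np.ndarray:
    """Valid stride-1 cross-correlation + bias (+ ReLU), float32 reference.

    Summation order is fixed to match the hardware: the bias joins the very
    first product, each kernel row accumulates left to right, and row
    partial sums combine top to bottom.
    """
    k = layer.kernel_size
    arr = _check_conv_input(x, k)
    h, w = arr.shape
    ho, wo = h - k + 1, w - k + 1
    wts = layer.weights
    out: np.ndarray | None = None
    for r in range(k):
        row_acc = arr[r : r + ho, 0:wo] * wts[r, 0]
        if r == 0:
            row_acc = row_acc + layer.bias
        for c in range(1, k):
            row_acc = row_acc + arr[r : r + ho, c : c + wo] * wts[r, c]
        out = row_acc if out is None else out + row_acc
    assert out is not None
    if layer.activation == "relu":
        out = np.maximum(out, np.float32(0.0))
    return out.astype(np.float32)


def conv2d_pipelined(x: np.ndarray, layer: ConvLayerSpec) -> tuple[np.ndarray, int]:
    """Hardware-dataflow convolution: K row units of K chained PEs.

    Each row unit streams one input row per output row, one column per
    cycle; PE ``c`` multiplies the incoming sample by its weight and adds
    the previous PE's registered partial sum, so a window's row partial
    completes after K cycles. Row partials are then summed across units
    top to bottom. Returns the output map and the stage cycle count
    (K fill cycles + one completed result per cycle thereafter).
    """
    k = layer.kernel_size
    arr = _check_conv_input(x, k)
    h, w = arr.shape
    ho, wo = h - k + 1, w - k + 1
    wts = layer.weights

    row_partials = np.empty((k, ho, wo), dtype=np.float32)
    for r in range(k):
        stream = arr[r : r + ho, :]  # this unit's input rows, all output rows at once
        regs = np.zeros((k, ho), dtype=np.float32)
        for j in range(w):  # one input column per clock cycle
            col = stream[:, j]
            new = np.empty_like(regs)
            first = col * wts[r, 0]
            if r == 0:
                first = first + layer.bias
            new[0] = first
            for c in range(1, k):
                new[c] = regs[c - 1] + col * wts[r, c]
            regs = new
            if j >= k - 1:
                row_partials[r, :, j - k + 1] = regs[k - 1]

    out = row_partials[0]
    for r in range(1, k):
        out = out + row_partials[r]
    if layer.activation == "relu":
        out = np.maximum(out, np.float32(0.0))
    return out.astype(np.float32), conv_cycles(k, ho, wo)


def conv_cycles(k: int, h_out: int, w_out: int) -> int:
    """Cycle model for a KxK layer: K-cycle pipeline fill, then one output
    per cycle."""
    return k + h_out * w_out


def pool_cycles(h_out: int, w_out: int) -> int:
    """Cycle model for two-stage pooling: the half-rate second comparison
    stage costs each window two base-clock cycles."""
    return 2 * h_out * w_out


def maxpool_two_stage(x: np.ndarray) -> np.ndarray:
    """Non-overlapping 2x2 max pooling via the two-stage comparator scheme.

    Stage 1 compares (Data0, Data1) and (Data2, Data3) in each window;
    stage 2 compares the two winners. Trailing odd rows/columns are
    dropped (floor semantics).
    """
    arr = np.asarray(x, dtype=np.float32)
    if arr.ndim != 2 or arr.size == 0:
        raise ShapeError(f"pooling input must be a non-empty 2-D matrix, got shape {arr.shape}")
    h, w = arr.shape
    h2, w2 = h // 2, w // 2
    arr = arr[: 2 * h2, : 2 * w2]
    d0 = arr[0::2, 0::2]
    d1 = arr[0::2, 1::2]
    d2 = arr[1::2, 0::2]
    d3 = arr[1::2, 1::2]
    stage1_a = np.maximum(d0, d1)
    stage1_b = np.maximum(d2, d3)
    return np.maximum(stage1_a, stage1_b)


def extract_features(
    x: np.ndarray,
    model: CNNModel,
    use_pipelined: bool = False,
) -> tuple[FeatureVector, CycleReport]:
    """Run the full conv/pool stack on a 20x256 map; returns the length-31
    feature vector and the per-stage cycle counts."""
    arr = np.asarray(x, dtype=np.float32)
    if arr.shape != (20, 256):
        raise ShapeError(f"extract_features expects a 20x256 input, got {arr.shape}")
    stage_cycles: dict[str, int] = {}
    cur = arr
    for idx, layer in enumerate(model.layers, start=1):
        if use_pipelined:
            cur, cycles = conv2d_pipelined(cur, layer)
        else:
            cur = conv2d_direct(cur, layer)
            k = layer.kernel_size
            cycles = conv_cycles(k, cur.shape[0], cur.shape[1])
        stage_cycles[f"conv{idx}"] = cycles
        cur = maxpool_two_stage(cur)
        stage_cycles[f"pool{idx}"] = pool_cycles(cur.shape[0], cur.shape[1])
    if cur.shape != (1, FEATURE_LENGTH):
        raise ShapeError(f"final map is {cur.shape}, expected (1, {FEATURE_LENGTH})")
    return FeatureVector(values=cur.reshape(-1)), CycleReport(stage_cycles=stage_cycles)


# ---------------------------------------------------------------------------
# Bundle serialization
# ---------------------------------------------------------------------------

def save_cnn_bundle(model: CNNModel, path: str | Path) -> None:
    """Write the kernel/bias bundle as JSON (float32 values survive the
    double round-trip exactly)."""
    payload = {
        "format": "epihybrid-cnn-bundle",
        "version": 1,
        "layers": [
            {
                "kernel_size": layer.kernel_size,
                "weights": layer.weights.astype(np.float64).tolist(),
                "bias": float(layer.bias),
                "activation": layer.activation,
            }
            for layer in model.layers
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_cnn_bundle(path: str | Path) -> CNNModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise BundleError(f"{path}: not valid JSON: {exc}") from exc
    if payload.get("format") != "epihybrid-cnn-bundle":
        raise BundleError(f"{path}: not a CNN bundle")
    try:
        layers = tuple(
            ConvLayerSpec(
                weights=np.asarray(spec["weights"], dtype=np.float32),
                bias=spec["bias"],
                activation=spec.get("activation", "relu"),
            )
            for spec in payload["layers"]
        )
        return CNNModel(layers=layers)  # type: ignore[arg-type]
    except (KeyError, ConfigError) as exc:
        raise BundleError(f"{path}: malformed CNN bundle: {exc}") from exc
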