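"""End-to-end detection pipeline: FFT front-end -> CNN -> SVM -> metrics,
with per-stage cycle accounting and latency reporting at a configured
clock (10 MHz by default, the operating frequency of the target circuit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cnn import (
    CNNModel,
    CycleReport,
    SVM_CYCLES_PER_SV,
    extract_features,
)
from .errors import ConfigError
from .fft import amplitude_spectrum
from .frames import EEGFrame
from .metrics import ConfusionCounts, accumulate, metrics_report
from .svm import Decision, SVMModel, decision_function, dpu_dataflow_eval

__all__ = [
    "PipelineConfig",
    "run_detection",
    "run_evaluation",
    "svm_stage_cycles",
    "latency_report",
]


@dataclass
class PipelineConfig:
    """Run-time configuration of the detection chain."""

    use_fft_frontend: bool = True
    clock_hz: float = 1e7
    svm_eval_path: str = "direct"  # or "dpu"
    use_pipelined_conv: bool = False
    seed: int = 0
    cnn_bundle: str | None = None
    svm_bundle: str | None = None
    input_source: str = "synthetic"  # synthetic | delimited | edf
    output_dir: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        try:
            # YAML 1.1 parses exponent forms without a sign ("2.0e7") as str
            self.clock_hz = float(self.clock_hz)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"clock_hz must be numeric, got {self.clock_hz!r}") from exc
        if not self.clock_hz > 0:
            raise ConfigError("clock_hz must be positive")
        if self.svm_eval_path not in ("direct", "dpu"):
            raise ConfigError("svm_eval_path must be 'direct' or 'dpu'")
        if self.input_source not in ("synthetic", "delimited", "edf"):
            raise ConfigError("input_source must be synthetic, delimited or edf")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(extra=extra, **kwargs)


def svm_stage_cycles(n_support: int) -> int:
    """SVM-stage cycle model: 113 cycles per support vector (3 DPU ops per
    feature element + 18 CORDIC micro-iterations + 2 MAC) plus the final
    offset addition."""
    if n_support < 1:
        raise ConfigError("n_support must be >= 1")
    return n_support * SVM_CYCLES_PER_SV + 1


def run_detection(
    frame: EEGFrame,
    cnn_model: CNNModel,
    svm_model: SVMModel,
    cfg: PipelineConfig | None = None,
) -> tuple[Decision, CycleReport]:
    """Classify one frame and account the cycles of every stage."""
    cfg = cfg or PipelineConfig()
    if cfg.use_fft_frontend:
        stage_input = amplitude_spectrum(frame).amplitude
    else:
        stage_input = frame.data
    features, report = extract_features(
        stage_input, cnn_model, use_pipelined=cfg.use_pipelined_conv
    )
    if cfg.svm_eval_path == "dpu":
        decision = dpu_dataflow_eval(features, svm_model)
    else:
        decision = decision_function(features, svm_model)
    stages = dict(report.stage_cycles)
    stages["svm"] = svm_stage_cycles(svm_model.n_support)
    return decision, CycleReport(stage_cycles=stages, clock_hz=cfg.clock_hz)


def run_evaluation(
    frames,
    cnn_model: CNNModel,
    svm_model: SVMModel,
    cfg: PipelineConfig | None = None,
) -> tuple[ConfusionCounts, dict]:
    """Classify labeled frames, accumulate confusion counts, and build the
    metrics report."""
    frames = list(frames)
    if not frames:
        raise ConfigError("run_evaluation requires at least one frame")
    pairs = []
    for frame in frames:
        if frame.label is None:
            raise ConfigError(f"frame {frame.frame_id!r} is unlabeled")
        decision, _ = run_detection(frame, cnn_model, svm_model, cfg)
        pairs.append((decision, frame.label))
    counts = accumulate(pairs)
    report = metrics_report(counts)
    if cfg is not None and cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(json.dumps(report, indent=1))
    return counts, report


def latency_report(report: CycleReport) -> str:
    """Per-stage cycles and milliseconds at the configured clock, with a
    monotone cumulative column; the SVM stage is listed last."""
    ms_per_cycle = 1e3 / report.clock_hz
    lines = [
        f"clock: {report.clock_hz / 1e6:g} MHz",
        f"{'stage':<8}{'cycles':>10}{'ms':>12}{'cumulative ms':>16}",
    ]
    cum = 0
    for name, cycles in report.ordered_stages():
        cum += cycles
        lines.append(
            f"{name:<8}{cycles:>10d}{cycles * ms_per_cycle:>12.4f}{cum * ms_per_cycle:>16.4f}"
        )
    lines.append(
        f"{'total':<8}{report.total_cycles:>10d}{report.total_cycles * ms_per_cycle:>12.4f}"
        f"{report.total_cycles * ms_per_cycle:>16.4f}"
    )
    return "\n".join(lines)
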