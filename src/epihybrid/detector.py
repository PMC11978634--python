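"""Model/Results front door for the hybrid detector.

``SeizureDetector`` holds labeled frames plus a training configuration;
``fit()`` runs the full training pipeline (CNN with temporary head, SMO
for the SVM) and returns a ``SeizureDetectorResults`` carrying the fitted
bundles, the held-out confusion counts, the evaluation statistics and a
``summary()`` table, with ``predict`` and latency reporting attached.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .cnn import CycleReport, save_cnn_bundle
from .frames import EEGFrame, SynthConfig, generate_frames
from .metrics import accuracy, sensitivity, specificity
from .pipeline import PipelineConfig, latency_report, run_detection
from .svm import save_svm_bundle
from .train import PipelineTrainResult, TrainConfig, train_pipeline

__all__ = ["SeizureDetector", "SeizureDetectorResults"]


class SeizureDetector:
    """Hybrid CNN-SVM seizure detector fitted to labeled EEG frames.

    Parameters
    ----------
    frames
        Labeled :class:`EEGFrame` sequence (ictal = 1, interictal = 0).
    config
        :class:`TrainConfig`; defaults used when omitted.
    use_fft_frontend
        Feed the CNN amplitude spectra (default) rather than raw voltage.
    """

    def __init__(
        self,
        frames: Sequence[EEGFrame],
        config: TrainConfig | None = None,
        use_fft_frontend: bool = True,
    ):
        self.frames = list(frames)
        self.config = config or TrainConfig()
        self.use_fft_frontend = use_fft_frontend

    @classmethod
    def from_synthetic(
        cls,
        synth_config: SynthConfig | None = None,
        config: TrainConfig | None = None,
        use_fft_frontend: bool = True,
    ) -> "SeizureDetector":
        """Build a detector over freshly generated synthetic frames."""
        synth_config = synth_config or SynthConfig()
        return cls(generate_frames(synth_config), config, use_fft_frontend)

    def fit(self) -> "SeizureDetectorResults":
        result = train_pipeline(self.frames, self.config, self.use_fft_frontend)
        return SeizureDetectorResults(self, result)


class SeizureDetectorResults:
    """Fitted detector: trained bundles, held-out evaluation, diagnostics."""

    def __init__(self, model: SeizureDetector, result: PipelineTrainResult):
        self.model = model
        self.cnn_model = result.cnn_model
        self.svm_model = result.svm_model
        self.counts = result.counts
        self.history = result.history
        self.train_indices = result.train_indices
        self.test_indices = result.test_indices

    # -- evaluation statistics on the held-out split ------------------------
    @property
    def sensitivity(self) -> float:
        return sensitivity(self.counts)

    @property
    def specificity(self) -> float:
        return specificity(self.counts)

    @property
    def accuracy(self) -> float:
        return accuracy(self.counts)

    def predict(self, frames: Sequence[EEGFrame], cfg: PipelineConfig | None = None):
        """Per-frame decisions through the float32 inference chain."""
        cfg = cfg or PipelineConfig(use_fft_frontend=self.model.use_fft_frontend)
        return [
            run_detection(f, self.cnn_model, self.svm_model, cfg)[0] for f in frames
        ]

    def cycle_report(self, clock_hz: float = 1e7) -> CycleReport:
        """Cycle/latency model of one detection with the fitted bundles."""
        cfg = PipelineConfig(
            use_fft_frontend=self.model.use_fft_frontend, clock_hz=clock_hz
        )
        _, report = run_detection(self.model.frames[0], self.cnn_model, self.svm_model, cfg)
        return report

    def save_bundles(self, directory: str | Path) -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cnn_path = directory / "cnn_bundle.json"
        svm_path = directory / "svm_bundle.json"
        save_cnn_bundle(self.cnn_model, cnn_path)
        save_svm_bundle(self.svm_model, svm_path)
        return cnn_path, svm_path

    def summary(self) -> str:
        """Plain-text summary: data sizes, model sizes, held-out metrics,
        and the latency model."""
        c = self.counts
        n_train, n_test = len(self.train_indices), len(self.test_indices)
        lines = [
            "Hybrid CNN-SVM seizure detector",
            "=" * 46,
            f"frames: {len(self.model.frames)} (train {n_train} / held-out {n_test})",
            f"FFT front-end: {'on' if self.model.use_fft_frontend else 'off'}",
            f"temporary-head training accuracy: {self.history.head_accuracy:.3f}",
            f"support vectors: {self.svm_model.n_support}",
            f"kernel scale sigma: {self.svm_model.sigma:.6g}"
            f"  (gamma_eff = {float(self.svm_model.gamma_eff):.6g})",
            "-" * 46,
            "held-out confusion counts (ictal positive):",
            f"  TP={c.TP}  FN={c.FN}  FP={c.FP}  TN={c.TN}",
            f"sensitivity: {self.sensitivity:5.1f} %",
            f"specificity: {self.specificity:5.1f} %",
            f"accuracy:    {self.accuracy:5.1f} %",
            "-" * 46,
            latency_report(self.cycle_report()),
        ]
        return "\n".join(lines)
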