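"""EEG frame container, synthetic frame generation, and recording I/O.

The detector operates on fixed-geometry windows: 20 channels x 256 samples
of single-precision voltage, nominally one second of scalp EEG at 256 Hz.
Synthetic frames emulate the two classes the classifier discriminates:

* interictal (between seizures): band-limited rhythmic background, a sum of
  low-frequency sinusoids (default 2-12 Hz) plus white Gaussian noise;
* ictal (during a seizure): the same background attenuated at low
  frequencies, boosted high-frequency (16-64 Hz) rhythmic components, and
  Poisson-placed biphasic spike-and-wave transients -- the classic
  electrographic signature of an electrographic seizure.

All generated data are stored as float32 so every downstream stage sees the
same bit patterns the single-precision hardware datapath would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, ParseError, ShapeError

__all__ = [
    "N_CHANNELS",
    "N_SAMPLES",
    "EEGFrame",
    "SynthConfig",
    "generate_frames",
    "read_delimited",
    "write_delimited",
    "segment_recording",
    "read_edf",
    "save_frame_set",
    "load_frame_set",
]

logger = logging.getLogger(__name__)

N_CHANNELS = 20
N_SAMPLES = 256

#: Low-band attenuation applied to the rhythmic background of ictal frames
#: (seizures suppress the normal posterior rhythm while fast activity builds).
ICTAL_LOW_BAND_ATTENUATION = 0.5

#: Frequency band (Hz) of the boosted ictal fast activity.
ICTAL_HIGH_BAND_HZ = (16.0, 64.0)


@dataclass(frozen=True)
class EEGFrame:
    """One 20 x 256 single-precision EEG window.

    Parameters
    ----------
    data
        Array of shape (20, 256), float32, finite.
    label
        ``1`` for ictal, ``0`` for interictal, ``None`` if unlabeled.
    sample_rate_hz
        Sampling rate of the window; 256 Hz by default.
    frame_id
        Optional identifier used by manifests and spectral frames.
    """

    data: np.ndarray
    label: int | None = None
    sample_rate_hz: float = 256.0
    frame_id: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.shape != (N_CHANNELS, N_SAMPLES):
            raise ShapeError(
                f"EEGFrame data must be {N_CHANNELS}x{N_SAMPLES}, got {arr.shape}"
            )
        if arr.dtype != np.float32:
            arr = arr.astype(np.float32)
        if not np.all(np.isfinite(arr)):
            raise ShapeError("EEGFrame data must be finite")
        if self.label not in (None, 0, 1):
            raise ConfigError(f"label must be 0, 1 or None, got {self.label!r}")
        if not self.sample_rate_hz > 0:
            raise ConfigError("sample_rate_hz must be positive")
        object.__setattr__(self, "data", arr)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic EEG generator.

    The defaults encode the qualitative ictal/interictal contrast the
    classifier is built to exploit: ictal frames gain fast (16-64 Hz)
    rhythmic power and spike-wave transients while their slow background is
    attenuated.
    """

    seed: int = 0
    n_frames: int = 100
    ictal_fraction: float = 0.5
    background_band_hz: tuple[float, float] = (2.0, 12.0)
    spike_rate_per_s: float = 3.0
    high_freq_gain: float = 3.0
    noise_sd: float = 0.5
    sample_rate_hz: float = 256.0
    n_background_components: int = 5
    n_fast_components: int = 3

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed: must be an integer")
        if not isinstance(self.n_frames, (int, np.integer)) or self.n_frames < 0:
            raise ConfigError("n_frames: must be a nonnegative integer")
        if not 0.0 <= self.ictal_fraction <= 1.0:
            raise ConfigError("ictal_fraction: must lie in [0, 1]")
        lo, hi = self.background_band_hz
        if not (0 < lo < hi):
            raise ConfigError("background_band_hz: need 0 < low < high")
        if self.spike_rate_per_s < 0:
            raise ConfigError("spike_rate_per_s: must be nonnegative")
        if not self.high_freq_gain > 0:
            raise ConfigError("high_freq_gain: must be positive")
        if not self.noise_sd > 0:
            raise ConfigError("noise_sd: must be positive")
        if not self.sample_rate_hz > 0:
            raise ConfigError("sample_rate_hz: must be positive")


def _spike_wave_template(fs: float, amp: float) -> np.ndarray:
    """Biphasic spike-and-wave transient: a sharp ~30 ms spike followed by a
    slower opposite-polarity wave, the canonical epileptiform discharge."""
    n = int(round(0.25 * fs))  # 250 ms footprint
    t = np.arange(n) / fs
    spike = amp * np.exp(-((t - 0.03) / 0.008) ** 2)
    wave = -0.6 * amp * np.exp(-((t - 0.12) / 0.045) ** 2)
    return spike + wave


def _synth_channel(rng: np.random.Generator, cfg: SynthConfig, ictal: bool) -> np.ndarray:
    fs = cfg.sample_rate_hz
    t = np.arange(N_SAMPLES) / fs
    lo, hi = cfg.background_band_hz

    sig = np.zeros(N_SAMPLES, dtype=np.float64)
    for _ in range(cfg.n_background_components):
        f = rng.uniform(lo, hi)
        a = rng.uniform(0.5, 1.5)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        sig += a * np.sin(2.0 * np.pi * f * t + phase)

    if ictal:
        sig *= ICTAL_LOW_BAND_ATTENUATION
        f_lo, f_hi = ICTAL_HIGH_BAND_HZ
        for _ in range(cfg.n_fast_components):
            f = rng.uniform(f_lo, f_hi)
            a = cfg.high_freq_gain * rng.uniform(0.3, 0.6)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            sig += a * np.sin(2.0 * np.pi * f * t + phase)
        n_spikes = rng.poisson(cfg.spike_rate_per_s * N_SAMPLES / fs)
        for _ in range(n_spikes):
            start = rng.integers(0, N_SAMPLES)
            amp = rng.uniform(2.0, 4.0)
            tpl = _spike_wave_template(fs, amp)
            stop = min(N_SAMPLES, start + tpl.size)
            sig[start:stop] += tpl[: stop - start]

    sig += rng.normal(0.0, cfg.noise_sd, size=N_SAMPLES)
    return sig.astype(np.float32)


def generate_frames(cfg: SynthConfig) -> list[EEGFrame]:
    """Generate ``cfg.n_frames`` labeled synthetic frames.

    Deterministic under ``cfg.seed``: the same config reproduces the same
    frame set bit for bit. The number of ictal frames is
    ``round(n_frames * ictal_fraction)``; ictal/interictal positions are
    shuffled by the same seeded generator.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(cfg.n_frames)
    if n == 0:
        return []
    n_ictal = int(np.floor(n * cfg.ictal_fraction + 0.5))
    labels = np.zeros(n, dtype=np.int64)
    labels[:n_ictal] = 1
    labels = rng.permutation(labels)

    frames: list[EEGFrame] = []
    for k in range(n):
        data = np.stack(
            [_synth_channel(rng, cfg, bool(labels[k])) for _ in range(N_CHANNELS)]
        )
        frames.append(
            EEGFrame(
                data=data,
                label=int(labels[k]),
                sample_rate_hz=cfg.sample_rate_hz,
                frame_id=f"synth-{cfg.seed}-{k:05d}",
            )
        )
    return frames


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def read_delimited(path: str | Path) -> EEGFrame:
    """Read a 20x256 numeric matrix from comma- or whitespace-delimited text.

    Raises
    ------
    ShapeError
        If the parsed matrix is not 20x256 (message reports observed dims).
    ParseError
        If a cell is not numeric (message reports 1-based row/column).
    """
    path = Path(path)
    rows: list[list[float]] = []
    with path.open("r") as fh:
        for r, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            cells = line.replace(",", " ").split()
            row = []
            for c, cell in enumerate(cells):
                try:
                    row.append(float(cell))
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: non-numeric cell at row {r + 1}, column {c + 1}: {cell!r}"
                    ) from exc
            rows.append(row)
    n_rows = len(rows)
    n_cols = len(rows[0]) if rows else 0
    if n_rows != N_CHANNELS or any(len(r) != N_SAMPLES for r in rows):
        bad_cols = {len(r) for r in rows} or {0}
        raise ShapeError(
            f"{path}: expected {N_CHANNELS}x{N_SAMPLES} matrix, "
            f"got {n_rows} rows with column counts {sorted(bad_cols)}"
        )
    data = np.asarray(rows, dtype=np.float32)
    return EEGFrame(data=data, frame_id=path.stem)


def write_delimited(frame: EEGFrame, path: str | Path) -> None:
    """Write a frame as whitespace-delimited text; float32 round-trip safe
    (9 significant digits)."""
    np.savetxt(Path(path), frame.data, fmt="%.9e")


# ---------------------------------------------------------------------------
# Recording segmentation
# ---------------------------------------------------------------------------

def segment_recording(
    samples: np.ndarray | Sequence[Sequence[float]],
    sample_rate_hz: float,
    window_s: float = 1.0,
) -> list[EEGFrame]:
    """Cut a multi-channel recording into consecutive 20x256 frames.

    ``samples`` is channels x time. Each window spans ``window_s`` seconds
    per channel; the channels x window block must hold exactly
    20*256 = 5120 samples and is reshaped row-major into the 20x256 frame
    geometry (identity when the recording already has 20 channels and the
    window is 256 samples). The trailing partial window is discarded; a
    recording shorter than one window yields an empty list with a warning.
    """
    arr = np.asarray(samples, dtype=np.float32)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ShapeError(f"samples must be channels x time, got shape {arr.shape}")
    n_ch, n_t = arr.shape
    win = int(round(window_s * sample_rate_hz))
    if win < 1:
        raise ConfigError("window_s: window must span at least one sample")
    if n_ch * win != N_CHANNELS * N_SAMPLES:
        raise ShapeError(
            f"{n_ch} channels x {win} samples per window = {n_ch * win} values; "
            f"frames require exactly {N_CHANNELS * N_SAMPLES}"
        )
    n_win = n_t // win
    if n_win == 0:
        logger.warning(
            "recording of %d samples is shorter than one window (%d); no frames",
            n_t,
            win,
        )
        return []
    frames = []
    for k in range(n_win):
        block = arr[:, k * win : (k + 1) * win]
        frames.append(
            EEGFrame(
                data=block.reshape(N_CHANNELS, N_SAMPLES),
                sample_rate_hz=sample_rate_hz,
                frame_id=f"seg-{k:05d}",
            )
        )
    return frames


def read_edf(path: str | Path, window_s: float = 1.0) -> list[EEGFrame]:
    """Read an EDF/EDF+ recording (as used by CHB-MIT) and segment it.

    Requires the optional ``mne`` dependency. Channels beyond the first 20
    are dropped; fewer than 20 channels raises a ShapeError unless the
    channel x window product still reshapes to 20x256.
    """
    try:
        import mne  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF ingestion requires the optional 'mne' dependency "
            "(pip install epihybrid[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().astype(np.float32)
    if data.shape[0] > N_CHANNELS:
        data = data[:N_CHANNELS]
    return segment_recording(data, raw.info["sfreq"], window_s=window_s)


# ---------------------------------------------------------------------------
# Frame-set serialization (one delimited file per frame + manifest)
# ---------------------------------------------------------------------------

def save_frame_set(frames: Iterable[EEGFrame], directory: str | Path, seed: int | None = None) -> Path:
    """Write frames as one text matrix each plus a TSV manifest
    (columns: frame_id, label, file, seed). Returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.tsv"
    with manifest.open("w") as fh:
        fh.write("frame_id\tlabel\tfile\tseed\n")
        for k, frame in enumerate(frames):
            fid = frame.frame_id or f"frame-{k:05d}"
            fname = f"{fid}.txt"
            write_delimited(frame, directory / fname)
            label = "" if frame.label is None else str(frame.label)
            fh.write(f"{fid}\t{label}\t{fname}\t{'' if seed is None else seed}\n")
    return manifest


def load_frame_set(manifest: str | Path) -> list[EEGFrame]:
    """Load a frame set written by :func:`save_frame_set`."""
    manifest = Path(manifest)
    directory = manifest.parent
    frames = []
    with manifest.open("r") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            frame = read_delimited(directory / parts[idx["file"]])
            label_s = parts[idx["label"]]
            frames.append(
                replace(
                    frame,
                    label=int(label_s) if label_s else None,
                    frame_id=parts[idx["frame_id"]],
                )
            )
    return frames
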