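"""256-point radix-2 decimation-in-time FFT front-end in single precision.

The feature extractor mirrors the hardware organisation: a bit-reversal
address permutation, a precomputed table of 128 twiddle factors W_256^m,
and eight butterfly stages whose arithmetic is carried entirely in
complex64 so rounding matches a single-precision datapath. The amplitude
spectrum (per-bin modulus) of each of the 20 channels is what the CNN
consumes; the two-sided 256-bin spectrum is kept so the CNN input stays
20 x 256.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ShapeError
from .frames import EEGFrame, N_CHANNELS, N_SAMPLES

__all__ = [
    "SpectralFrame",
    "bit_reverse_permutation",
    "twiddle_table",
    "fft256",
    "amplitude_spectrum",
]


@dataclass(frozen=True)
class SpectralFrame:
    """Amplitude spectrum of an :class:`EEGFrame`, same 20 x 256 geometry."""

    amplitude: np.ndarray
    source_frame_id: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.amplitude)
        if arr.shape != (N_CHANNELS, N_SAMPLES):
            raise ShapeError(
                f"SpectralFrame must be {N_CHANNELS}x{N_SAMPLES}, got {arr.shape}"
            )
        if arr.dtype != np.float32:
            arr = arr.astype(np.float32)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ShapeError("amplitudes must be finite and nonnegative")
        object.__setattr__(self, "amplitude", arr)


def bit_reverse_permutation(n: int) -> np.ndarray:
    """Self-inverse permutation of 0..n-1 reversing log2(n)-bit indices.

    This is the address reordering the hardware's address generator applies
    so that the in-place butterfly stages read contiguous operand pairs.
    """
    if n < 1 or (n & (n - 1)) != 0:
        raise ConfigError(f"n must be a power of two, got {n}")
    bits = n.bit_length() - 1
    idx = np.arange(n)
    rev = np.zeros(n, dtype=np.int64)
    for b in range(bits):
        rev |= ((idx >> b) & 1) << (bits - 1 - b)
    return rev


def twiddle_table(n: int = N_SAMPLES) -> np.ndarray:
    """The n/2 twiddle factors W_n^m = exp(-2*pi*i*m/n), m = 0..n/2-1.

    Computed in double precision and rounded once to complex64, emulating a
    ROM of single-precision constants.
    """
    if n < 2 or (n & (n - 1)) != 0:
        raise ConfigError(f"n must be a power of two >= 2, got {n}")
    m = np.arange(n // 2)
    return np.exp(-2j * np.pi * m / n).astype(np.complex64)


def fft256(row: np.ndarray, twiddle: np.ndarray | None = None) -> np.ndarray:
    """Radix-2 DIT FFT of one (or a batch of) real length-256 rows.

    Accepts shape ``(..., 256)``; all butterfly arithmetic is complex64.
    Returns complex64 of the same shape.
    """
    arr = np.asarray(row)
    n = N_SAMPLES
    if arr.shape[-1] != n:
        raise ShapeError(f"fft256 requires length-{n} rows, got {arr.shape[-1]}")
    if twiddle is None:
        twiddle = twiddle_table(n)
    if twiddle.shape != (n // 2,):
        raise ConfigError(f"twiddle table must have {n // 2} entries")

    a = arr.astype(np.float32)[..., bit_reverse_permutation(n)].astype(np.complex64)
    stages = n.bit_length() - 1  # 8 butterfly stages for n = 256
    for s in range(1, stages + 1):
        m = 1 << s
        half = m >> 1
        # W_n^{k * n/m} for k = 0..half-1: stride through the base table.
        w = twiddle[:: n // m][:half]
        a = a.reshape(*a.shape[:-1], n // m, m)
        top = a[..., :half]
        t = (w * a[..., half:]).astype(np.complex64)
        a = np.concatenate([top + t, top - t], axis=-1)
        a = a.reshape(*a.shape[:-2], n)
    return a


def amplitude_spectrum(frame: EEGFrame) -> SpectralFrame:
    """Per-channel FFT modulus of a frame; output keeps the 20x256 geometry."""
    spec = fft256(frame.data)
    return SpectralFrame(amplitude=np.abs(spec), source_frame_id=frame.frame_id)
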