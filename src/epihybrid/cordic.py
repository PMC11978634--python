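"""Hyperbolic CORDIC evaluation of exp and ln in single precision.

The SVM kernel needs exponentials (and optionally logarithms for feature
normalisation). Both are produced by one shift-and-add iteration core:

* rotation mode drives the angle register ``z`` to zero through rotations
  by ``atanh(2^-i)``, leaving ``(x, y) = (cosh z0, sinh z0)`` after gain
  compensation, so ``exp(z0) = x + y``;
* vectoring mode drives ``y`` to zero, accumulating ``atanh(y0/x0)`` in
  ``z``; with ``(x0, y0) = (f+1, f-1)`` this yields ``ln f = 2 z`` without
  any division.

The iteration schedule is the standard hyperbolic one: i = 1..16 with the
convergence-mandated repeats at i = 4 and i = 13 (18 micro-iterations).
All register arithmetic is float32; shifts are realised as multiplication
by the exact power of two 2^-i, which is lossless in floating point.

Post-processing: rotation mode only re-combines x + y. Vectoring mode adds
a first-order residual correction ``z + y/x`` (the remaining angle is
``atanh(y/x) ~ y/x`` to cubic order), which brings ln to float32 rounding
accuracy near 1 instead of the raw ~atanh(2^-16) truncation floor.
Range reduction is conventional: ``exp`` splits v = m*ln2 + r with
|r| <= ln2/2 (Cody-Waite two-constant reduction) and rescales by 2^m;
``ln`` extracts the exponent so the mantissa lies in [sqrt(1/2), sqrt(2)),
avoiding cancellation for arguments near 1.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ITERATIONS",
    "iteration_schedule",
    "angle_rom",
    "hyperbolic_gain",
    "cordic_core",
    "cordic_exp",
    "cordic_ln",
    "error_sweep",
]

DEFAULT_ITERATIONS = 16

#: Iteration indices that must be repeated for hyperbolic CORDIC convergence
#: (i, 3i+1 rule: 4, 13, 40, ...).
_REPEAT_INDICES = (4, 13, 40)

_F32_ONE = np.float32(1.0)

# Cody-Waite split of ln 2 for float32 range reduction: the high part has
# its trailing mantissa bits zeroed so m * LN2_HI is exact for |m| < 2^16.
_LN2_HI = np.float32(np.float64(0.693359375))
_LN2_LO = np.float32(np.log(2.0) - 0.693359375)
_INV_LN2 = np.float32(1.0 / np.log(2.0))
_LN2_F64 = np.log(2.0)
_SQRT_HALF = np.float32(np.sqrt(0.5))


def iteration_schedule(n_iterations: int = DEFAULT_ITERATIONS) -> list[int]:
    """Hyperbolic iteration indices 1..n with the standard repeats."""
    if n_iterations < 1:
        raise DomainError("n_iterations must be >= 1")
    sched: list[int] = []
    for i in range(1, n_iterations + 1):
        sched.append(i)
        if i in _REPEAT_INDICES:
            sched.append(i)
    return sched


def angle_rom(n_iterations: int = DEFAULT_ITERATIONS) -> np.ndarray:
    """Single-precision atanh(2^-i) table for i = 1..n (ROM contents;
    repeats reuse the same entry)."""
    i = np.arange(1, n_iterations + 1, dtype=np.float64)
    return np.arctanh(2.0 ** (-i)).astype(np.float32)


def hyperbolic_gain(n_iterations: int = DEFAULT_ITERATIONS) -> float:
    """The CORDIC gain K_h = prod sqrt(1 - 2^-2i) over the full schedule
    (repeats included), in double precision."""
    prod = 1.0
    for i in iteration_schedule(n_iterations):
        prod *= np.sqrt(1.0 - 2.0 ** (-2 * i))
    return float(prod)


def _max_rotation(n_iterations: int) -> float:
    return float(sum(np.arctanh(2.0 ** (-i)) for i in iteration_schedule(n_iterations)))


def cordic_core(
    value,
    mode: str,
    n_iterations: int = DEFAULT_ITERATIONS,
):
    """Run the hyperbolic iteration core; returns registers ``(x, y, z)``.

    Parameters
    ----------
    value
        Rotation mode: the target angle ``z0`` (scalar or array), which must
        lie inside the convergence bound (~1.118 for 16 iterations).
        Vectoring mode: a pair ``(x0, y0)`` with ``|y0| < x0`` and
        ``|atanh(y0/x0)|`` inside the same bound.
    mode
        ``"rotation"`` (exp) or ``"vectoring"`` (log).

    Rotation mode pre-loads ``x`` with 1/K_h so the outputs are the
    gain-compensated ``(cosh z0, sinh z0)`` directly.
    """
    rom = angle_rom(n_iterations)
    bound = _max_rotation(n_iterations)
    inv_gain = np.float32(1.0 / hyperbolic_gain(n_iterations))

    if mode == "rotation":
        z = np.asarray(value, dtype=np.float32)
        if not np.all(np.isfinite(z)):
            raise DomainError("rotation input must be finite")
        if np.any(np.abs(z) > bound):
            raise DomainError(
                f"rotation angle outside convergence bound {bound:.4f}; "
                "apply range reduction first"
            )
        x = np.full_like(z, inv_gain)
        y = np.zeros_like(z)
    elif mode == "vectoring":
        x0, y0 = value
        x = np.asarray(x0, dtype=np.float32).copy()
        y = np.asarray(y0, dtype=np.float32).copy()
        x, y = np.broadcast_arrays(x, y)
        x, y = x.astype(np.float32), y.astype(np.float32)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise DomainError("vectoring input must be finite")
        if np.any(x <= 0) or np.any(np.abs(y) >= x):
            raise DomainError("vectoring requires 0 < |y| < x (|y/x| < 1)")
        with np.errstate(divide="ignore"):
            ratio = np.arctanh(np.clip(y.astype(np.float64) / x.astype(np.float64), -1, 1))
        if np.any(np.abs(ratio) > bound):
            raise DomainError(
                f"vectoring angle outside convergence bound {bound:.4f}"
            )
        z = np.zeros_like(x)
    else:
        raise DomainError(f"unknown mode {mode!r}")

    for i in iteration_schedule(n_iterations):
        p = np.float32(2.0 ** (-i))
        alpha = rom[i - 1]
        if mode == "rotation":
            d_pos = z >= 0
        else:
            d_pos = y < 0  # drive y toward zero
        xs = x * p
        ys = y * p
        x_new = np.where(d_pos, x + ys, x - ys).astype(np.float32)
        y_new = np.where(d_pos, y + xs, y - xs).astype(np.float32)
        z_new = np.where(d_pos, z - alpha, z + alpha).astype(np.float32)
        x, y, z = x_new, y_new, z_new
    return x, y, z


def cordic_exp(v, n_iterations: int = DEFAULT_ITERATIONS):
    """Single-precision e**v via hyperbolic CORDIC rotation mode.

    Range reduction v = m*ln2 + r with |r| <= ln2/2; the core evaluates
    e**r = cosh r + sinh r and the result is rescaled by 2**m through
    exponent arithmetic (ldexp). Underflow below the float32 subnormal
    range flushes to 0 (logged at debug level); overflow saturates to inf.
    Scalars in, scalar out; arrays in, array out.
    """
    arr = np.asarray(v, dtype=np.float32)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if not np.all(np.isfinite(arr)):
        raise DomainError("cordic_exp requires finite input")
    # Saturate outside the float32 result range: e**89 overflows, e**-104
    # underflows past the subnormals, so clipping the argument there leaves
    # every representable result unchanged.
    arg = np.clip(arr, np.float32(-104.0), np.float32(89.0))
    m = np.rint(arg * _INV_LN2).astype(np.int32)
    mf = m.astype(np.float32)
    r = (arg - mf * _LN2_HI) - mf * _LN2_LO
    x, y, _ = cordic_core(r, "rotation", n_iterations)
    with np.errstate(under="ignore", over="ignore"):
        out = np.ldexp((x + y).astype(np.float32), m).astype(np.float32)
    n_under = int(np.count_nonzero((out == 0) & (arr < 0)))
    if n_under:
        logger.debug("cordic_exp: %d result(s) underflowed to 0", n_under)
    return out[0] if scalar else out


def cordic_ln(v, n_iterations: int = DEFAULT_ITERATIONS):
    """Single-precision natural log via hyperbolic CORDIC vectoring mode.

    The argument is reduced to v = 2**e * f with f in [sqrt(1/2), sqrt(2))
    so ln f is small and no cancellation occurs near v = 1; vectoring on
    (f+1, f-1) accumulates atanh((f-1)/(f+1)) = ln(f)/2, the post-stage
    applies the residual correction z + y/x, and ln v = e*ln2 + 2*z_corr.
    """
    arr = np.asarray(v, dtype=np.float32)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError("cordic_ln requires finite positive input")
    f, e = np.frexp(arr)  # f in [0.5, 1)
    # shift mantissa into [sqrt(1/2), sqrt(2)) to keep ln f small
    low = f < _SQRT_HALF
    f = np.where(low, f + f, f).astype(np.float32)
    e = (e - low.astype(e.dtype)).astype(np.int32)

    x0 = (f + _F32_ONE).astype(np.float32)
    y0 = (f - _F32_ONE).astype(np.float32)
    t = (y0 / x0).astype(np.float32)
    # Small-angle bypass: below |t| = 2^-7 the iteration core's float32
    # angle accumulation noise (~1e-7) would dominate the tiny result, so
    # post-processing returns the odd series atanh(t) ~ t + t^3/3 directly
    # (truncation error t^5/5, relative t^4/5 < 1e-9 at the threshold).
    small = np.abs(t) < np.float32(2.0 ** -7)
    t_series = (t + (t * t * t) * np.float32(1.0 / 3.0)).astype(np.float32)
    y0_safe = np.where(small, np.float32(0.25), y0)  # keep core in-domain
    x, y, z = cordic_core((x0, y0_safe), "vectoring", n_iterations)
    z_corr = (z + y / x).astype(np.float32)
    z_corr = np.where(small, t_series, z_corr)
    ef = e.astype(np.float32)
    out = (ef * _LN2_HI + (np.float32(2.0) * z_corr + ef * _LN2_LO)).astype(np.float32)
    return out[0] if scalar else out


def error_sweep(
    fn: str = "exp",
    n_points: int = 10_000,
    n_iterations: int = DEFAULT_ITERATIONS,
) -> dict[str, np.ndarray]:
    """Relative-error sweep of a CORDIC function against the double-precision
    library reference; returns inputs, outputs, reference and relative error.
    """
    if fn == "exp":
        grid = np.linspace(-30.0, 30.0, n_points).astype(np.float32)
        got = cordic_exp(grid, n_iterations)
        ref = np.exp(grid.astype(np.float64))
    elif fn == "ln":
        grid = np.geomspace(2.0 ** -30, 2.0 ** 30, n_points).astype(np.float32)
        got = cordic_ln(grid, n_iterations)
        ref = np.log(grid.astype(np.float64))
    else:
        raise DomainError(f"unknown function {fn!r}")
    denom = np.maximum(np.abs(ref), np.finfo(np.float64).tiny)
    rel = np.abs(got.astype(np.float64) - ref) / denom
    return {"input": grid, "output": got, "reference": ref, "rel_error": rel}
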