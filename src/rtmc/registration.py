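"""Rigid subpixel displacement estimation via Fourier-domain NCC.

The displacement between a (high-pass filtered) frame and the template is
found by evaluating the normalized cross-correlation (NCC) over a window of
integer candidate shifts, then refining the integer peak with independent
one-dimensional parabola fits along each axis.

The NCC at shift ``(u, v)`` is the Pearson correlation between the two images
restricted to their overlap region, which makes the estimate invariant to
linear gray-value changes (illumination fluctuation, gain drift). All of the
overlap sums it needs — cross products, per-image sums and sums of squares,
and the overlap pixel count — are cross-correlations of the images (or their
squares) with an all-ones mask, so the whole map is computed with a handful
of FFTs instead of a loop over shifts.

Sign convention used throughout the package: a result ``(dx, dy)`` means the
frame content sits ``dx`` columns to the right and ``dy`` rows down relative
to the template; correction therefore applies ``(-dx, -dy)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.fft import irfft2, next_fast_len, rfft2

from .exceptions import (
    DegenerateInputError,
    DimensionError,
    UndefinedCorrelationError,
)

__all__ = [
    "NCCMap",
    "RegistrationResult",
    "RegistrationParams",
    "ncc_spatial_oracle",
    "ncc_fourier",
    "subpixel_peak",
    "apply_shift",
    "register_frame",
]


@dataclass(frozen=True)
class NCCMap:
    """NCC values over the integer shift window ``[-max_shift, +max_shift]²``.

    ``values[iy, ix]`` is the correlation at shift
    ``(u, v) = (ix - max_shift, iy - max_shift)`` (u = column lag, v = row
    lag); the grid center is shift (0, 0). ``valid`` marks lags where the
    overlap was large enough and both variance terms were non-degenerate.
    """

    values: np.ndarray
    valid: np.ndarray
    max_shift: int

    def lag(self, iy: int, ix: int) -> tuple[int, int]:
        """Map a grid index to its (u, v) shift."""
        return ix - self.max_shift, iy - self.max_shift


@dataclass(frozen=True)
class RegistrationResult:
    """Estimated displacement of a frame relative to the template."""

    dx: float
    dy: float
    peak_ncc: float
    integer_fallback: bool = False
    frame_index: int = -1


@dataclass(frozen=True)
class RegistrationParams:
    """Tunables for the NCC search window and numerical guards."""

    max_shift: int = 20
    min_overlap: float = 0.5  # fraction of full-frame area
    eps: float = 1e-12


def ncc_spatial_oracle(f1: np.ndarray, f2: np.ndarray, u: int, v: int) -> float:
    """Literal spatial-domain NCC at a single integer shift (u, v).

    Brute-force reference: restrict both images to the overlap region of f1
    and f2-shifted-by-(u, v), subtract the overlap means, and correlate.
    O(N) per lag — intended as the oracle the fast Fourier path is tested
    against, not as a production code path.
    """
    f1 = np.asarray(f1, dtype=np.float64)
    f2 = np.asarray(f2, dtype=np.float64)
    if f1.shape != f2.shape:
        raise DimensionError(f"shape mismatch: {f1.shape} vs {f2.shape}")
    h, w = f1.shape
    u, v = int(u), int(v)
    # f2 shifted right/down by (u, v): overlap in f1 coordinates
    y0, y1 = max(0, v), min(h, h + v)
    x0, x1 = max(0, u), min(w, w + u)
    if y0 >= y1 or x0 >= x1:
        raise UndefinedCorrelationError(f"empty overlap at shift ({u}, {v})")
    a = f1[y0:y1, x0:x1]
    b = f2[y0 - v : y1 - v, x0 - u : x1 - u]
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt(np.sum(da * da) * np.sum(db * db))
    if denom == 0.0:
        raise UndefinedCorrelationError(
            f"zero variance in overlap patch at shift ({u}, {v})"
        )
    return float(np.sum(da * db) / denom)


def ncc_fourier(
    f1: np.ndarray,
    f2: np.ndarray,
    max_shift: int = 20,
    min_overlap: float = 0.5,
    eps: float = 1e-12,
) -> NCCMap:
    """Compute the NCC map over ``[-max_shift, +max_shift]²`` with FFTs.

    Both images are zero-padded to at least ``size + max_shift`` per axis so
    every lag inside the window is a true linear (non-circular) correlation.
    Lags whose overlap covers less than ``min_overlap`` of the frame area, or
    where either variance term falls below ``eps``, are masked invalid.
    """
    f1 = np.asarray(f1, dtype=np.float64)
    f2 = np.asarray(f2, dtype=np.float64)
    if f1.shape != f2.shape:
        raise DimensionError(f"shape mismatch: {f1.shape} vs {f2.shape}")
    h, w = f1.shape
    m = int(max_shift)
    if m < 0 or m >= min(h, w) / 2:
        raise DimensionError(
            f"max_shift {m} must be in [0, min(h, w)/2) for {h}x{w} frames"
        )

    # pad so lags up to ±m suffer no circular aliasing
    shape = (next_fast_len(h + m + 1), next_fast_len(w + m + 1))
    F1 = rfft2(f1, shape)
    F2c = np.conj(rfft2(f2, shape))
    F1sq = rfft2(f1 * f1, shape)
    F2sqc = np.conj(rfft2(f2 * f2, shape))
    I1 = rfft2(np.ones((h, w)), shape)
    I2c = np.conj(I1)

    xcorr = irfft2(F1 * F2c, shape)
    sum1 = irfft2(F1 * I2c, shape)    # sum of f1 over the overlap, per lag
    sum2 = irfft2(I1 * F2c, shape)    # sum of f2 over the overlap, per lag
    sq1 = irfft2(F1sq * I2c, shape)
    sq2 = irfft2(I1 * F2sqc, shape)
    n_ov = irfft2(I1 * I2c, shape)    # overlap pixel count, per lag

    # extract the centered lag window: lag t lives at index t mod shape
    idx_y = np.arange(-m, m + 1) % shape[0]
    idx_x = np.arange(-m, m + 1) % shape[1]
    win = np.ix_(idx_y, idx_x)
    xcorr, sum1, sum2, sq1, sq2, n_ov = (
        a[win] for a in (xcorr, sum1, sum2, sq1, sq2, n_ov)
    )
    n_ov = np.maximum(np.rint(n_ov), 1.0)

    num = xcorr - sum1 * sum2 / n_ov
    var1 = sq1 - sum1 * sum1 / n_ov
    var2 = sq2 - sum2 * sum2 / n_ov

    valid = (n_ov >= min_overlap * h * w) & (var1 > eps) & (var2 > eps)
    values = np.zeros_like(num)
    np.divide(num, np.sqrt(var1 * var2), out=values, where=valid)
    values = np.clip(values, -1.0, 1.0, out=values)
    values[~valid] = np.nan

    if not valid.any():
        raise DegenerateInputError("all lags masked: degenerate input images")
    return NCCMap(values=values, valid=valid, max_shift=m)


def _parabola_offset(left: float, center: float, right: float) -> float:
    """Vertex offset of the parabola through three unit-spaced samples.

    Clamped to [-0.5, 0.5]; a flat (zero-curvature) triple yields 0.
    """
    denom = 2.0 * left - 4.0 * center + 2.0 * right
    if denom == 0.0:
        return 0.0
    return float(np.clip((left - right) / denom, -0.5, 0.5))


def subpixel_peak(ncc_map: NCCMap) -> RegistrationResult:
    """Locate the NCC peak and refine it to subpixel precision.

    The integer argmax (first occurrence in row-major order on ties) is
    refined by fitting independent 1-D parabolas through the peak and its two
    axis neighbors in x and in y. If any of the four neighbors is outside the
    window or masked, the integer peak is returned with
    ``integer_fallback=True``.
    """
    vals = ncc_map.values
    if not ncc_map.valid.any():
        raise DegenerateInputError("NCC map is fully masked")
    flat = np.where(ncc_map.valid, vals, -np.inf)
    iy, ix = np.unravel_index(np.argmax(flat), flat.shape)
    peak = float(vals[iy, ix])
    u, v = ncc_map.lag(iy, ix)

    ny, nx = vals.shape
    ok = (
        0 < ix < nx - 1
        and 0 < iy < ny - 1
        and ncc_map.valid[iy, ix - 1]
        and ncc_map.valid[iy, ix + 1]
        and ncc_map.valid[iy - 1, ix]
        and ncc_map.valid[iy + 1, ix]
    )
    if not ok:
        return RegistrationResult(dx=float(u), dy=float(v), peak_ncc=peak,
                                  integer_fallback=True)
    off_x = _parabola_offset(vals[iy, ix - 1], peak, vals[iy, ix + 1])
    off_y = _parabola_offset(vals[iy - 1, ix], peak, vals[iy + 1, ix])
    return RegistrationResult(dx=u + off_x, dy=v + off_y, peak_ncc=peak)


def apply_shift(frame: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Translate frame content by dx columns (right) and dy rows (down).

    Resampling is bilinear; pixels exposed at the border are zero-filled.
    Integer shifts reduce to an exact copy.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if dx == 0.0 and dy == 0.0:
        return frame.copy()
    return ndimage.shift(frame, (dy, dx), order=1, mode="constant", cval=0.0,
                         prefilter=False)


def register_frame(
    filtered_frame: np.ndarray,
    template: np.ndarray,
    params: RegistrationParams | None = None,
    frame_index: int = -1,
) -> RegistrationResult:
    """Estimate the displacement of a filtered frame relative to the template.

    Composes :func:`ncc_fourier` and :func:`subpixel_peak`. The result is the
    shift of the frame's content relative to the template, so correction is
    ``apply_shift(frame, -dx, -dy)``.
    """
    p = params or RegistrationParams()
    ncc = ncc_fourier(filtered_frame, template, max_shift=p.max_shift,
                      min_overlap=p.min_overlap, eps=p.eps)
    res = subpixel_peak(ncc)
    if frame_index >= 0:
        res = RegistrationResult(res.dx, res.dy, res.peak_ncc,
                                 res.integer_fallback, frame_index)
    return res
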