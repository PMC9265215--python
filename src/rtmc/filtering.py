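"""Zero-sum Gaussian high-pass filtering.

One-photon miniscope frames carry a large diffuse background from out-of-focus
light scatter. Convolving with a Gaussian kernel whose coefficients have been
mean-subtracted (so they sum to zero) removes that smooth background while
preserving neuron-scale structure: the positive central lobe of the kernel is
matched to the size of a neuron, so cell bodies and fixed landmarks such as
blood vessels survive filtering and anchor the correlation-based registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .exceptions import DimensionError, ParameterError

__all__ = ["FilterKernel", "make_highpass_kernel", "highpass_filter"]


@dataclass(frozen=True)
class FilterKernel:
    """A mean-subtracted (zero-sum) Gaussian kernel.

    Attributes
    ----------
    coefficients : ndarray
        Square array with odd side length; sums to zero to machine precision.
    sigma : float
        Standard deviation of the underlying Gaussian, in pixels.
    center : tuple of int
        Index of the kernel center, ``(row, col)``.
    """

    coefficients: np.ndarray
    sigma: float
    center: tuple[int, int]

    @property
    def size(self) -> int:
        return self.coefficients.shape[0]


def make_highpass_kernel(
    neuron_diameter: float = 10.0,
    sigma: float | None = None,
    size_factor: float = 3.0,
) -> FilterKernel:
    """Build the zero-sum Gaussian high-pass kernel.

    The side length is the smallest odd integer at least
    ``size_factor * neuron_diameter`` (three neuron diameters by default).
    ``sigma`` defaults to half the neuron diameter (the neuron radius); the
    Gaussian is evaluated on the kernel grid and its spatial mean subtracted,
    so the total weight is zero and constant/smooth image content is
    annihilated.

    Parameters
    ----------
    neuron_diameter : float
        Typical neuron diameter in pixels (~10 px for miniscope data).
    sigma : float, optional
        Gaussian standard deviation in pixels; default ``neuron_diameter / 2``.
    size_factor : float
        Kernel side length as a multiple of the neuron diameter.
    """
    if neuron_diameter < 1:
        raise ParameterError(f"neuron_diameter must be >= 1, got {neuron_diameter}")
    if size_factor <= 0:
        raise ParameterError(f"size_factor must be > 0, got {size_factor}")
    if sigma is None:
        sigma = neuron_diameter / 2.0
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")

    side = int(np.ceil(size_factor * neuron_diameter))
    if side % 2 == 0:
        side += 1
    c = side // 2
    y, x = np.mgrid[0:side, 0:side]
    g = np.exp(-((x - c) ** 2 + (y - c) ** 2) / (2.0 * sigma**2))
    g -= g.mean()
    return FilterKernel(coefficients=g, sigma=float(sigma), center=(c, c))


def highpass_filter(frame: np.ndarray, kernel: FilterKernel) -> np.ndarray:
    """Convolve a frame with the zero-sum kernel, same-size output.

    Boundaries are handled by reflection padding so the frame edge does not
    generate a spurious step response. The output is real-valued and signed.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise DimensionError(f"frame must be 2-D, got shape {frame.shape}")
    k = kernel.coefficients
    if frame.shape[0] < k.shape[0] or frame.shape[1] < k.shape[1]:
        raise DimensionError(
            f"frame {frame.shape} is smaller than kernel {k.shape}"
        )
    pad = k.shape[0] // 2
    padded = np.pad(frame, pad, mode="reflect")
    # symmetric kernel: convolution and correlation coincide
    return fftconvolve(padded, k, mode="valid")
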