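"""Gaussian smoothing kernels shared by the null simulator and generators.

The smoothness convention everywhere is full width at half maximum in voxel
units, FWHM = 2*sqrt(2*ln 2) * sigma ~= 2.3548 * sigma.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_kernel1d(fwhm_vox: float, truncate: float = 4.0) -> np.ndarray:
    """Normalized (sum 1) discrete Gaussian weights for a given FWHM."""
    sigma = fwhm_vox * FWHM_TO_SIGMA
    if sigma <= 0:
        return np.array([1.0])
    radius = max(1, int(truncate * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def _separable(data: np.ndarray, weights: np.ndarray, mode: str) -> np.ndarray:
    out = np.asarray(data, dtype=np.float64)
    for axis in range(out.ndim):
        out = ndimage.correlate1d(out, weights, axis=axis, mode=mode, cval=0.0)
    return out


def smooth_periodic(data: np.ndarray, fwhm_vox: float) -> np.ndarray:
    """Smooth with periodic boundaries (stationary statistics everywhere)."""
    if fwhm_vox <= 0:
        return np.asarray(data, dtype=np.float64).copy()
    return _separable(data, gaussian_kernel1d(fwhm_vox), mode="wrap")


def smooth_unit_variance(noise: np.ndarray, fwhm_vox: float,
                         mask: np.ndarray | None = None) -> np.ndarray:
    """Smooth white noise with edge/mask renormalization to unit variance.

    Convolves ``noise * mask`` with a Gaussian kernel and divides by the
    pointwise standard deviation that the convolution of unit-variance white
    noise would have there, sqrt((k^2 * mask)(x)).  This removes the variance
    attenuation that plain convolution produces at mask edges, so thresholding
    behaves uniformly across the field of view.  Returns 0 outside the mask.
    """
    noise = np.asarray(noise, dtype=np.float64)
    m = np.ones(noise.shape) if mask is None else np.asarray(mask, dtype=np.float64)
    if fwhm_vox <= 0:
        return noise * m
    w = gaussian_kernel1d(fwhm_vox)
    num = _separable(noise * m, w, mode="constant")
    var = _separable(m, w ** 2, mode="constant")
    out = np.zeros_like(noise)
    inside = m > 0
    out[inside] = num[inside] / np.sqrt(var[inside])
    return out
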