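"""Lanczos-3 interpolation for integer upscaling factors.

The kernel is the a = 3 windowed sinc

    L(t) = sinc(t) * sinc(t / 3)   for |t| < 3, else 0,

applied separably with centre-aligned sampling: output pixel i samples
input position (i + 0.5) / s - 0.5.  Rows of the resampling matrix are
renormalised to sum to 1, so constant images map to constant images
exactly, and scale 1 reduces to the identity.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["lanczos_kernel", "upscale_lanczos"]

_A = 3  # kernel support radius


def lanczos_kernel(t: np.ndarray) -> np.ndarray:
    """L(t) = sinc(t) sinc(t/a) on |t| < a (numpy sinc is sin(pi x)/(pi x))."""
    t = np.asarray(t, dtype=float)
    out = np.sinc(t) * np.sinc(t / _A)
    return np.where(np.abs(t) < _A, out, 0.0)


@lru_cache(maxsize=32)
def _resample_matrix(n_in: int, scale: int) -> np.ndarray:
    """(n_in * scale, n_in) matrix applying 1D Lanczos-3 upscaling.

    Out-of-range taps are clamped to the edge sample (edge extension).
    """
    n_out = n_in * scale
    mat = np.zeros((n_out, n_in))
    for i in range(n_out):
        x = (i + 0.5) / scale - 0.5
        j0 = int(np.floor(x)) - _A + 1
        taps = np.arange(j0, j0 + 2 * _A)
        weights = lanczos_kernel(x - taps)
        weights = weights / weights.sum()
        np.add.at(mat[i], np.clip(taps, 0, n_in - 1), weights)
    return mat


def upscale_lanczos(image: np.ndarray, scale: int) -> np.ndarray:
    """Upscale a 2D image by an integer factor with Lanczos-3.

    Separable: rows then columns through the precomputed resampling
    matrix.  ``scale = 1`` returns the image unchanged (up to float
    round-off of an identity matmul).
    """
    if int(scale) != scale or scale < 1:
        raise ValueError("scale must be a positive integer")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("upscale_lanczos expects a 2D image")
    scale = int(scale)
    if scale == 1:
        return img.copy()
    mx = _resample_matrix(img.shape[0], scale)
    my = _resample_matrix(img.shape[1], scale)
    return mx @ img @ my.T
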