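"""Temporal and spatial preprocessing of BOLD series.

The chain, in order: discard equilibration frames, per-voxel linear
detrending, zero-phase temporal low-pass filtering, and in-plane
Gaussian smoothing.  Each step takes and returns a
:class:`~fmrisr.io.FunctionalSeries`, so the chain composes freely and
either arm of the analysis (native-resolution or super-resolved) can
share it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .io import FunctionalSeries

__all__ = [
    "PreprocessConfig",
    "discard_initial",
    "detrend_linear",
    "lowpass_temporal",
    "smooth_spatial",
    "run_chain",
]

# kernel truncation radius, in units of sigma
_TRUNCATE = 4.0


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    ``n_discard`` frames are dropped from the start (equilibration);
    ``lowpass_cutoff`` is in Hz and must stay below Nyquist = 1/(2 TR);
    ``spatial_sigma`` is the Gaussian sd in pixels *of the grid being
    smoothed*.
    """

    n_discard: int = 60
    detrend: bool = True
    lowpass: bool = True
    lowpass_cutoff: float = 0.1
    smoothing: bool = True
    spatial_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        if self.spatial_sigma < 0:
            raise ValueError("spatial_sigma must be >= 0")
        if self.lowpass_cutoff <= 0:
            raise ValueError("lowpass_cutoff must be positive")


def discard_initial(series: FunctionalSeries, n: int) -> FunctionalSeries:
    """Drop the first ``n`` frames (magnetization equilibration)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= series.n_volumes:
        raise ValueError(
            f"cannot discard {n} of {series.n_volumes} frames; nothing would remain"
        )
    if n == 0:
        return series
    return series.with_data(series.data[:, :, :, n:])


def detrend_linear(series: FunctionalSeries) -> FunctionalSeries:
    """Remove the per-voxel least-squares line (intercept + slope).

    Output timecourses have zero mean and zero fitted slope; applying
    the operation twice equals applying it once (projection).
    """
    t_len = series.n_volumes
    if t_len < 3:
        raise ValueError("need at least 3 time points to detrend")
    t = np.arange(t_len, dtype=float)
    design = np.stack([np.ones(t_len), t], axis=1)  # (T, 2)
    # hat matrix applied along time: fitted = X (X^T X)^-1 X^T y
    pinv = np.linalg.pinv(design)  # (2, T)
    flat = series.data.reshape(-1, t_len)
    fitted = (flat @ pinv.T) @ design.T
    return series.with_data((flat - fitted).reshape(series.data.shape))


def lowpass_temporal(series: FunctionalSeries, cutoff: float | None = 0.1) -> FunctionalSeries:
    """Zero-phase Butterworth (order 4) low-pass along time.

    The forward-backward pass (``sosfiltfilt``) gives zero phase delay
    and squares the magnitude response; DC gain stays exactly 1, so
    constant timecourses are fixed points.
    """
    nyquist = 0.5 / series.tr
    if cutoff is None or cutoff <= 0:
        raise ValueError("cutoff must be a positive frequency in Hz")
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyquist} Hz")
    sos = signal.butter(4, cutoff, btype="low", fs=1.0 / series.tr, output="sos")
    filtered = signal.sosfiltfilt(sos, series.data, axis=3)
    return series.with_data(filtered)


def smooth_spatial(data, sigma: float = 1.5):
    """In-plane 2D Gaussian smoothing (reflective boundary, 4-sigma kernel).

    Accepts a :class:`FunctionalSeries` (smooths every slice of every
    frame), or a bare 2D/3D array (smooths the two leading axes).
    ``sigma`` is in pixels; ``sigma = 0`` is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")

    def _smooth_array(arr: np.ndarray) -> np.ndarray:
        if sigma == 0:
            return arr.copy()
        sigmas = (sigma, sigma) + (0,) * (arr.ndim - 2)
        return ndimage.gaussian_filter(
            arr.astype(float), sigma=sigmas, mode="reflect", truncate=_TRUNCATE
        )

    if isinstance(data, FunctionalSeries):
        return data.with_data(_smooth_array(data.data))
    arr = np.asarray(data)
    if arr.ndim < 2:
        raise ValueError("need a 2D image (or stack) to smooth")
    return _smooth_array(arr)


def run_chain(series: FunctionalSeries, cfg: PreprocessConfig) -> FunctionalSeries:
    """Apply the full chain: discard -> detrend -> low-pass -> smooth."""
    out = discard_initial(series, cfg.n_discard)
    if cfg.detrend:
        out = detrend_linear(out)
    if cfg.lowpass:
        out = lowpass_temporal(out, cfg.lowpass_cutoff)
    if cfg.smoothing and cfg.spatial_sigma > 0:
        out = smooth_spatial(out, cfg.spatial_sigma)
    return out
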