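"""Canonical hemodynamic response function (double-gamma).

The convention follows SPM's canonical HRF: a positive gamma density
peaking near 5-6 s minus a later undershoot gamma scaled by 1/6,
sampled at the series TR over a 32 s support and normalised to unit
sum so that convolution preserves the scale of a sustained response.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["canonical_hrf"]

PEAK_DELAY = 6.0  # s, shape of the response gamma (scale 1)
UNDERSHOOT_DELAY = 16.0  # s, shape of the undershoot gamma (scale 1)
UNDERSHOOT_RATIO = 6.0  # peak/undershoot amplitude ratio
DURATION = 32.0  # s, kernel support


def canonical_hrf(tr: float, duration: float = DURATION) -> np.ndarray:
    """Sample the canonical double-gamma HRF at interval ``tr`` seconds.

    Returns a kernel of length ``ceil(duration / tr)`` whose entries sum
    to 1 (so convolving a sustained boxcar tends to the boxcar height).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, duration, tr)
    h = stats.gamma.pdf(t, PEAK_DELAY) - stats.gamma.pdf(t, UNDERSHOOT_DELAY) / UNDERSHOOT_RATIO
    s = h.sum()
    if s <= 0:
        raise ValueError("degenerate HRF sampling; increase duration or decrease tr")
    return h / s
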