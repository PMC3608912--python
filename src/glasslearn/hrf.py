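"""Canonical double-gamma hemodynamic response function."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["double_gamma_hrf", "convolve_regressor"]


def double_gamma_hrf(tr_s: float = 1.5, duration_s: float = 32.0,
                     peak_delay_s: float = 6.0, undershoot_delay_s: float = 16.0,
                     peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                     undershoot_ratio: float = 1.0 / 6.0,
                     oversampling: int = 16) -> np.ndarray:
    """Sampled double-gamma HRF, peak-normalized to 1.

    The response is the difference of two gamma densities: a positive lobe
    peaking near ``peak_delay_s`` and an undershoot near
    ``undershoot_delay_s`` scaled by ``undershoot_ratio``.  Computed on a
    fine grid then decimated to the TR so short TRs do not alias the peak.
    """
    dt = tr_s / oversampling
    t = np.arange(0.0, duration_s, dt)
    # gamma with shape a, scale b peaks at (a - 1) * b: parameterize so the
    # positive lobe's mode sits exactly at peak_delay_s
    peak = stats.gamma.pdf(t, peak_delay_s / peak_disp + 1.0, scale=peak_disp)
    under = stats.gamma.pdf(t, undershoot_delay_s / undershoot_disp + 1.0,
                            scale=undershoot_disp)
    h = peak - undershoot_ratio * under
    h = h / h.max()
    return h[::oversampling]


def convolve_regressor(boxcar: np.ndarray, hrf: np.ndarray) -> np.ndarray:
    """Causal convolution truncated to the regressor length."""
    return np.convolve(boxcar, hrf)[: len(boxcar)]
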