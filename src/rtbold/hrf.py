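"""Canonical haemodynamic response function.

The kernel is the SPM-style difference of two gamma densities
``g(t; 6, 1) - (1/6) g(t; 16, 1)`` (shape = delay / dispersion,
scale = dispersion), sampled on an oversampled "microtime" grid and
peak-normalised to 1 so that regression coefficients are in the units of the
trial amplitudes that generated the signal.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .config import HRFSpec

__all__ = ["canonical_hrf"]


def canonical_hrf(spec: HRFSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sample the canonical double-gamma HRF.

    Parameters
    ----------
    spec
        Kernel parameters; defaults to the canonical (6, 16, 1, 1, 1/6) form
        sampled every 0.1 s over 32 s.

    Returns
    -------
    t, h
        Time grid (s) and the peak-normalised kernel values.
    """
    spec = spec or HRFSpec()
    t = np.arange(0.0, spec.duration, spec.microtime_dt)
    peak = stats.gamma.pdf(
        t, spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion
    )
    undershoot = stats.gamma.pdf(
        t,
        spec.undershoot_delay / spec.undershoot_dispersion,
        scale=spec.undershoot_dispersion,
    )
    h = peak - spec.undershoot_ratio * undershoot
    return t, h / h.max()
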