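"""Canonical double-gamma hemodynamic response function.

The canonical HRF is the difference of two gamma densities — a positive
response peaking around 5 s and a later undershoot — with the parameter
set popularised by SPM (peak delay 6 s, undershoot delay 16 s, unit
dispersions, undershoot ratio 1/6, 32 s support).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma

__all__ = ["HrfParams", "canonical_hrf"]


@dataclass(frozen=True)
class HrfParams:
    """Parameters of the double-gamma canonical HRF (all delays in seconds)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length_s: float = 32.0
    microtime_bins: int = 16

    def __post_init__(self) -> None:
        for name in ("peak_delay_s", "undershoot_delay_s", "peak_disp",
                     "undershoot_disp", "length_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be nonnegative")
        if self.length_s < max(self.peak_delay_s, self.undershoot_delay_s):
            raise ValueError("length_s must cover both gamma components")
        if self.microtime_bins < 1:
            raise ValueError("microtime_bins must be >= 1")


def canonical_hrf(params: HrfParams | None = None, dt_s: float = 0.125) -> np.ndarray:
    """Sample the canonical HRF on ``[0, length_s]`` at step ``dt_s``.

    The kernel is ``gampdf(t; peak_delay/peak_disp, peak_disp) -
    ratio * gampdf(t; undershoot_delay/undershoot_disp, undershoot_disp)``,
    rescaled to unit peak.

    Parameters
    ----------
    params
        HRF shape parameters; defaults to the canonical set.
    dt_s
        Sampling interval in seconds (e.g. ``tr_s / microtime_bins``).
    """
    if params is None:
        params = HrfParams()
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    t = np.arange(0.0, params.length_s + dt_s / 2, dt_s)
    peak = _gamma.pdf(t, params.peak_delay_s / params.peak_disp,
                      scale=params.peak_disp)
    under = _gamma.pdf(t, params.undershoot_delay_s / params.undershoot_disp,
                       scale=params.undershoot_disp)
    h = peak - params.undershoot_ratio * under
    return h / np.max(h)
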