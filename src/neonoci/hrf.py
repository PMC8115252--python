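"""Double-gamma haemodynamic response function.

The kernel is the difference of two gamma densities,

    h(t) = g(t; a1, b1) - c * g(t; a2, b2),

normalised so its peak value is 1 (a convention that fixes the otherwise
arbitrary scale; response amplitude then lives entirely in the GLM beta).
Neonatal haemodynamics differ from the adult canonical response, so all five
shape parameters are configurable; the default is the adult canonical
double-gamma (peak gamma shape 6 / scale 1 s, undershoot shape 16 / scale
1 s, undershoot ratio 1/6), which peaks near 5 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class Hrf:
    peak_shape: float = 6.0
    peak_scale: float = 1.0
    undershoot_shape: float = 16.0
    undershoot_scale: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    dt: float = 0.05       # sampling step of the fine evaluation grid (s)
    duration: float = 32.0  # kernel support (s)

    def __post_init__(self):
        for name in ("peak_shape", "peak_scale", "undershoot_shape", "undershoot_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= self.dt:
            raise ValueError("duration must exceed dt")


def double_gamma_hrf(hrf: Hrf = Hrf()) -> tuple[np.ndarray, np.ndarray]:
    """Sample the kernel on its fine grid.

    Returns
    -------
    t : ndarray
        Time points 0, dt, 2 dt, ..., <= duration.
    h : ndarray
        Kernel values, peak-normalised to 1; h(0) = 0.
    """
    t = np.arange(0.0, hrf.duration + hrf.dt / 2, hrf.dt)
    peak = stats.gamma.pdf(t, a=hrf.peak_shape, scale=hrf.peak_scale)
    under = stats.gamma.pdf(t, a=hrf.undershoot_shape, scale=hrf.undershoot_scale)
    h = peak - hrf.undershoot_ratio * under
    h[t <= 0] = 0.0
    peak_val = np.max(np.abs(h))
    if peak_val == 0:
        raise ValueError("degenerate HRF: kernel identically zero")
    return t, h / peak_val
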