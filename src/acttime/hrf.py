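"""Canonical double-gamma hemodynamic response function."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["HrfSpec", "hrf_kernel"]


@dataclass(frozen=True)
class HrfSpec:
    """Double-gamma HRF parameters.

    The kernel is the difference of two gamma densities,
    ``g(t; peak_delay/d1, d1) - undershoot_ratio * g(t; undershoot_delay/d2, d2)``,
    scaled to unit peak.  Defaults are the conventional canonical HRF:
    6-s peak, 16-s undershoot, unit dispersions, undershoot ratio 1/6.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0

    def __post_init__(self) -> None:
        if self.duration < 24.0:
            raise ValueError("HRF kernel must cover at least 24 s")


def hrf_kernel(spec: HrfSpec, dt: float) -> np.ndarray:
    """Sample the double-gamma kernel at interval ``dt``, unit peak height."""
    t = np.arange(0.0, spec.duration + dt / 2, dt)
    peak = stats.gamma.pdf(t, spec.peak_delay / spec.peak_dispersion,
                           scale=spec.peak_dispersion)
    under = stats.gamma.pdf(t, spec.undershoot_delay / spec.undershoot_dispersion,
                            scale=spec.undershoot_dispersion)
    h = peak - spec.undershoot_ratio * under
    return h / np.max(h)
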