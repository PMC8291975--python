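"""Circular statistics for event-phase analyses.

All angles are degrees on [0, 360).  The confidence interval of the circular
mean follows the dispersion-based construction of Fisher (1993) as used in
the CircStat conventions; the Rayleigh p value uses the standard large-sample
series correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


def wrap_degrees(angles) -> np.ndarray:
    return np.asarray(angles, dtype=float) % 360.0


def resultant(angles_deg) -> tuple[float, float]:
    """Mean direction (deg) and mean resultant length R-bar."""
    a = np.deg2rad(wrap_degrees(angles_deg))
    if a.size == 0:
        raise ValueError("empty circular sample")
    z = np.exp(1j * a).mean()
    return float(np.rad2deg(np.angle(z)) % 360.0), float(np.abs(z))


@dataclass
class CircularMeanResult:
    mean_deg: float
    ci_halfwidth_deg: float  # NaN when undefined (R-bar too small)
    r: float
    n: int

    @property
    def ci_defined(self) -> bool:
        return np.isfinite(self.ci_halfwidth_deg)


def circular_mean_ci(angles_deg, confidence: float = 0.95) -> CircularMeanResult:
    """Circular mean with dispersion-based confidence interval.

    Returns the mean direction, the CI half-width in degrees (NaN, with a
    warning, when the sample is too dispersed for the interval to exist),
    the mean resultant length and n.
    """
    angles_deg = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    n = angles_deg.size
    mean_deg, rbar = resultant(angles_deg)
    if n < 2:
        return CircularMeanResult(mean_deg, np.nan, rbar, n)
    R = n * rbar
    chi2 = stats.chi2.ppf(confidence, 1)
    with np.errstate(invalid="ignore"):
        if rbar < 0.9:
            arg = np.sqrt((2.0 * n * (2.0 * R**2 - n * chi2)) / (4.0 * n - chi2))
        else:
            arg = np.sqrt(n**2 - (n**2 - R**2) * np.exp(chi2 / n))
        cos_hw = arg / R
    if not np.isfinite(cos_hw) or cos_hw > 1.0:
        warnings.warn(
            "circular mean CI undefined: sample too dispersed (R-bar ~ 0)",
            stacklevel=2,
        )
        hw = np.nan
    else:
        hw = float(np.rad2deg(np.arccos(cos_hw)))
    return CircularMeanResult(mean_deg, hw, rbar, n)


def rayleigh_test(angles_deg) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns ``(z, p)`` with ``z = n * R-bar**2`` and the series-corrected
    p value.  Warns for n < 10 where the approximation is rough.
    """
    angles_deg = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    n = angles_deg.size
    if n < 10:
        warnings.warn("Rayleigh test with n < 10: p value approximation is rough", stacklevel=2)
    _, rbar = resultant(angles_deg)
    z = n * rbar**2
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return float(z), float(min(max(p, 0.0), 1.0))
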