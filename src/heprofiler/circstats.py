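"""Circular (directional) statistics by trigonometric moments.

For angles theta_1..theta_n, the p-th trigonometric moment is
``m_p = n^-1 sum exp(i p theta)``; the mean resultant length is
``R = |m_1|`` and the mean direction ``mu = arg(m_1)``.  Derived measures
follow the standard directional-statistics definitions (Fisher 1993;
Pewsey; the conventions of the common circular-statistics toolboxes):

* circular variance  ``V = 1 - R``            (0 = concentrated, 1 = dispersed)
* circular std       ``s = sqrt(-2 ln R)``
* angular deviation  ``s0 = sqrt(2 (1 - R))``
* skewness           ``b = mean(sin(2 (theta - mu)))``
* kurtosis           ``k = mean(cos(2 (theta - mu)))``
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "resultant_length",
    "circ_mean",
    "circ_var",
    "circ_std",
    "angular_deviation",
    "circ_skewness",
    "circ_kurtosis",
]

#: Floor on R before the logarithm in circ_std, capping the statistic at a
#: large finite value for perfectly dispersed samples.
_R_FLOOR = 1e-12


def _moment(angles: np.ndarray, p: int = 1) -> complex:
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        return complex(np.nan, np.nan)
    return complex(np.mean(np.exp(1j * p * a)))


def resultant_length(angles: np.ndarray) -> float:
    """Mean resultant length R in [0, 1]."""
    return float(np.abs(_moment(angles)))


def circ_mean(angles: np.ndarray) -> float:
    """Mean direction in (-pi, pi]."""
    return float(np.angle(_moment(angles)))


def circ_var(angles: np.ndarray) -> float:
    """Circular variance 1 - R."""
    return 1.0 - resultant_length(angles)


def circ_std(angles: np.ndarray) -> float:
    """Circular standard deviation sqrt(-2 ln R)."""
    # clamp R into [floor, 1]: round-off can push it past 1 for
    # concentrated samples, and 0 would make the statistic infinite
    r = min(max(resultant_length(angles), _R_FLOOR), 1.0)
    return float(np.sqrt(-2.0 * np.log(r)))


def angular_deviation(angles: np.ndarray) -> float:
    """Angular deviation sqrt(2 (1 - R)), bounded by sqrt(2)."""
    # R can exceed 1 by float round-off for concentrated samples
    return float(np.sqrt(2.0 * max(0.0, 1.0 - resultant_length(angles))))


def circ_skewness(angles: np.ndarray) -> float:
    """Second-moment skewness about the mean direction."""
    a = np.asarray(angles, dtype=float)
    mu = circ_mean(a)
    return float(np.mean(np.sin(2.0 * (a - mu))))


def circ_kurtosis(angles: np.ndarray) -> float:
    """Second-moment kurtosis (concentration of doubled deviations)."""
    a = np.asarray(angles, dtype=float)
    mu = circ_mean(a)
    return float(np.mean(np.cos(2.0 * (a - mu))))
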