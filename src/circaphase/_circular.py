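"""Small helpers for circular quantities (phases in radians on [0, 2pi))."""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats

TWO_PI = 2.0 * np.pi
#: radians -> hours conversion factor for a 24 h cycle
HOURS_PER_RADIAN = 12.0 / np.pi


def wrap(theta):
    """Wrap angles into the half-open interval [0, 2pi).

    A tiny negative input can round to exactly 2pi under the float modulo;
    such values are mapped back to 0 to keep the interval half-open.
    """
    out = np.asarray(theta, dtype=float) % TWO_PI
    return np.where(out >= TWO_PI, 0.0, out)


def hours_to_radians(hours):
    return wrap(np.asarray(hours, dtype=float) * np.pi / 12.0)


def radians_to_hours(theta):
    return wrap(theta) * HOURS_PER_RADIAN


def phase_grid(n: int) -> np.ndarray:
    """``n`` equally spaced grid points on [0, 2pi), starting at 0."""
    return np.arange(n) * (TWO_PI / n)


def circular_mean(theta, weights=None, axis=None):
    """Weighted circular mean, wrapped to [0, 2pi).

    Ties (zero resultant) return 0.0 by convention; callers that need a
    documented tie rule handle the degenerate case themselves.
    """
    theta = np.asarray(theta, dtype=float)
    if weights is None:
        c = np.cos(theta).sum(axis=axis)
        s = np.sin(theta).sum(axis=axis)
    else:
        weights = np.asarray(weights, dtype=float)
        c = (weights * np.cos(theta)).sum(axis=axis)
        s = (weights * np.sin(theta)).sum(axis=axis)
    return wrap(np.arctan2(s, c))


def resultant_length(theta, weights=None, axis=None):
    """Mean resultant length R-bar in [0, 1]."""
    theta = np.asarray(theta, dtype=float)
    if weights is None:
        n = theta.shape[axis] if axis is not None else theta.size
        c = np.cos(theta).sum(axis=axis) / n
        s = np.sin(theta).sum(axis=axis) / n
    else:
        weights = np.asarray(weights, dtype=float)
        tot = weights.sum(axis=axis)
        c = (weights * np.cos(theta)).sum(axis=axis) / tot
        s = (weights * np.sin(theta)).sum(axis=axis) / tot
    return np.hypot(c, s)


def kappa_from_resultant(rbar):
    """Approximate the von Mises concentration with mean resultant length ``rbar``.

    Best-practice piecewise approximation (Fisher, Statistical Analysis of
    Circular Data, 1993, sec. 4.5.5). Vectorized; rbar >= 1 maps to a large
    finite concentration.
    """
    rbar = np.clip(np.asarray(rbar, dtype=float), 0.0, 1.0 - 1e-12)
    small = rbar < 0.53
    mid = (rbar >= 0.53) & (rbar < 0.85)
    kappa = np.empty_like(rbar)
    r = rbar[small]
    kappa[small] = 2 * r + r**3 + 5 * r**5 / 6
    r = rbar[mid]
    kappa[mid] = -0.4 + 1.39 * r + 0.43 / (1 - r)
    r = rbar[~small & ~mid]
    kappa[~small & ~mid] = 1 / (r**3 - 4 * r**2 + 3 * r)
    return kappa


def vonmises_logpdf(theta, loc, kappa):
    """log density of the von Mises distribution on the circle."""
    theta = np.asarray(theta, dtype=float)
    return kappa * np.cos(theta - loc) - np.log(TWO_PI) - np.log(special.ive(0, kappa)) - kappa


def vonmises_kappa_for_interval(halfwidth: float, mass: float = 0.95) -> float:
    """Concentration whose central interval of half-width ``halfwidth`` holds ``mass``.

    Used to translate prior statements like "the width of the 95% interval is
    4 h" into a von Mises concentration (4 h width -> halfwidth pi/6 rad).
    """
    if not 0 < halfwidth < np.pi:
        raise ValueError("halfwidth must be in (0, pi)")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")

    def deficit(log_kappa):
        kappa = np.exp(log_kappa)
        return stats.vonmises(kappa).cdf(halfwidth) - stats.vonmises(kappa).cdf(-halfwidth) - mass

    sol = optimize.brentq(deficit, -10.0, 15.0)
    return float(np.exp(sol))
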