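"""Bracketed root-finding helpers for profile estimators and intervals.

All heterogeneity statistics used here (corrected Cochran Q, Breslow-Day)
are continuous and, on well-behaved data, monotone non-increasing in rho,
so estimating equations are solved by Brent's method on the admissible
range with explicit boundary handling.
"""

from __future__ import annotations

from typing import Callable

from scipy.optimize import brentq

from .results import ProfileInterval

EPS = 1e-8
XTOL = 1e-10

__all__ = ["solve_decreasing", "invert_band", "EPS", "XTOL"]


def solve_decreasing(
    stat: Callable[[float], float],
    target: float,
    lo: float,
    hi: float = 1.0,
) -> tuple[float, bool]:
    """Solve ``stat(rho) == target`` for a non-increasing ``stat``.

    Returns ``(rho, at_boundary)``.  If the statistic is already below the
    target at the lower end of the admissible range there is no crossing
    from above and the lower boundary is returned flagged; symmetrically
    for the upper end.
    """
    a, b = lo + EPS, hi - EPS
    fa = stat(a) - target
    fb = stat(b) - target
    if fa < 0:
        return lo, True
    if fb > 0:
        return hi, True
    root = brentq(lambda r: stat(r) - target, a, b, xtol=XTOL)
    return float(root), False


def invert_band(
    stat: Callable[[float], float],
    q_low: Callable[[float], float],
    q_high: Callable[[float], float],
    lo: float,
    hi: float,
    level: float,
) -> ProfileInterval:
    """Confidence set ``{rho : q_low(rho) <= stat(rho) <= q_high(rho)}``.

    ``stat`` is assumed non-increasing and the quantile functions slowly
    varying, so the set is an interval; endpoints are found by Brent's
    method, truncated to ``(lo, hi)`` with flags.
    """
    a, b = lo + EPS, hi - EPS
    top_a = stat(a) - q_high(a)
    bot_b = stat(b) - q_low(b)
    if stat(a) - q_low(a) < 0 or stat(b) - q_high(b) > 0:
        # whole curve below the lower quantile, or above the upper one
        return ProfileInterval(
            float("nan"), float("nan"), level, empty=True
        )
    if top_a <= 0:
        low, low_tr = lo, True
    else:
        low = float(brentq(lambda r: stat(r) - q_high(r), a, b, xtol=XTOL))
        low_tr = False
    if bot_b >= 0:
        high, high_tr = hi, True
    else:
        high = float(brentq(lambda r: stat(r) - q_low(r), a, b, xtol=XTOL))
        high_tr = False
    return ProfileInterval(low, high, level, low_tr, high_tr)
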