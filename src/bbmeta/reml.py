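"""Restricted maximum likelihood estimation of the intra-class correlation.

Works with the normal approximation to the per-study log-odds-ratios under
the multiplicative overdispersion model: theta_hat_j ~ N(theta,
sigma_j^2 (1 + a_j rho)).  The restricted log-likelihood (dropping
constants) is

    l_R(rho, theta) = -1/2 log(sum w*_j) - 1/2 sum w*_j (theta_hat_j - theta)^2
                      + 1/2 sum log(w*_j),

with w*_j = w_j / (1 + a_j rho).  The mean profiles out analytically as the
weighted average, leaving a one-dimensional problem in rho; the stationarity
condition in rho is solved on the admissible range.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

from ._roots import EPS, XTOL
from .effects import EffectTable, admissible_rho_range
from .results import ICCResult, ProfileInterval

__all__ = ["restricted_loglik", "profile_loglik", "rho_reml", "ci_reml_profile"]


def restricted_loglik(effects: EffectTable, rho: float, theta: float) -> float:
    w = effects.weights_fem / (1.0 + effects.a * rho)
    resid = effects.theta - theta
    return float(
        -0.5 * np.log(np.sum(w))
        - 0.5 * np.sum(w * resid**2)
        + 0.5 * np.sum(np.log(w))
    )


def profile_loglik(effects: EffectTable, rho: float) -> float:
    """Restricted log-likelihood with theta profiled out analytically."""
    w = effects.weights_fem / (1.0 + effects.a * rho)
    theta = float(np.sum(w * effects.theta) / np.sum(w))
    return restricted_loglik(effects, rho, theta)


def _score(effects: EffectTable, rho: float) -> float:
    """Derivative of the profiled restricted log-likelihood (x2).

    Zero of this function is the REML stationarity condition: the weighted
    average of a_j/(1+a_j rho) under w*-weights, plus the weighted residual
    term, balances the unweighted sum.
    """
    w = effects.weights_fem / (1.0 + effects.a * rho)
    g = effects.a / (1.0 + effects.a * rho)
    theta = float(np.sum(w * effects.theta) / np.sum(w))
    resid2 = (effects.theta - theta) ** 2
    return float(
        np.sum(w * g) / np.sum(w) + np.sum(w * resid2 * g) - np.sum(g)
    )


def rho_reml(effects: EffectTable, max_iter: int = 500) -> ICCResult:
    """REML point estimate of rho.

    Solves the stationarity condition on the admissible range; when the
    condition has no interior root the likelihood is monotone and the
    better boundary is returned flagged.
    """
    lo, hi = admissible_rho_range(effects)
    a, b = lo + EPS, hi - EPS
    fa, fb = _score(effects, a), _score(effects, b)
    if fa <= 0 and fb <= 0:
        # decreasing likelihood throughout: boundary solution at rho_min
        return ICCResult(method="REML", rho=lo, at_boundary=True)
    if fa >= 0 and fb >= 0:
        return ICCResult(method="REML", rho=hi, at_boundary=True)
    if fa < 0 < fb:
        # interior stationary point is a minimum; pick the better boundary
        better = lo if profile_loglik(effects, a) >= profile_loglik(effects, b) else hi
        return ICCResult(method="REML", rho=better, at_boundary=True)
    rho = float(brentq(lambda r: _score(effects, r), a, b, xtol=XTOL, maxiter=max_iter))
    return ICCResult(method="REML", rho=rho, at_boundary=False)


def ci_reml_profile(effects: EffectTable, level: float = 0.95) -> ProfileInterval:
    """Profile-likelihood CI: all rho within the chi-square(1) drop of l_R."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    est = rho_reml(effects)
    lo, hi = admissible_rho_range(effects)
    a, b = lo + EPS, hi - EPS
    cut = profile_loglik(effects, est.rho) - chi2.ppf(level, 1) / 2.0
    f = lambda r: profile_loglik(effects, r) - cut

    if est.rho <= a or f(a) >= 0:
        low, low_tr = lo, True
    else:
        low = float(brentq(f, a, est.rho, xtol=XTOL))
        low_tr = False
    if est.rho >= b or f(b) >= 0:
        high, high_tr = hi, True
    else:
        high = float(brentq(f, est.rho, b, xtol=XTOL))
        high_tr = False
    return ProfileInterval(low, high, level, low_tr, high_tr)
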