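"""Cochran's Q machinery and Q-based estimators of the intra-class correlation.

Cochran's statistic with fixed-effect inverse-variance weights ``w_j``,

    Q = sum_j w_j (theta_j - theta_bar_w)^2,

is the classical heterogeneity statistic for log-odds-ratios.  Under the
multiplicative overdispersion model the correct weights at intra-class
correlation ``rho`` are ``w*_j = w_j / (1 + a_j rho)``; the corrected
statistic ``Q*(rho)`` built with those weights is approximately
chi-square(K-1) when rho is the true value.  Three point estimators follow:

* ``rho_moment`` — closed-form moment estimator equating Q to its
  overdispersion-model mean ``K - 1 + (K a_bar - a_bar_w) rho``;
* ``rho_mandel_paule`` — root of ``Q*(rho) = K - 1``;
* ``rho_corrected_mp`` — root of ``Q*(rho) = E(Q)``, where ``E(Q)`` comes
  from a gamma approximation to the distribution of Q that corrects the
  notoriously poor chi-square approximation for log-odds-ratios.

Profile confidence intervals invert the chi-square or gamma band for
``Q*(rho)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from scipy.stats import binom, chi2, gamma as gamma_dist

from ._roots import EPS, invert_band, solve_decreasing
from .effects import EffectTable, admissible_rho_range
from .results import ICCResult, ProfileInterval

__all__ = [
    "cochran_q",
    "expected_q_odm",
    "rho_moment",
    "rho_mandel_paule",
    "rho_corrected_mp",
    "ci_q_profile",
    "ci_gamma_profile",
    "GammaApproxParams",
    "gamma_approx_params",
    "EthProvider",
    "NullEth",
    "ExactMomentsEth",
    "DEFAULT_ETH",
    "GammaApproxError",
    "DegenerateDenominatorError",
]


class DegenerateDenominatorError(ValueError):
    """Moment-estimator denominator K*a_bar - a_bar_w is not positive."""


class GammaApproxError(ValueError):
    """The gamma approximation to Q broke down (non-positive variance)."""


def cochran_q(effects: EffectTable, rho: float = 0.0) -> float:
    """Corrected Cochran statistic Q*(rho); ``rho=0`` gives the plain Q."""
    w = effects.weights_fem / (1.0 + effects.a * rho)
    tbar = float(np.sum(w * effects.theta) / np.sum(w))
    return float(np.sum(w * (effects.theta - tbar) ** 2))


def expected_q_odm(effects: EffectTable, rho: float) -> float:
    """Mean of Q under the overdispersion model: K-1 + (K a_bar - a_bar_w) rho."""
    K = effects.K
    w = effects.weights_fem
    abar = float(np.mean(effects.a))
    abar_w = float(np.sum(w * effects.a) / np.sum(w))
    return K - 1 + (K * abar - abar_w) * rho


def rho_moment(effects: EffectTable, truncate_at_zero: bool = False) -> ICCResult:
    """Closed-form moment estimator of rho from Cochran's Q.

    Negative values (Q < K-1 suggests underdispersion) are kept unless
    ``truncate_at_zero``; the estimate is floored at ``-1/max(a_j)``.
    """
    K = effects.K
    w = effects.weights_fem
    abar = float(np.mean(effects.a))
    abar_w = float(np.sum(w * effects.a) / np.sum(w))
    denom = K * abar - abar_w
    if denom <= 0:
        raise DegenerateDenominatorError(
            f"K*a_bar - a_bar_w = {denom:.6g} <= 0; the moment equation has "
            "no usable slope (all studies may be of minimal size)"
        )
    q = cochran_q(effects, 0.0)
    raw = (q - (K - 1)) / denom
    floor = -1.0 / float(np.max(effects.a))
    rho = max(raw, floor)
    at_boundary = raw < floor
    if truncate_at_zero and rho < 0.0:
        rho, at_boundary = 0.0, True
    return ICCResult(method="M", rho=float(rho), at_boundary=at_boundary)


def rho_mandel_paule(effects: EffectTable) -> ICCResult:
    """Mandel-Paule estimator: root of Q*(rho) = K - 1."""
    lo, hi = admissible_rho_range(effects)
    rho, at_boundary = solve_decreasing(
        lambda r: cochran_q(effects, r), effects.K - 1, lo, hi
    )
    return ICCResult(method="MP", rho=rho, at_boundary=at_boundary)


# ---------------------------------------------------------------------------
# theoretical mean of Q for log-odds-ratios


@runtime_checkable
class EthProvider(Protocol):
    """Provider of the theoretical approximation to E(Q) for LOR.

    ``uses_weights`` declares whether the provider depends on the
    rho-corrected weights; providers here do not, so gamma parameters are
    computed once at the null fit and held fixed along profile curves.
    """

    uses_weights: bool

    def __call__(self, effects: EffectTable) -> float: ...


class NullEth:
    """Trivial provider returning the chi-square mean K - 1."""

    uses_weights = False

    def __call__(self, effects: EffectTable) -> float:
        return float(effects.K - 1)


class ExactMomentsEth:
    """Theoretical E(Q) for LOR from exact per-study binomial moments.

    Because Q uses *estimated* inverse-variance weights, its null mean
    deviates from K-1, badly so for probabilities far from one half.  This
    provider fits the null (common LOR from the fixed-effect estimate,
    control probabilities from the data), computes per-study joint moments
    of the weight and the effect error exactly by enumerating the two
    binomial supports, and combines them through a second-order expansion
    of the weighted-mean term of Q.  Zero cells inside the enumeration get
    the 0.5 continuity correction on all four cells, mirroring the effects
    module.
    """

    uses_weights = False

    def __init__(self, support_tol: float = 1e-13):
        self.support_tol = support_tol

    def _arm(self, n: int, p: float):
        xs = np.arange(n + 1)
        pmf = binom.pmf(xs, n, p)
        keep = pmf > self.support_tol
        xs, pmf = xs[keep], pmf[keep]
        interior = (xs > 0) & (xs < n)
        safe_x = np.maximum(xs, 1)
        safe_nx = np.maximum(n - xs, 1)
        l_raw = np.where(interior, np.log(safe_x / safe_nx), 0.0)
        v_raw = np.where(interior, 1 / safe_x + 1 / safe_nx, np.inf)
        l_cor = np.log((xs + 0.5) / (n - xs + 0.5))
        v_cor = 1 / (xs + 0.5) + 1 / (n - xs + 0.5)
        return pmf, l_raw, v_raw, l_cor, v_cor, ~interior

    def _study_moments(self, n1: int, n2: int, p1: float, p2: float, theta0: float):
        f1, l1, v1, l1c, v1c, b1 = self._arm(n1, p1)
        f2, l2, v2, l2c, v2c, b2 = self._arm(n2, p2)
        P = np.outer(f1, f2)
        P /= P.sum()
        mask = b1[:, None] | b2[None, :]
        L = np.where(mask, l1c[:, None] - l2c[None, :], l1[:, None] - l2[None, :])
        V = np.where(mask, v1c[:, None] + v2c[None, :], v1[:, None] + v2[None, :])
        u = L - theta0
        W = 1.0 / V
        ex = lambda g: float(np.sum(P * g))
        return (
            ex(W),
            ex(W * W),
            ex(W * u),
            ex(W * u * u),
            ex(W * W * u),
            ex(W * W * u * u),
            ex(W * W * W * u * u),
        )

    def __call__(self, effects: EffectTable) -> float:
        w = effects.weights_fem
        theta0 = float(np.sum(w * effects.theta) / np.sum(w))
        e0 = np.exp(theta0)
        p2 = effects.x2 / effects.n2
        p1 = p2 * e0 / (1 - p2 + p2 * e0)
        # enumeration needs integer supports; corrected tables in the
        # effects step only shift counts by 0.5, so round the sizes back
        n1 = np.rint(effects.n1 - effects.corrected).astype(int)
        n2 = np.rint(effects.n2 - effects.corrected).astype(int)
        mom = np.array(
            [
                self._study_moments(int(a), int(b), float(c), float(d), theta0)
                for a, b, c, d in zip(n1, n2, p1, p2)
            ]
        )
        w1, w2, m1, m2, b2u, a2, a3 = mom.T
        mu = w1.sum()
        var_w = (w2 - w1**2).sum()
        et2 = a2.sum() + m1.sum() ** 2 - (m1**2).sum()
        c_same = a3 - w1 * a2
        b_same = b2u - w1 * m1
        et2d = c_same.sum() + 2 * (b_same.sum() * m1.sum() - (b_same * m1).sum())
        return float(m2.sum() - (et2 / mu - et2d / mu**2 + et2 * var_w / mu**3))


DEFAULT_ETH: EthProvider = ExactMomentsEth()


@dataclass(frozen=True)
class GammaApproxParams:
    """Moments and gamma parameters approximating the distribution of Q."""

    mean_q: float
    var_q: float

    @property
    def shape(self) -> float:
        return self.mean_q**2 / self.var_q

    @property
    def scale(self) -> float:
        return self.var_q / self.mean_q


def gamma_approx_params(
    effects: EffectTable,
    rho: float = 0.0,
    provider: EthProvider = DEFAULT_ETH,
) -> GammaApproxParams:
    """Gamma-approximation parameters for the distribution of Q.

    The mean is the theoretical provider value shrunk toward K-1 with the
    empirical coefficient 0.678; the variance follows the companion
    quadratic ``4.74(K-1) - 12.17 E(Q) + 9.42 E(Q)^2/(K-1)``.
    """
    del rho  # providers here do not consume rho-corrected weights
    K = effects.K
    eth = provider(effects)
    mean_q = (K - 1) - 0.678 * ((K - 1) - eth)
    var_q = 4.74 * (K - 1) - 12.17 * mean_q + 9.42 * mean_q**2 / (K - 1)
    if var_q <= 0 or mean_q <= 0:
        raise GammaApproxError(
            f"gamma approximation broke down: K={K}, E(Q)={mean_q:.6g}, "
            f"Var(Q)={var_q:.6g}"
        )
    return GammaApproxParams(mean_q=float(mean_q), var_q=float(var_q))


def rho_corrected_mp(
    effects: EffectTable,
    provider: EthProvider = DEFAULT_ETH,
) -> ICCResult:
    """Corrected Mandel-Paule estimator: root of Q*(rho) = E(Q)."""
    params = gamma_approx_params(effects, provider=provider)
    lo, hi = admissible_rho_range(effects)
    rho, at_boundary = solve_decreasing(
        lambda r: cochran_q(effects, r), params.mean_q, lo, hi
    )
    return ICCResult(
        method="cMP",
        rho=rho,
        at_boundary=at_boundary,
        meta={"gamma_params": params},
    )


def ci_q_profile(effects: EffectTable, level: float = 0.95) -> ProfileInterval:
    """Profile CI for rho inverting the chi-square band on Q*(rho)."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    K = effects.K
    alpha = 1 - level
    lo, hi = admissible_rho_range(effects)
    q_lo = chi2.ppf(alpha / 2, K - 1)
    q_hi = chi2.ppf(1 - alpha / 2, K - 1)
    return invert_band(
        lambda r: cochran_q(effects, r),
        lambda r: q_lo,
        lambda r: q_hi,
        lo,
        hi,
        level,
    )


def ci_gamma_profile(
    effects: EffectTable,
    level: float = 0.95,
    provider: EthProvider = DEFAULT_ETH,
) -> ProfileInterval:
    """Profile CI for rho inverting the gamma band on Q*(rho).

    Same construction as :func:`ci_q_profile` with gamma quantiles.  With
    the default provider the gamma parameters do not depend on the
    rho-corrected weights and are held fixed along the profile; this is
    recorded in the interval metadata.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    params = gamma_approx_params(effects, provider=provider)
    alpha = 1 - level
    lo, hi = admissible_rho_range(effects)
    g_lo = gamma_dist.ppf(alpha / 2, params.shape, scale=params.scale)
    g_hi = gamma_dist.ppf(1 - alpha / 2, params.shape, scale=params.scale)
    interval = invert_band(
        lambda r: cochran_q(effects, r),
        lambda r: g_lo,
        lambda r: g_hi,
        lo,
        hi,
        level,
    )
    interval.meta["gamma_params"] = params
    interval.meta["quantiles_fixed_at_null"] = not provider.uses_weights
    return interval
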