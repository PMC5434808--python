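"""Mantel-Haenszel pooling and the overdispersion-corrected Breslow-Day test.

The Breslow-Day statistic compares each study's treatment-arm event count
with its expectation under a common odds ratio (the Mantel-Haenszel
estimate), scaled by the asymptotic variance of that count.  Under
beta-binomial overdispersion the four cell contributions to the inverse
variance are deflated by the arm design effects ``C_ij = 1 + (n_ij - 1) rho``,
making the statistic a decreasing function of rho.  Equating it to its
chi-square mean K-1 yields a Mandel-Paule-type estimator of rho, and
inverting the chi-square band yields a profile confidence interval.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2, norm

from ._roots import EPS, invert_band, solve_decreasing
from .data import MetaDataset, Study2x2
from .results import ICCResult, PooledResult, ProfileInterval

__all__ = [
    "mh_pooled_or",
    "bd_expected_count",
    "bd_statistic",
    "rho_breslow_day",
    "ci_bd_profile",
    "bd_admissible_range",
    "DegenerateMHError",
]


class DegenerateMHError(ZeroDivisionError, ValueError):
    """Mantel-Haenszel denominator sum is zero."""


def mh_pooled_or(data: MetaDataset, level: float = 0.95) -> PooledResult:
    """Mantel-Haenszel pooled odds ratio with Robins-Breslow-Greenland CI.

    Zero cells are handled natively (no continuity correction): studies
    contribute zero to the numerator or denominator sums.
    """
    x1, n1, x2, n2 = data.x1, data.n1, data.x2, data.n2
    N = n1 + n2
    num = np.sum(x1 * (n2 - x2) / N)
    den = np.sum(x2 * (n1 - x1) / N)
    if den == 0 or num == 0:
        raise DegenerateMHError(
            "Mantel-Haenszel estimator degenerate: a marginal sum is zero"
        )
    psi = float(num / den)
    # Robins-Breslow-Greenland variance of log(psi_MH)
    P = (n2 - x2 + x1) / N
    Q = (n1 - x1 + x2) / N
    R = x1 * (n2 - x2) / N
    S = x2 * (n1 - x1) / N
    Rs, Ss = R.sum(), S.sum()
    var = (
        np.sum(P * R) / (2 * Rs**2)
        + np.sum(P * S + Q * R) / (2 * Rs * Ss)
        + np.sum(Q * S) / (2 * Ss**2)
    )
    se = float(np.sqrt(var))
    z = norm.ppf(0.5 + level / 2)
    theta = float(np.log(psi))
    return PooledResult(
        pool_method="MH",
        icc_method=None,
        theta=theta,
        se=se,
        ci_low=theta - z * se,
        ci_high=theta + z * se,
        level=level,
    )


def bd_expected_count(study: Study2x2, psi: float) -> float:
    """Expected treatment-arm events under a common odds ratio ``psi``.

    The admissible root of the quadratic

        E (N - m1 - n1 + E) / ((m1 - E)(n1 - E)) = psi,

    with event margin ``m1 = x1 + x2``, lying strictly inside
    ``(max(0, m1 - n2), min(n1, m1))``.
    """
    if psi <= 0:
        raise ValueError("psi must be positive")
    return float(
        _expected_counts(
            np.array([study.x1], float),
            np.array([study.n1], float),
            np.array([study.x2], float),
            np.array([study.n2], float),
            psi,
        )[0]
    )


def _expected_counts(x1, n1, x2, n2, psi):
    """Vectorized quadratic solve for the expected counts (interior roots)."""
    N = n1 + n2
    m1 = x1 + x2
    lo = np.maximum(0.0, m1 - n2)
    hi = np.minimum(n1, m1)
    A = 1.0 - psi
    B = (N - m1 - n1) + psi * (m1 + n1)
    C = -psi * m1 * n1
    if abs(A) < 1e-12:
        return -C / B  # psi = 1: hypergeometric mean n1 m1 / N
    disc = np.sqrt(B * B - 4 * A * C)
    r1 = (-B + disc) / (2 * A)
    r2 = (-B - disc) / (2 * A)
    in1 = (r1 > lo) & (r1 < hi)
    in2 = (r2 > lo) & (r2 < hi)
    # when both qualify numerically, pick the smaller defining-equation residual
    def resid(E):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.abs(E * (N - m1 - n1 + E) - psi * (m1 - E) * (n1 - E))
    E = np.where(in1 & ~in2, r1, np.where(in2 & ~in1, r2,
                 np.where(resid(r1) <= resid(r2), r1, r2)))
    if not np.all((E > lo) & (E < hi)):
        j = int(np.argmax(~((E > lo) & (E < hi))))
        raise AssertionError(
            f"no admissible root of the expected-count quadratic for "
            f"study index {j} (psi={psi:.6g})"
        )
    return E


def _bd_terms(data: MetaDataset):
    """Counts entering the BD statistic, with the per-study 0.5 correction.

    The asymptotic variance is undefined when a table has an empty cell;
    those studies get 0.5 added to each cell (and hence to the margins) for
    the BD computation only.  The MH odds ratio is computed on the raw
    counts, which it handles natively.
    """
    psi = mh_pooled_or(data).psi
    x1, n1, x2, n2 = data.x1, data.n1, data.x2, data.n2
    zero = np.array([s.has_zero_cell() for s in data])
    c = np.where(zero, 0.5, 0.0)
    x1, x2, n1, n2 = x1 + c, x2 + c, n1 + 2 * c, n2 + 2 * c
    E = _expected_counts(x1, n1, x2, n2, psi)
    return x1, n1, x2, n2, E, psi


def bd_statistic(data: MetaDataset, rho: float = 0.0) -> float:
    """Breslow-Day homogeneity statistic, corrected for overdispersion.

    ``rho = 0`` gives the classical Breslow-Day statistic.
    """
    x1, n1, x2, n2, E, _ = _bd_terms(data)
    return _bd_statistic_from_terms(x1, n1, x2, n2, E, rho, data)


def _bd_statistic_from_terms(x1, n1, x2, n2, E, rho, data):
    N = n1 + n2
    m1 = x1 + x2
    C1 = 1 + (n1 - 1) * rho
    C2 = 1 + (n2 - 1) * rho
    inv_var = (
        1 / (E * C1)
        + 1 / ((m1 - E) * C2)
        + 1 / ((n1 - E) * C1)
        + 1 / ((N - m1 - n1 + E) * C2)
    )
    var = 1.0 / inv_var
    if np.any(var <= 0) or np.any(~np.isfinite(var)):
        j = int(np.argmax((var <= 0) | ~np.isfinite(var)))
        raise ValueError(
            f"non-positive Breslow-Day variance for study "
            f"{data.ids[j]!r} at rho={rho}"
        )
    return float(np.sum((x1 - E) ** 2 / var))


def bd_admissible_range(data: MetaDataset) -> tuple[float, float]:
    """Admissible rho interval: (max(-1/a_max, -1/(max n_ij - 1)), 1)."""
    from .effects import admissible_rho_range, study_effects

    lo, hi = admissible_rho_range(study_effects(data))
    return lo, hi


def rho_breslow_day(data: MetaDataset) -> ICCResult:
    """Breslow-Day-based estimator: root of X2_BD(rho) = K - 1.

    The statistic decreases in rho and attains its lower limit at rho = 1;
    if even that exceeds K-1 the estimate is set to 1 and flagged.  When
    X2_BD(0) < K-1 the root is negative (underdispersion).
    """
    lo, hi = bd_admissible_range(data)
    x1, n1, x2, n2, E, _ = _bd_terms(data)
    stat = lambda r: _bd_statistic_from_terms(x1, n1, x2, n2, E, r, data)
    rho, at_boundary = solve_decreasing(stat, data.K - 1, lo, hi)
    return ICCResult(method="BD", rho=rho, at_boundary=at_boundary)


def ci_bd_profile(data: MetaDataset, level: float = 0.95) -> ProfileInterval:
    """Profile CI for rho inverting the chi-square band on X2_BD(rho)."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    K = data.K
    alpha = 1 - level
    lo, hi = bd_admissible_range(data)
    x1, n1, x2, n2, E, _ = _bd_terms(data)
    stat = lambda r: _bd_statistic_from_terms(x1, n1, x2, n2, E, r, data)
    q_lo = chi2.ppf(alpha / 2, K - 1)
    q_hi = chi2.ppf(1 - alpha / 2, K - 1)
    return invert_band(stat, lambda r: q_lo, lambda r: q_hi, lo, hi, level)
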