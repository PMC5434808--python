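"""Per-study effect measures and their variances under overdispersion.

For study ``j`` with event counts ``x_ij`` out of ``n_ij`` (i = 1 treatment,
2 control), the effect measure is the log-odds-ratio

    theta_j = log psi_j,   psi_j = x1 (n2 - x2) / (x2 (n1 - x1)).

Under independent binomial sampling, the delta-method variance of theta_j is
``1/x1 + 1/(n1-x1) + 1/x2 + 1/(n2-x2)``.  When the counts in each arm are
beta-binomial with intra-class correlation ``rho``, each arm's contribution is
inflated by the design effect ``1 + (n - 1) rho``:

    Var(theta_j) = [1+(n1-1)rho]/(n1 p1 q1) + [1+(n2-1)rho]/(n2 p2 q2).

The same variance can be written in the multiplicative overdispersion form
``(v_j / N_j) (1 + a_j rho)`` where ``v_j/N_j`` is the binomial (fixed-effect)
variance and ``a_j`` grows linearly with the study size ``N_j``
(``a_j = N_j/2 - 1`` for balanced studies).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .data import MetaDataset

__all__ = [
    "EffectTable",
    "CorrectionRule",
    "study_effects",
    "bb_variance",
    "odm_coefficients",
    "design_effects",
    "tau2_equivalent",
    "admissible_rho_range",
    "RhoDomainError",
]

CorrectionRule = Literal["only-zero", "always", "never"]


class RhoDomainError(ValueError):
    """rho outside the admissible range for some study."""


@dataclass(frozen=True)
class EffectTable:
    """Per-study derived quantities, in original study order.

    Counts are stored *after* the continuity-correction rule has been
    applied, so every downstream formula uses one consistent set of
    proportions.
    """

    ids: tuple[str, ...]
    x1: np.ndarray
    n1: np.ndarray
    x2: np.ndarray
    n2: np.ndarray
    psi: np.ndarray
    theta: np.ndarray
    var_fem: np.ndarray
    p1_hat: np.ndarray
    p2_hat: np.ndarray
    N: np.ndarray
    R: np.ndarray  # allocation ratio n1/n2
    v: np.ndarray  # FEM variance scale: var_fem = v / N
    a: np.ndarray  # overdispersion inflation coefficient
    corrected: np.ndarray  # bool, 0.5 correction applied

    @property
    def K(self) -> int:
        return len(self.ids)

    @property
    def weights_fem(self) -> np.ndarray:
        return 1.0 / self.var_fem

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study_id": list(self.ids),
                "x1": self.x1,
                "n1": self.n1,
                "x2": self.x2,
                "n2": self.n2,
                "psi": self.psi,
                "theta": self.theta,
                "var_fem": self.var_fem,
                "p1_hat": self.p1_hat,
                "p2_hat": self.p2_hat,
                "N": self.N,
                "R": self.R,
                "v": self.v,
                "a": self.a,
                "corrected": self.corrected,
            }
        )


def study_effects(
    data: MetaDataset,
    correction: CorrectionRule = "only-zero",
    add: float = 0.5,
) -> EffectTable:
    """Compute the per-study effect table.

    ``correction`` controls the continuity correction: ``"only-zero"``
    (default) adds ``add`` to all four cells of a study if and only if that
    study has an empty cell; ``"always"`` corrects every study;
    ``"never"`` leaves counts untouched (zero cells then yield infinite
    variances).
    """
    x1, n1, x2, n2 = data.x1, data.n1, data.x2, data.n2
    zero = np.array([s.has_zero_cell() for s in data])
    if correction == "always":
        fire = np.ones(data.K, dtype=bool)
    elif correction == "never":
        fire = np.zeros(data.K, dtype=bool)
    elif correction == "only-zero":
        fire = zero
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown correction rule {correction!r}")

    c = np.where(fire, add, 0.0)
    x1 = x1 + c
    x2 = x2 + c
    n1 = n1 + 2 * c
    n2 = n2 + 2 * c

    with np.errstate(divide="ignore", invalid="ignore"):
        psi = x1 * (n2 - x2) / (x2 * (n1 - x1))
        theta = np.log(psi)
        var_fem = 1 / x1 + 1 / x2 + 1 / (n1 - x1) + 1 / (n2 - x2)
        p1 = x1 / n1
        p2 = x2 / n2
        N = n1 + n2
        R = n1 / n2
        # t_i = 1/(p_i q_i): per-arm variance scale for one observation
        t1 = 1 / (p1 * (1 - p1))
        t2 = 1 / (p2 * (1 - p2))
        v = (R + 1) * (t1 / R + t2)
        # a solves var_fem * (1 + a*rho) == bb_variance(rho) identically
        a = (t1 + t2) / (t1 / n1 + t2 / n2) - 1

    return EffectTable(
        ids=tuple(data.ids),
        x1=x1,
        n1=n1,
        x2=x2,
        n2=n2,
        psi=psi,
        theta=theta,
        var_fem=var_fem,
        p1_hat=p1,
        p2_hat=p2,
        N=N,
        R=R,
        v=v,
        a=a,
        corrected=fire,
    )


def _per_study_lower(n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lo1 = np.where(n1 > 1, -1 / (n1 - 1), -np.inf)
        lo2 = np.where(n2 > 1, -1 / (n2 - 1), -np.inf)
    return np.maximum(lo1, lo2)


def _check_rho(effects: EffectTable, rho: float) -> None:
    lo = _per_study_lower(effects.n1, effects.n2)
    if rho <= lo.max():
        j = int(np.argmax(lo))  # the binding (most restrictive) study
        raise RhoDomainError(
            f"rho={rho} not admissible: study {effects.ids[j]!r} requires "
            f"rho > {lo[j]:.6g}"
        )


def bb_variance(effects: EffectTable, rho: float) -> np.ndarray:
    """Beta-binomial (design-effect inflated) variance of each study's LOR."""
    _check_rho(effects, rho)
    n1, n2 = effects.n1, effects.n2
    p1, p2 = effects.p1_hat, effects.p2_hat
    return (1 + (n1 - 1) * rho) / (n1 * p1 * (1 - p1)) + (
        1 + (n2 - 1) * rho
    ) / (n2 * p2 * (1 - p2))


def odm_coefficients(effects: EffectTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-study ``(v_j, a_j)`` of the multiplicative overdispersion model.

    Satisfies ``(v_j / N_j) (1 + a_j rho) == bb_variance(effects, rho)``
    for every admissible rho.
    """
    return effects.v, effects.a


def design_effects(data: MetaDataset, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Variance-inflation factors ``C_ij = 1 + (n_ij - 1) rho`` per arm."""
    n1, n2 = data.n1, data.n2
    lo = _per_study_lower(n1, n2)
    if rho <= lo.max():
        j = int(np.argmax(lo))
        raise RhoDomainError(
            f"rho={rho} not admissible: study {data.ids[j]!r} requires "
            f"rho > {lo[j]:.6g}"
        )
    return 1 + (n1 - 1) * rho, 1 + (n2 - 1) * rho


def tau2_equivalent(p1, p2, n1, n2, rho):
    """Additive between-study variance with the same first two LOR moments.

    Maps the intra-class correlation onto the tau^2 scale of the standard
    additive random-effects model (valid when probabilities and sizes are
    shared across studies).
    """
    return (
        (n1 - 1) / (n1 * p1 * (1 - p1)) + (n2 - 1) / (n2 * p2 * (1 - p2))
    ) * rho


def admissible_rho_range(effects: EffectTable) -> tuple[float, float]:
    """Dataset-wide open interval of admissible rho values.

    Lower bound ``max(-1/max(a_j), -1/(max(n_ij) - 1))``; upper bound 1.
    """
    n_max = float(np.max(np.r_[effects.n1, effects.n2]))
    lo = -1.0 / (n_max - 1.0)
    a_max = float(np.max(effects.a))
    if a_max > 0:
        lo = max(lo, -1.0 / a_max)
    return lo, 1.0
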