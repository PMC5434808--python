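"""Beta-binomial meta-analysis simulator and bias/coverage experiment runner.

Each simulated meta-analysis draws K studies with equal arm sizes
``n_j ~ round(Normal(n, n/4))`` left-truncated at 5, control-arm counts
``X_2j ~ BetaBinomial(n_j, p2, rho)`` and treatment-arm counts with the
probability implied by the common log-odds-ratio theta,
``p1 = p2 e^theta / (1 - p2 + p2 e^theta)``.  Beta-binomial draws use the
conjugate construction: ``p ~ Beta(pi s, (1 - pi) s)`` with
``s = 1/rho - 1`` then ``X ~ Binomial(n, p)``, which has mean ``n pi`` and
variance ``n pi (1 - pi) (1 + (n - 1) rho)`` exactly; ``rho = 0`` draws
plain binomials.

The experiment runner estimates rho by any subset of the five methods (with
profile CIs), pools the odds ratio by inverse-variance and/or corrected
Mantel-Haenszel at each estimate, and aggregates bias and coverage with
Monte Carlo standard errors.  Randomness is fully determined by a master
seed with per-cell, per-replicate substreams, so cells can be run in any
order or in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import MetaDataset, Study2x2
from .effects import study_effects
from .pooling import (
    ICC_METHODS,
    POOL_METHODS,
    _icc_with_ci,
    pool_corrected_mh,
    pool_inverse_variance,
)

__all__ = [
    "SimConfig",
    "SimSummary",
    "generate_dataset",
    "beta_binomial",
    "lor_bias_analytic",
    "run_cell",
    "run_grid",
    "paper_grid",
    "PAPER_GRID_AXES",
]


@dataclass(frozen=True)
class SimConfig:
    """One cell of the simulation grid."""

    K: int
    n: int
    rho: float
    theta: float
    p2: float
    reps: int = 1000
    seed: int = 0
    level: float = 0.95
    cell: int = 0  # substream index within a grid

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.n < 5:
            raise ValueError("mean arm size n must be >= 5")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if not 0 < self.p2 < 1:
            raise ValueError("p2 must be in (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")

    @property
    def p1(self) -> float:
        e = np.exp(self.theta)
        return float(self.p2 * e / (1 - self.p2 + self.p2 * e))

    @property
    def psi(self) -> float:
        return float(np.exp(self.theta))


def beta_binomial(
    rng: np.random.Generator,
    n: np.ndarray,
    pi: float,
    rho: float,
) -> np.ndarray:
    """Draw beta-binomial counts for each size in ``n`` (binomial if rho=0)."""
    n = np.asarray(n)
    if rho == 0:
        return rng.binomial(n, pi)
    s = 1.0 / rho - 1.0
    p = rng.beta(pi * s, (1 - pi) * s, size=n.shape)
    return rng.binomial(n, p)


def generate_dataset(config: SimConfig, rng: np.random.Generator) -> MetaDataset:
    """Simulate one meta-analysis dataset under the beta-binomial model."""
    nj = np.rint(rng.normal(config.n, np.sqrt(config.n / 4.0), config.K))
    nj = np.maximum(5, nj).astype(int)
    x1 = beta_binomial(rng, nj, config.p1, config.rho)
    x2 = beta_binomial(rng, nj, config.p2, config.rho)
    return MetaDataset(
        Study2x2(f"sim{j + 1}", int(a), int(m), int(b), int(m))
        for j, (a, b, m) in enumerate(zip(x1, x2, nj))
    )


def lor_bias_analytic(p1, p2, n1, n2, rho):
    """Leading-order bias of the sample log-odds-ratio under overdispersion.

    The per-arm log-odds bias term ``-(1 - 2p)(1 + (n - 1) rho)/(2 n p (1-p))``
    is O(1/n) at rho = 0 but O(1) otherwise; the two arms cancel exactly when
    p1 = p2 and n1 = n2.
    """
    b1 = (1 - 2 * np.asarray(p1)) * (1 + (np.asarray(n1) - 1) * rho) / (
        2 * np.asarray(n1) * np.asarray(p1) * (1 - np.asarray(p1))
    )
    b2 = (1 - 2 * np.asarray(p2)) * (1 + (np.asarray(n2) - 1) * rho) / (
        2 * np.asarray(n2) * np.asarray(p2) * (1 - np.asarray(p2))
    )
    return -b1 + b2


def _rng_for(config: SimConfig, rep: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=int(config.seed), spawn_key=(int(config.cell), int(rep))
    )
    return np.random.default_rng(ss)


@dataclass
class SimSummary:
    """Aggregated bias/coverage for one grid cell."""

    config: SimConfig
    replicates: pd.DataFrame = field(repr=False)

    def _est_groups(self):
        return self.replicates.groupby("estimator", sort=False)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format summary: one row per estimator x pooler x metric."""
        cfg = self.config
        rows = []
        base = {
            "K": cfg.K,
            "n": cfg.n,
            "rho": cfg.rho,
            "theta": cfg.theta,
            "p2": cfg.p2,
            "reps": cfg.reps,
            "seed": cfg.seed,
            "cell": cfg.cell,
        }

        def add(estimator, pooler, metric, value, mc_se):
            rows.append(
                {
                    **base,
                    "estimator": estimator,
                    "pooler": pooler,
                    "metric": metric,
                    "value": value,
                    "mc_se": mc_se,
                }
            )

        for est, g in self._est_groups():
            ok = g[g["rho_ok"]]
            m = len(ok)
            if m:
                bias = ok["rho_hat"] - cfg.rho
                add(est, "", "bias_rho", bias.mean(), bias.std(ddof=1) / np.sqrt(m))
                cov = ok["rho_covered"].mean()
                add(est, "", "coverage_rho", cov, np.sqrt(cov * (1 - cov) / m))
                add(est, "", "boundary_rate", ok["rho_boundary"].mean(), np.nan)
            add(est, "", "failures", len(g) - m, np.nan)
            for pool in g["pooler"].dropna().unique():
                gp = g[(g["pooler"] == pool) & g["pool_ok"]]
                m = len(gp)
                if not m:
                    continue
                bias_psi = np.exp(gp["theta_hat"]) - cfg.psi
                add(est, pool, "bias_psi", bias_psi.mean(),
                    bias_psi.std(ddof=1) / np.sqrt(m))
                bias_lor = gp["theta_hat"] - cfg.theta
                add(est, pool, "bias_lor", bias_lor.mean(),
                    bias_lor.std(ddof=1) / np.sqrt(m))
                cov = gp["psi_covered"].mean()
                add(est, pool, "coverage_psi", cov, np.sqrt(cov * (1 - cov) / m))
        return pd.DataFrame(rows)

    def metric(self, estimator: str, metric: str, pooler: str = "") -> tuple[float, float]:
        t = self.to_tidy()
        row = t[
            (t["estimator"] == estimator)
            & (t["pooler"] == pooler)
            & (t["metric"] == metric)
        ]
        if row.empty:
            raise KeyError((estimator, pooler, metric))
        r = row.iloc[0]
        return float(r["value"]), float(r["mc_se"])


def _one_replicate(config, rep, estimators, poolers):
    rng = _rng_for(config, rep)
    data = generate_dataset(config, rng)
    effects = study_effects(data)
    zero_cells = int(sum(s.has_zero_cell() for s in data))
    out = []
    for est in estimators:
        rec = {
            "rep": rep,
            "estimator": est,
            "zero_cell_studies": zero_cells,
            "rho_hat": np.nan,
            "rho_ok": False,
            "rho_boundary": False,
            "rho_covered": False,
            "pooler": None,
            "pool_ok": False,
            "theta_hat": np.nan,
            "psi_covered": False,
        }
        try:
            icc = _icc_with_ci(data, effects, est, config.level)
            rec.update(
                rho_hat=icc.rho,
                rho_ok=True,
                rho_boundary=icc.at_boundary,
                rho_covered=(
                    icc.ci_low is not None
                    and icc.ci_low <= config.rho <= icc.ci_high
                ),
            )
        except Exception:
            out.append(rec)
            continue
        if not poolers:
            out.append(rec)
            continue
        for pool in poolers:
            prec = dict(rec)
            prec["pooler"] = pool
            try:
                if pool == "IV":
                    pl = pool_inverse_variance(effects, icc.rho, config.level)
                else:
                    pl = pool_corrected_mh(data, icc.rho, config.level)
                prec.update(
                    pool_ok=True,
                    theta_hat=pl.theta,
                    psi_covered=pl.ci_low <= config.theta <= pl.ci_high,
                )
            except Exception:
                pass
            out.append(prec)
    return out


def run_cell(
    config: SimConfig,
    estimators: Sequence[str] = ICC_METHODS,
    poolers: Sequence[str] = POOL_METHODS,
) -> SimSummary:
    """Run one simulation cell; fully reproducible from the config seed."""
    unknown = set(estimators) - set(ICC_METHODS)
    if unknown:
        raise ValueError(f"unknown estimators {sorted(unknown)}")
    unknown = set(poolers) - set(POOL_METHODS)
    if unknown:
        raise ValueError(f"unknown poolers {sorted(unknown)}")
    records = []
    for rep in range(config.reps):
        records.extend(_one_replicate(config, rep, estimators, poolers))
    return SimSummary(config=config, replicates=pd.DataFrame(records))


def run_grid(
    grid: Iterable[SimConfig],
    estimators: Sequence[str] = ICC_METHODS,
    poolers: Sequence[str] = POOL_METHODS,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every cell of a grid; returns the concatenated tidy summary.

    Each cell gets an independent substream (its ``cell`` index), so results
    do not depend on execution order.
    """
    frames = []
    for i, cfg in enumerate(grid):
        cfg = replace(cfg, cell=cfg.cell or i)
        if progress:  # pragma: no cover - cosmetic
            print(f"cell {i}: {cfg}", flush=True)
        frames.append(run_cell(cfg, estimators, poolers).to_tidy())
    return pd.concat(frames, ignore_index=True)


#: axes of the full published study design (reps = 10000 per cell)
PAPER_GRID_AXES = {
    "K": (5, 10, 20, 30, 50, 80),
    "n": (10, 20, 40, 50, 80, 100, 160, 250, 640, 1000),
    # 0 to 0.1 in steps of 0.01, then 0.1 to 0.3 in steps of 0.05,
    # enumerated literally (0.1 appears in both ranges)
    "rho": tuple(np.round(np.arange(0.0, 0.1 + 1e-9, 0.01), 2))
    + tuple(np.round(np.arange(0.1, 0.3 + 1e-9, 0.05), 2)),
    "theta": (0.0, 1.0, 2.0, 3.0),
    "p2": (0.1, 0.2, 0.4),
}


def paper_grid(reps: int = 10000, seed: int = 0, level: float = 0.95) -> list[SimConfig]:
    """Enumerate the full study configuration space as SimConfig cells."""
    axes = PAPER_GRID_AXES
    cells = []
    i = 0
    for K in axes["K"]:
        for n in axes["n"]:
            for rho in axes["rho"]:
                for theta in axes["theta"]:
                    for p2 in axes["p2"]:
                        cells.append(
                            SimConfig(
                                K=K, n=n, rho=float(rho), theta=float(theta),
                                p2=float(p2), reps=reps, seed=seed,
                                level=level, cell=i,
                            )
                        )
                        i += 1
    return cells
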