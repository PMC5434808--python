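"""Result containers shared by the estimation and pooling modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ICCResult", "ProfileInterval", "PooledResult"]


@dataclass(frozen=True)
class ProfileInterval:
    """A profile confidence interval for the intra-class correlation.

    ``low_truncated``/``high_truncated`` flag endpoints clipped to the
    admissible range; ``empty`` flags a confidence set with no admissible
    member (endpoints are then NaN).
    """

    low: float
    high: float
    level: float
    low_truncated: bool = False
    high_truncated: bool = False
    empty: bool = False
    meta: dict = field(default_factory=dict, compare=False)

    def contains(self, rho: float) -> bool:
        return (not self.empty) and self.low <= rho <= self.high

    @property
    def width(self) -> float:
        return self.high - self.low


@dataclass(frozen=True)
class ICCResult:
    """Point estimate of the intra-class correlation rho."""

    method: str
    rho: float
    ci_low: float | None = None
    ci_high: float | None = None
    at_boundary: bool = False
    converged: bool = True
    meta: dict = field(default_factory=dict, compare=False)

    def with_interval(self, interval: ProfileInterval) -> "ICCResult":
        return ICCResult(
            method=self.method,
            rho=self.rho,
            ci_low=interval.low if not interval.empty else None,
            ci_high=interval.high if not interval.empty else None,
            at_boundary=self.at_boundary,
            converged=self.converged,
            meta={**self.meta, "interval": interval},
        )


@dataclass(frozen=True)
class PooledResult:
    """Pooled odds ratio on the log and natural scales.

    ``psi`` is always ``exp(theta)`` and the OR-scale bounds are the
    exponentiated LOR bounds.
    """

    pool_method: str
    icc_method: str | None
    theta: float
    se: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def psi(self) -> float:
        return float(np.exp(self.theta))

    @property
    def psi_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def psi_high(self) -> float:
        return float(np.exp(self.ci_high))
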