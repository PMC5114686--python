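"""Meta-analytic pooling of historical control cohorts.

When the historical controls come from several sources (past RCT control
arms, registries), the control-mean estimate feeding the threshold rules
should account for between-source variability. This module provides
inverse-variance fixed-effect pooling and DerSimonian-Laird
random-effects pooling of cohort means, plus an adapter that re-expresses
a pooled estimate as a synthetic cohort (mean + effective sample size) so
the threshold rules can consume it unchanged.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

from .design import HistoricalCohort

__all__ = [
    "PoolMethod",
    "PooledEstimate",
    "fixed_effect_pool",
    "random_effects_pool",
    "pooled_to_cohort",
]


class PoolMethod(str, enum.Enum):
    FIXED = "fixed"
    RANDOM = "random"


@dataclass(frozen=True)
class PooledEstimate:
    """Pooled control-mean estimate.

    ``tau2`` is the between-source variance (0 under the fixed-effect
    model); ``effective_n = sigma^2 / se^2`` expresses the pooled
    precision on the patient-count scale of a single cohort with the
    planning sigma.
    """

    estimate: float
    se: float
    tau2: float
    method: PoolMethod
    effective_n: float
    k: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"se must be > 0, got {self.se}")
        if self.tau2 < 0:
            raise ValueError(f"tau2 must be >= 0, got {self.tau2}")
        if self.method is PoolMethod.FIXED and self.tau2 != 0:
            raise ValueError("fixed-effect pooling requires tau2 = 0")


def _weights(cohorts: Sequence[HistoricalCohort], sigma: float) -> list[float]:
    # cohort-level variance: observed sd when recorded, planning sigma otherwise
    out = []
    for c in cohorts:
        s = c.sd if (c.sd is not None and c.sd > 0) else sigma
        out.append(c.n_h / s**2)
    return out


def fixed_effect_pool(cohorts: Sequence[HistoricalCohort],
                      sigma: float = 1.0) -> PooledEstimate:
    """Inverse-variance fixed-effect pooled mean across cohorts."""
    if len(cohorts) == 0:
        raise ValueError("need at least one cohort to pool")
    w = _weights(cohorts, sigma)
    sw = sum(w)
    est = sum(wi * c.mean for wi, c in zip(w, cohorts)) / sw
    se = 1.0 / math.sqrt(sw)
    return PooledEstimate(estimate=est, se=se, tau2=0.0,
                          method=PoolMethod.FIXED,
                          effective_n=sigma**2 / se**2, k=len(cohorts))


def random_effects_pool(cohorts: Sequence[HistoricalCohort],
                        sigma: float = 1.0) -> PooledEstimate:
    """DerSimonian-Laird random-effects pooled mean across cohorts.

    The method-of-moments between-source variance is

        tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))

    with Q the fixed-effect heterogeneity statistic; cohorts are then
    re-weighted by 1 / (sigma_i^2/n_i + tau2). With a single cohort (or
    Q <= k-1) this reduces to the fixed-effect result.
    """
    if len(cohorts) == 0:
        raise ValueError("need at least one cohort to pool")
    fixed = fixed_effect_pool(cohorts, sigma)
    if len(cohorts) == 1:
        return PooledEstimate(estimate=fixed.estimate, se=fixed.se, tau2=0.0,
                              method=PoolMethod.RANDOM,
                              effective_n=fixed.effective_n, k=1)
    w = _weights(cohorts, sigma)
    sw = sum(w)
    q = sum(wi * (c.mean - fixed.estimate) ** 2 for wi, c in zip(w, cohorts))
    k = len(cohorts)
    denom = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (q - (k - 1)) / denom)
    w_star = [1.0 / (1.0 / wi + tau2) for wi in w]
    sws = sum(w_star)
    est = sum(wi * c.mean for wi, c in zip(w_star, cohorts)) / sws
    se = 1.0 / math.sqrt(sws)
    return PooledEstimate(estimate=est, se=se, tau2=tau2,
                          method=PoolMethod.RANDOM,
                          effective_n=sigma**2 / se**2, k=k)


def pooled_to_cohort(p: PooledEstimate, sigma: float = 1.0) -> HistoricalCohort:
    """Express a pooled estimate as a synthetic single cohort.

    The effective sample size is floor-rounded (conservative: a slightly
    wider CI) with a floor of 1, so CI-based threshold rules can be
    applied to multi-source historical data unchanged.
    """
    n_eff = max(1, math.floor(p.effective_n + 1e-9))
    return HistoricalCohort(source_id=f"pooled[{p.method.value},k={p.k}]",
                            n_h=n_eff, mean=p.estimate, sd=None)
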