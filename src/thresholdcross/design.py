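"""Closed-form planning mathematics for threshold-crossing trials.

A threshold-crossing trial replaces the concurrent control arm of an RCT
with an efficacy threshold ``t`` derived from historical control data: a
single experimental arm is run, and efficacy is claimed when a one-sample
test rejects ``H0t: mu_N <= t`` at a one-sided level alpha. This module
holds the deterministic planning layer: sample sizes for the two-arm
reference design and the single-arm design, the threshold rules, the
known-variance z-tests, and an exact (marginal over the historical
sampling distribution) rejection-probability oracle that the Monte Carlo
engine is validated against.

All tests are known-variance z-tests with the planning sigma; sample
sizes round by ceiling. ``round_to_hundred`` exists purely for
"about 400"-style reporting and never feeds back into the planning math.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import InfeasibleDesignError

__all__ = [
    "DesignParams",
    "RuleTag",
    "ThresholdRule",
    "HistoricalCohort",
    "Threshold",
    "TrialResult",
    "ZTestResult",
    "parallel_group_sample_size",
    "single_arm_sample_size",
    "compute_threshold",
    "planned_trial_size",
    "one_sample_z_test",
    "two_sample_z_test",
    "exact_rejection_probability",
    "round_to_hundred",
]


@dataclass(frozen=True)
class DesignParams:
    """Planning assumptions for a normally distributed endpoint.

    Parameters
    ----------
    delta
        Standardized effect size (mu_N - mu_C) / sigma assumed under the
        alternative; dimensionless, > 0. Reference value 0.2.
    sigma
        Known standard deviation of the endpoint, in endpoint units.
    alpha
        One-sided significance level, conventionally 0.025.
    power
        Target power 1 - beta, conventionally 0.80.
    """

    delta: float
    sigma: float = 1.0
    alpha: float = 0.025
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if not 0.0 < self.power < 1.0:
            raise ValueError(f"power must be in (0, 1), got {self.power}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


class RuleTag(str, enum.Enum):
    """How the efficacy threshold is derived from the historical mean."""

    NAIVE_MEAN = "naive_mean"
    CI_UPPER = "ci_upper"
    CI_UPPER_PLUS = "ci_upper_plus"


@dataclass(frozen=True)
class ThresholdRule:
    """Tagged choice of threshold derivation.

    NAIVE_MEAN uses the observed historical mean directly; CI_UPPER uses
    the upper boundary of a two-sided ``gamma`` confidence interval for
    the control mean; CI_UPPER_PLUS additionally adds a fraction ``c`` of
    the assumed standardized effect (c in {0.1, 0.2, 0.3} are the
    reference choices).
    """

    tag: RuleTag = RuleTag.CI_UPPER
    gamma: float = 0.95
    c: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError(f"gamma must be in (0, 1), got {self.gamma}")
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")

    @classmethod
    def parse(cls, label: str) -> "ThresholdRule":
        """Parse a short CLI label: ``naive``, ``ci``, or ``ci+<c>``."""
        s = label.strip().lower()
        if s in ("naive", "naive_mean", "mean"):
            return cls(RuleTag.NAIVE_MEAN)
        if s in ("ci", "ci_upper"):
            return cls(RuleTag.CI_UPPER)
        if s.startswith("ci+"):
            return cls(RuleTag.CI_UPPER_PLUS, c=float(s[3:]))
        if s in ("ci_upper_plus",):
            return cls(RuleTag.CI_UPPER_PLUS, c=0.1)
        raise ValueError(f"unrecognized threshold rule label: {label!r}")

    @property
    def label(self) -> str:
        if self.tag is RuleTag.NAIVE_MEAN:
            return "naive"
        if self.tag is RuleTag.CI_UPPER:
            return "ci"
        return f"ci+{self.c:g}"

    def standardized_offset(self, n_h: float, delta: float) -> float:
        """Distance t - hist_mean in sigma units for historical size n_h.

        0 for NAIVE_MEAN; the CI half-width z_{(1+gamma)/2}/sqrt(n_h) for
        CI_UPPER; that plus c*delta for CI_UPPER_PLUS. ``n_h`` may be
        ``math.inf`` for the no-uncertainty limit.
        """
        if self.tag is RuleTag.NAIVE_MEAN:
            return 0.0
        half_width = norm.ppf((1.0 + self.gamma) / 2.0) / math.sqrt(n_h)
        if self.tag is RuleTag.CI_UPPER:
            return half_width
        return half_width + self.c * delta


@dataclass(frozen=True)
class HistoricalCohort:
    """One historical control group: summaries and optional raw values."""

    source_id: str
    n_h: int
    mean: float
    sd: float | None = None
    values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_h < 1:
            raise ValueError(f"n_h must be >= 1, got {self.n_h}")
        if self.sd is not None and self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.values is not None:
            vals = np.asarray(self.values, dtype=float)
            if len(vals) != self.n_h:
                raise ValueError(
                    f"{len(vals)} patient values but n_h={self.n_h}"
                )
            if not math.isclose(float(vals.mean()), self.mean,
                                rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError("stored mean disagrees with patient values")
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            if self.sd is not None and not math.isclose(
                    sd, self.sd, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError("stored sd disagrees with patient values")

    @classmethod
    def from_values(cls, source_id: str,
                    values: Sequence[float]) -> "HistoricalCohort":
        vals = np.asarray(values, dtype=float)
        if vals.size < 1:
            raise ValueError("need at least one patient value")
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        return cls(source_id=source_id, n_h=int(vals.size),
                   mean=float(vals.mean()), sd=sd,
                   values=tuple(float(v) for v in vals))


@dataclass(frozen=True)
class Threshold:
    """A derived efficacy threshold with its provenance."""

    t: float
    rule: ThresholdRule
    provenance: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class TrialResult:
    """Summary of one trial arm: size, mean, standard deviation."""

    n: int
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class ZTestResult:
    z: float
    reject: bool
    alpha: float
    critical: float


def parallel_group_sample_size(params: DesignParams) -> int:
    """Per-group size for a two-arm superiority z-test.

    n = ceil( 2 (z_{1-alpha} + z_{power})^2 / delta^2 ), the classical
    two-sample formula for a known-variance normal endpoint.
    """
    z_a = norm.ppf(1.0 - params.alpha)
    z_b = norm.ppf(params.power)
    return math.ceil(2.0 * (z_a + z_b) ** 2 / params.delta**2)


def single_arm_sample_size(effective_delta: float, alpha: float = 0.025,
                           power: float = 0.80) -> int:
    """Size of a single-arm trial testing against a fixed threshold.

    n = ceil( (z_{1-alpha} + z_{power})^2 / effective_delta^2 ) where
    ``effective_delta`` is the standardized distance between the assumed
    treatment mean and the threshold. Raises InfeasibleDesignError when
    that distance is non-positive (the threshold sits at or above the
    assumed treatment mean, so no sample size can help).
    """
    if effective_delta <= 0:
        raise InfeasibleDesignError(
            f"effective standardized effect {effective_delta:g} <= 0: "
            "threshold meets or exceeds the assumed treatment mean"
        )
    z_a = norm.ppf(1.0 - alpha)
    z_b = norm.ppf(power)
    return math.ceil((z_a + z_b) ** 2 / effective_delta**2)


def compute_threshold(hist: HistoricalCohort, rule: ThresholdRule,
                      params: DesignParams,
                      use_observed_sd: bool = False) -> Threshold:
    """Derive the efficacy threshold t from a historical cohort.

    NAIVE_MEAN: t = hist.mean. CI_UPPER: t = mean + z_{(1+gamma)/2} *
    sigma / sqrt(n_h). CI_UPPER_PLUS adds c * delta * sigma on top.
    The default sigma is the planning sigma from ``params`` (the
    deterministic half-width convention); ``use_observed_sd=True``
    substitutes the cohort's own sd where available.
    """
    sigma = params.sigma
    if use_observed_sd and hist.sd is not None and hist.sd > 0:
        sigma = hist.sd
    if rule.tag is RuleTag.NAIVE_MEAN:
        t = hist.mean
    else:
        half = norm.ppf((1.0 + rule.gamma) / 2.0) * sigma / math.sqrt(hist.n_h)
        t = hist.mean + half
        if rule.tag is RuleTag.CI_UPPER_PLUS:
            t += rule.c * params.delta * params.sigma
    return Threshold(
        t=t, rule=rule,
        provenance={"source_id": hist.source_id, "hist_mean": hist.mean,
                    "n_h": hist.n_h, "sigma_used": sigma},
    )


def planned_trial_size(rule: ThresholdRule, n_h: float,
                       params: DesignParams) -> int:
    """Deterministic planned size of the threshold-crossing trial.

    The assumed standardized effect is reduced by the rule's known
    threshold offset (the CI half-width plus any c*delta inflation), not
    by a random draw: effective_delta = delta - offset(n_h). Monotone
    non-increasing in n_h; converges to the naive single-arm size as
    n_h -> infinity.
    """
    if n_h < 1:
        raise ValueError(f"n_h must be >= 1, got {n_h}")
    eff = params.delta - rule.standardized_offset(n_h, params.delta)
    return single_arm_sample_size(eff, params.alpha, params.power)


def one_sample_z_test(trial: TrialResult, t: Threshold | float,
                      alpha: float = 0.025, sigma: float = 1.0) -> ZTestResult:
    """Known-variance one-sample z-test of H0t: mu_N <= t.

    z = (mean - t) sqrt(n) / sigma, rejecting iff z > z_{1-alpha}. Ties
    at the critical value do not reject.
    """
    t_val = t.t if isinstance(t, Threshold) else float(t)
    z = (trial.mean - t_val) * math.sqrt(trial.n) / sigma
    crit = float(norm.ppf(1.0 - alpha))
    return ZTestResult(z=z, reject=z > crit, alpha=alpha, critical=crit)


def two_sample_z_test(exp: TrialResult, ctrl: TrialResult,
                      alpha: float = 0.025, sigma: float = 1.0) -> ZTestResult:
    """Known-variance two-sample z-test of H0: mu_E <= mu_C (one-sided)."""
    se = sigma * math.sqrt(1.0 / exp.n + 1.0 / ctrl.n)
    z = (exp.mean - ctrl.mean) / se
    crit = float(norm.ppf(1.0 - alpha))
    return ZTestResult(z=z, reject=z > crit, alpha=alpha, critical=crit)


def exact_rejection_probability(rule: ThresholdRule, n_h: float, n: int,
                                params: DesignParams,
                                true_delta: float = 0.0,
                                drift: float = 0.0) -> float:
    """Exact rejection probability of the threshold design, marginally
    over the historical sampling distribution.

    The historical cohort mean is drawn around mu_C_hist with variance
    sigma^2/n_h, the trial mean around mu_C_hist + drift +
    true_delta*sigma with variance sigma^2/n, and the threshold is the
    historical mean plus the rule's offset. The rejection event
    ``trial_mean - t > z_{1-alpha} sigma / sqrt(n)`` is then a normal
    tail probability:

        1 - Phi( (offset + z_{1-alpha}/sqrt(n) - true_delta - drift/sigma)
                 / sqrt(1/n + 1/n_h) )

    in standardized units. ``true_delta=0`` gives the (possibly drifted)
    type-I error; ``true_delta=params.delta`` gives power. ``n_h`` may be
    ``math.inf`` for the no-historical-uncertainty limit.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    offset = rule.standardized_offset(n_h, params.delta)
    z_a = norm.ppf(1.0 - params.alpha)
    inv_nh = 0.0 if math.isinf(n_h) else 1.0 / n_h
    num = offset + z_a / math.sqrt(n) - true_delta - drift / params.sigma
    den = math.sqrt(1.0 / n + inv_nh)
    return float(norm.sf(num / den))


def round_to_hundred(n: int) -> int:
    """Nearest-hundred presentation helper for 'about 400'-style reporting."""
    return int(round(n / 100.0)) * 100
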