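"""Multistage decision flow for threshold-crossing development programs.

After the initial single-arm trial, the result is classified against an
efficacy threshold and a futility threshold: crossing the efficacy
threshold (by the one-sided lower confidence bound, equivalently the
one-sample z-test) deems the product EFFECTIVE; a point estimate below
the futility threshold deems it INEFFECTIVE and terminates development;
anything in between is PROMISING and triggers a pre-agreed second stage,
either a conventional RCT against concurrent controls or, where an RCT
is impractical, a second single-arm trial against the same threshold
with fresh data.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm

from .design import (
    DesignParams,
    Threshold,
    ThresholdRule,
    TrialResult,
    parallel_group_sample_size,
    planned_trial_size,
)
from .simulate import Scenario, cell_rng

__all__ = [
    "Outcome",
    "Stage2",
    "DecisionThresholds",
    "MultistagePlan",
    "MultistageSummary",
    "classify_trial_outcome",
    "simulate_multistage",
]


class Outcome(str, enum.Enum):
    EFFECTIVE = "effective"
    PROMISING = "promising"
    INEFFECTIVE = "ineffective"


class Stage2(str, enum.Enum):
    RCT = "rct"
    SECOND_SINGLE_ARM = "second_single_arm"
    NONE = "none"


@dataclass(frozen=True)
class DecisionThresholds:
    """Efficacy and futility benchmarks, in endpoint units.

    In ``simulate_multistage`` either field may be ``None``: the
    efficacy threshold is then derived per replicate from the simulated
    historical cohort via the scenario's rule, and the futility
    threshold defaults to the historical point estimate itself
    (sponsor-set, so fully overridable).
    """

    efficacy_t: Optional[float] = None
    futility_f: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.efficacy_t is not None and self.futility_f is not None
                and self.futility_f > self.efficacy_t):
            raise ValueError("futility threshold must not exceed the "
                             "efficacy threshold")


@dataclass(frozen=True)
class MultistagePlan:
    """What happens to a PROMISING stage-1 result.

    ``alpha2`` is the one-sided level of the stage-2 test. No
    multiplicity adjustment is applied across stages by default (the
    overall false-positive rate is then bounded by alpha1 + alpha2);
    pass ``split_alpha=True`` to halve both stage levels instead.
    """

    stage2: Stage2 = Stage2.RCT
    alpha2: float = 0.025
    split_alpha: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha2 < 0.5:
            raise ValueError(f"alpha2 must be in (0, 0.5), got {self.alpha2}")


@dataclass(frozen=True)
class MultistageSummary:
    """Program-level operating characteristics from the flow simulation."""

    p_effective: float
    p_promising: float
    p_ineffective: float
    p_overall_positive: float
    p_stage2_positive_given_promising: float
    expected_total_n: float
    stage1_n: int
    stage2_n: int
    n_reps: int
    seed: int


def classify_trial_outcome(trial: TrialResult, dt: DecisionThresholds,
                           params: DesignParams,
                           use_point_estimate: bool = False) -> Outcome:
    """Classify a completed single-arm trial.

    EFFECTIVE iff the one-sided lower (1-alpha) confidence bound
    ``mean - z_{1-alpha} sigma / sqrt(n)`` exceeds the efficacy
    threshold (the test-equivalent crossing rule; with
    ``use_point_estimate=True`` the point estimate is compared
    instead). INEFFECTIVE iff the point estimate falls below the
    futility threshold. Otherwise PROMISING.
    """
    if dt.efficacy_t is None or dt.futility_f is None:
        raise ValueError("classification needs both thresholds set")
    margin = 0.0 if use_point_estimate else \
        norm.ppf(1.0 - params.alpha) * params.sigma / math.sqrt(trial.n)
    if trial.mean - margin > dt.efficacy_t:
        return Outcome.EFFECTIVE
    if trial.mean < dt.futility_f:
        return Outcome.INEFFECTIVE
    return Outcome.PROMISING


def _stage_alphas(scenario: Scenario, plan: MultistagePlan) -> tuple[float, float]:
    a1, a2 = scenario.params.alpha, plan.alpha2
    if plan.split_alpha:
        return a1 / 2.0, a2 / 2.0
    return a1, a2


def simulate_multistage(scenario: Scenario, dt: DecisionThresholds,
                        plan: MultistagePlan, n_reps: int,
                        seed: int,
                        use_point_estimate: bool = False) -> MultistageSummary:
    """Simulate the full two-stage development program.

    Per replicate: a historical cohort fixes the thresholds (unless
    given numerically in ``dt``), a stage-1 single-arm trial of the
    planned size is run and classified; PROMISING results proceed to
    stage 2 — a two-arm RCT against a freshly simulated concurrent
    control, or a second single-arm trial against the same threshold,
    per the plan. Returns the stage-1 outcome probabilities, the overall
    probability of a positive conclusion (stage-1 EFFECTIVE or stage-2
    rejection), and the expected total number of patients across stages
    (both RCT arms counted). Stage-2 trials use fresh data only; stage-1
    data are not pooled in.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    p, rule = scenario.params, scenario.rule
    n1 = planned_trial_size(rule, scenario.n_h, p)
    alpha1, alpha2 = _stage_alphas(scenario, plan)
    rng = cell_rng(seed, "flow", rule.label, rule.gamma, scenario.n_h,
                   scenario.drift, scenario.true_delta, scenario.mu_c_hist,
                   plan.stage2.value, plan.alpha2, plan.split_alpha,
                   dt.efficacy_t, dt.futility_f, n_reps)

    # sufficient statistics per replicate: historical and trial means
    hist_means = rng.normal(scenario.mu_c_hist,
                            p.sigma / math.sqrt(scenario.n_h), size=n_reps)
    mu_n = scenario.mu_c_hist + scenario.drift + scenario.true_delta * p.sigma
    trial_means = rng.normal(mu_n, p.sigma / math.sqrt(n1), size=n_reps)

    offset = rule.standardized_offset(scenario.n_h, p.delta) * p.sigma
    eff_t = np.full(n_reps, dt.efficacy_t, dtype=float) \
        if dt.efficacy_t is not None else hist_means + offset
    fut_f = np.full(n_reps, dt.futility_f, dtype=float) \
        if dt.futility_f is not None else hist_means

    margin = 0.0 if use_point_estimate else \
        norm.ppf(1.0 - alpha1) * p.sigma / math.sqrt(n1)
    effective = trial_means - margin > eff_t
    ineffective = ~effective & (trial_means < fut_f)
    promising = ~effective & ~ineffective

    n_prom = int(promising.sum())
    stage2_positive = np.zeros(n_reps, dtype=bool)
    if plan.stage2 is Stage2.RCT:
        n2_group = parallel_group_sample_size(
            DesignParams(p.delta, p.sigma, alpha2, p.power))
        stage2_n = 2 * n2_group
        if n_prom:
            se = p.sigma / math.sqrt(n2_group)
            ctrl = rng.normal(scenario.mu_c_hist + scenario.drift, se,
                              size=n_prom)
            exp = rng.normal(mu_n, se, size=n_prom)
            z = (exp - ctrl) / (p.sigma * math.sqrt(2.0 / n2_group))
            stage2_positive[promising] = z > norm.ppf(1.0 - alpha2)
    elif plan.stage2 is Stage2.SECOND_SINGLE_ARM:
        stage2_n = n1  # same size rule, same threshold, fresh data
        if n_prom:
            means2 = rng.normal(mu_n, p.sigma / math.sqrt(n1), size=n_prom)
            margin2 = norm.ppf(1.0 - alpha2) * p.sigma / math.sqrt(n1)
            stage2_positive[promising] = means2 - margin2 > eff_t[promising]
    else:
        stage2_n = 0

    positive = effective | stage2_positive
    p_prom = n_prom / n_reps
    return MultistageSummary(
        p_effective=float(effective.mean()),
        p_promising=p_prom,
        p_ineffective=float(ineffective.mean()),
        p_overall_positive=float(positive.mean()),
        p_stage2_positive_given_promising=(
            float(stage2_positive.sum() / n_prom) if n_prom else 0.0),
        expected_total_n=n1 + p_prom * stage2_n,
        stage1_n=n1, stage2_n=stage2_n, n_reps=n_reps, seed=int(seed))
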