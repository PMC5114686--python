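"""Run configuration, cohort CSV schemas, and the end-to-end pipeline.

The configuration file is the machine-readable analysis plan of a
threshold-crossing program: estimand metadata, design parameters,
threshold rules, the historical-control source, the scenario grid and
the multistage plan, all fixed up front together with the seed. Running
the same configuration with the same seed reproduces every output byte
for byte.

Historical cohorts may be given inline as summaries, read from CSV
(summary schema ``source_id,n,mean,sd`` or patient-level schema
``source_id,patient_id,outcome``), or generated synthetically.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import (
    DesignParams,
    HistoricalCohort,
    ThresholdRule,
    compute_threshold,
    parallel_group_sample_size,
    planned_trial_size,
    round_to_hundred,
)
from .errors import CohortCSVError, ConfigError, InfeasibleDesignError
from .flow import DecisionThresholds, MultistagePlan, Stage2, simulate_multistage
from .pooling import PoolMethod, fixed_effect_pool, pooled_to_cohort, random_effects_pool
from .simulate import GridConfig, Scenario, cell_rng, figure2_grid, simulate_historical_cohort

__all__ = [
    "RunConfig",
    "load_config",
    "read_cohort_csv",
    "write_cohort_csv",
    "resolve_cohorts",
    "run_pipeline",
]

SUMMARY_COLS = {"source_id", "n", "mean", "sd"}
PATIENT_COLS = {"source_id", "patient_id", "outcome"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (see ``load_config`` for the file schema)."""

    design: DesignParams
    rules: tuple[ThresholdRule, ...]
    historical: dict
    estimand: dict = field(default_factory=dict)
    pooling: PoolMethod = PoolMethod.FIXED
    grid: dict = field(default_factory=dict)
    flow: Optional[dict] = None
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        sources = [k for k in ("csv", "cohorts", "generate")
                   if k in self.historical]
        if len(sources) != 1:
            raise ConfigError(
                "historical input must name exactly one of csv / cohorts / "
                f"generate, got {sources or 'none'}")


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw)}")
    try:
        design = DesignParams(**raw.get("design", {"delta": 0.2}))
        rules = tuple(ThresholdRule.parse(r) for r in raw.get("rules", ["ci"]))
        return RunConfig(
            design=design,
            rules=rules,
            historical=raw.get("historical", {}),
            estimand=raw.get("estimand", {}),
            pooling=PoolMethod(raw.get("pooling", "fixed")),
            grid=raw.get("grid", {}),
            flow=raw.get("flow"),
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "results")),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def _numeric(series: pd.Series, col: str, path: Path) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.index[out.isna()]
    if len(bad):
        # +2: 1-based data rows after the header line
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise CohortCSVError(
            f"{path}: non-numeric or missing value in column {col!r} "
            f"at line(s) {lines}")
    return out


def read_cohort_csv(path: str | Path) -> list[HistoricalCohort]:
    """Read historical cohorts from CSV.

    Two schemas are accepted: summary rows ``source_id,n,mean,sd`` (one
    cohort per row) or patient-level rows ``source_id,patient_id,outcome``
    (grouped by source, summaries recomputed). A patient-level file may
    carry an optional ``n`` column stating the cohort size, which is
    checked against the actual row count. Mixing schemas is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise CohortCSVError(f"cohort file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise CohortCSVError(f"{path}: cannot parse CSV: {exc}") from exc
    cols = set(df.columns)
    is_summary = SUMMARY_COLS <= cols
    is_patient = PATIENT_COLS <= cols
    if is_summary and is_patient:
        raise CohortCSVError(f"{path}: mixed summary and patient-level schema")
    if not (is_summary or is_patient):
        raise CohortCSVError(
            f"{path}: header must contain {sorted(SUMMARY_COLS)} or "
            f"{sorted(PATIENT_COLS)}, got {sorted(cols)}")
    if df.empty:
        raise CohortCSVError(f"{path}: no data rows")
    if is_summary:
        n = _numeric(df["n"], "n", path)
        mean = _numeric(df["mean"], "mean", path)
        sd = _numeric(df["sd"], "sd", path)
        dup = df["source_id"][df["source_id"].duplicated()]
        if len(dup):
            raise CohortCSVError(
                f"{path}: duplicated source_id {dup.iloc[0]!r}")
        return [HistoricalCohort(source_id=str(s), n_h=int(ni),
                                 mean=float(m), sd=float(sdi))
                for s, ni, m, sdi in zip(df["source_id"], n, mean, sd)]
    outcome = _numeric(df["outcome"], "outcome", path)
    stated_n = _numeric(df["n"], "n", path) if "n" in cols else None
    cohorts = []
    for sid in df["source_id"].drop_duplicates():
        mask = df["source_id"] == sid
        vals = outcome[mask].to_numpy(dtype=float)
        if stated_n is not None:
            stated = set(stated_n[mask].astype(int))
            if stated != {len(vals)}:
                raise CohortCSVError(
                    f"{path}: source {sid!r} states n={sorted(stated)} but "
                    f"has {len(vals)} patient rows")
        cohorts.append(HistoricalCohort.from_values(str(sid), vals))
    return cohorts


def write_cohort_csv(cohorts: list[HistoricalCohort], path: str | Path) -> None:
    """Write cohorts to CSV, patient-level when raw values are available."""
    path = Path(path)
    if all(c.values is not None for c in cohorts):
        rows = [(c.source_id, i + 1, v)
                for c in cohorts for i, v in enumerate(c.values)]
        pd.DataFrame(rows, columns=["source_id", "patient_id", "outcome"]
                     ).to_csv(path, index=False)
    else:
        rows = [(c.source_id, c.n_h, c.mean,
                 c.sd if c.sd is not None else "") for c in cohorts]
        pd.DataFrame(rows, columns=["source_id", "n", "mean", "sd"]
                     ).to_csv(path, index=False)


def resolve_cohorts(config: RunConfig) -> list[HistoricalCohort]:
    """Materialize the historical cohorts named by the configuration."""
    hist = config.historical
    if "csv" in hist:
        return read_cohort_csv(hist["csv"])
    if "cohorts" in hist:
        try:
            return [HistoricalCohort(source_id=str(c["source_id"]),
                                     n_h=int(c["n"]), mean=float(c["mean"]),
                                     sd=float(c["sd"]) if c.get("sd")
                                     is not None else None)
                    for c in hist["cohorts"]]
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid inline cohort: {exc}") from exc
    gen = hist["generate"]
    n_sources = int(gen.get("sources", 1))
    rng = cell_rng(config.seed, "historical_generator", gen.get("n_h"),
                   gen.get("mu", 0.0), gen.get("sigma"), n_sources)
    sigma = float(gen.get("sigma", config.design.sigma))
    return [simulate_historical_cohort(int(gen["n_h"]),
                                       float(gen.get("mu", 0.0)), sigma,
                                       rng, source_id=f"sim{i + 1}")
            for i in range(n_sources)]


def _config_hash(config: RunConfig) -> str:
    def default(o: Any) -> Any:
        if isinstance(o, (DesignParams, ThresholdRule)):
            return asdict(o)
        return str(o)
    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def _threshold_report(config: RunConfig,
                      cohorts: list[HistoricalCohort]) -> dict:
    p = config.design
    pool_fn = (fixed_effect_pool if config.pooling is PoolMethod.FIXED
               else random_effects_pool)
    pooled = pool_fn(cohorts, p.sigma)
    hist = pooled_to_cohort(pooled, p.sigma)
    per_rule = {}
    for rule in config.rules:
        th = compute_threshold(hist, rule, p)
        entry: dict[str, Any] = {"threshold": th.t, "rule": rule.label,
                                 "gamma": rule.gamma, "c": rule.c}
        try:
            n = planned_trial_size(rule, hist.n_h, p)
            entry["planned_n"] = n
            entry["planned_n_rounded"] = round_to_hundred(n)
        except InfeasibleDesignError as exc:
            entry["planned_n"] = None
            entry["infeasible"] = str(exc)
        per_rule[rule.label] = entry
    n2 = parallel_group_sample_size(p)
    return {
        "estimand": config.estimand,
        "design": asdict(p),
        "pooled": {"estimate": pooled.estimate, "se": pooled.se,
                   "tau2": pooled.tau2, "method": pooled.method.value,
                   "effective_n": pooled.effective_n, "k": pooled.k},
        "two_arm_reference": {"per_group": n2, "total": 2 * n2,
                              "per_group_rounded": round_to_hundred(n2),
                              "total_rounded": round_to_hundred(2 * n2)},
        "thresholds": per_rule,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full plan: pool -> threshold -> size -> simulate -> flow.

    Writes ``threshold_report.json``, ``oc_grid.csv``, optionally
    ``flow_summary.json``, and ``run_log.json`` (config hash, seed,
    package version) under the output directory; returns the artifact
    paths keyed by name. Identical configuration and seed give
    byte-identical outputs. Module errors are re-raised with the
    pipeline stage named.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name: str, fn):
        try:
            return fn()
        except (CohortCSVError, ConfigError, InfeasibleDesignError,
                ValueError) as exc:
            raise type(exc)(f"[stage: {name}] {exc}") from exc

    cohorts = stage("historical-input", lambda: resolve_cohorts(config))
    report = stage("threshold",
                   lambda: _threshold_report(config, cohorts))
    path = out / "threshold_report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    artifacts["threshold_report"] = path

    grid_cfg = dict(config.grid)
    pooled_nh = report["pooled"]["effective_n"]
    n_h_grid = tuple(int(v) for v in grid_cfg.pop(
        "n_h", [max(1, math.floor(pooled_nh))]))
    gc = stage("grid-config", lambda: GridConfig(
        params=config.design, rules=config.rules, n_h_grid=n_h_grid,
        drifts=tuple(float(d) for d in grid_cfg.pop("drifts", [0.0])),
        n_reps_type1=int(grid_cfg.pop("n_reps_type1", 100_000)),
        n_reps_power=int(grid_cfg.pop("n_reps_power", 10_000)),
        seed=config.seed,
        mu_c_hist=float(grid_cfg.pop("mu_c_hist", 0.0)),
        include_two_arm=bool(grid_cfg.pop("include_two_arm", True))))
    if grid_cfg:
        raise ConfigError(f"[stage: grid-config] unknown grid keys: "
                          f"{sorted(grid_cfg)}")
    oc = stage("simulate", lambda: figure2_grid(gc))
    path = out / "oc_grid.csv"
    oc.to_csv(path, index=False)
    artifacts["oc_grid"] = path

    if config.flow is not None:
        fl = dict(config.flow)
        plan = MultistagePlan(stage2=Stage2(fl.get("stage2", "rct")),
                              alpha2=float(fl.get("alpha2", 0.025)),
                              split_alpha=bool(fl.get("split_alpha", False)))
        dt = DecisionThresholds(efficacy_t=fl.get("efficacy_t"),
                                futility_f=fl.get("futility_f"))
        sc = Scenario(params=config.design, rule=config.rules[0],
                      n_h=n_h_grid[-1],
                      true_delta=float(fl.get("true_delta", 0.0)),
                      drift=float(fl.get("drift", 0.0)))
        summary = stage("flow", lambda: simulate_multistage(
            sc, dt, plan, int(fl.get("n_reps", 10_000)), config.seed))
        path = out / "flow_summary.json"
        path.write_text(json.dumps(asdict(summary), indent=2,
                                   sort_keys=True) + "\n")
        artifacts["flow_summary"] = path

    log = {"config_sha256": _config_hash(config), "seed": config.seed,
           "version": __version__,
           "numpy": np.__version__, "pandas": pd.__version__}
    path = out / "run_log.json"
    path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    artifacts["run_log"] = path
    return artifacts
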