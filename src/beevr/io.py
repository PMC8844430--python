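"""Tabular formats, run configuration and the end-to-end pipeline.

Everything tabular is CSV; reports are JSON plus a short human-readable
summary; run configurations are YAML or JSON with every omitted key filled
from the study's printed constants.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import behavior, qpcr, synth
from .errors import ConfigError, PipelineStageError, SchemaError
from .protocol import (
    EXCLUDED,
    LEARNER,
    NON_LEARNER,
    ProtocolConfig,
    classify_cohort,
    sessions_to_tables,
)
from .synth import AgentParams, CqSimDesign
from .vr_world import WorldConfig

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "RunConfig",
    "load_config",
    "run_pipeline",
]

# column name -> kind ("num" coerced to float, "int", "str")
SCHEMAS: dict[str, dict[str, str]] = {
    "sensor_log": {"t_s": "num", "ax": "num", "ay": "num", "bx": "num", "by": "num"},
    "trials": {
        "bee_id": "str", "trial": "int", "phase": "str", "cs_plus_side": "str",
        "first_choice": "str", "latency_s": "num", "freeze_s": "num", "iti_s": "num",
    },
    "trajectories": {
        "bee_id": "str", "trial": "int", "phase": "str",
        "t_s": "num", "x_cm": "num", "y_cm": "num", "heading_deg": "num",
    },
    "cq": {
        "bee_id": "str", "group": "str", "region": "str", "gene": "str",
        "replicate": "int", "cq": "num",
    },
    "expression": {
        "bee_id": "str", "group": "str", "region": "str", "gene": "str",
        "mean_cq": "num", "delta_cq": "num", "qr": "num",
        "normalization_factor": "num", "normalized_expression": "num",
        "qc_status": "str", "is_reference": "str", "flag": "str",
    },
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a CSV against a declared schema.

    Column set must match the schema (order is restored from it); malformed
    numeric cells raise a :class:`SchemaError` naming the column and the
    1-based file line. An empty file with a valid header is an empty table.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(spec) - set(df.columns)
    extra = set(df.columns) - set(spec)
    if missing or extra:
        raise SchemaError(
            f"{path}: columns do not match schema {schema!r} "
            f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
        )
    df = df[list(spec)]
    for col, kind in spec.items():
        if kind == "str":
            continue
        raw = df[col].replace("", np.nan)
        converted = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & converted.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"'{col}' at line {line}"
            )
        if kind == "int":
            df[col] = converted.astype("Int64")
        else:
            df[col] = converted.astype(float)
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write a table in its schema's column order."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    missing = set(spec) - set(df.columns)
    if missing:
        raise SchemaError(f"cannot write {schema!r}: missing columns {sorted(missing)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[list(spec)].to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Aggregate configuration of a full simulation + analysis run.

    All defaults equal the study's printed constants; any override is echoed
    in the run log/report.
    """

    world: WorldConfig = field(default_factory=WorldConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    learner_agent: AgentParams = field(default_factory=lambda: synth.LEARNER_AGENT)
    nonlearner_agent: AgentParams = field(default_factory=lambda: synth.NONLEARNER_AGENT)
    qpcr_design: CqSimDesign = field(default_factory=CqSimDesign)
    n_bees: int = 35
    learner_fraction: float = 0.5
    sd_threshold: float = 0.3
    nf_method: str = "geometric_mean"
    seed: int = 0
    outdir: str = "results"
    make_plots: bool = False


def _merge_dataclass(cls, defaults, data: dict[str, Any], path: str):
    """Recursively overlay a dict onto a (frozen) dataclass instance."""
    known = {f.name: f for f in fields(cls)}
    updates = {}
    for key, value in data.items():
        if key not in known:
            warnings.warn(f"unknown config key '{path}{key}' ignored", stacklevel=2)
            continue
        current = getattr(defaults, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            updates[key] = _merge_dataclass(type(current), current, value, f"{path}{key}.")
        else:
            updates[key] = _coerce(value, current, f"{path}{key}")
    try:
        return dataclasses.replace(defaults, **updates)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def _coerce(value, current, path: str):
    if isinstance(current, bool):
        if not isinstance(value, bool):
            raise ConfigError(f"{path}: expected bool, got {type(value).__name__}")
        return value
    if isinstance(current, int) and not isinstance(current, bool):
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"{path}: expected int, got {type(value).__name__}")
        return value
    if isinstance(current, float):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{path}: expected number, got {type(value).__name__}")
        return float(value)
    if isinstance(current, str):
        if not isinstance(value, str):
            raise ConfigError(f"{path}: expected string, got {type(value).__name__}")
        return value
    if isinstance(current, tuple):
        if not isinstance(value, (list, tuple)):
            raise ConfigError(f"{path}: expected list, got {type(value).__name__}")
        return tuple(value)
    if isinstance(current, dict):
        if not isinstance(value, dict):
            raise ConfigError(f"{path}: expected mapping, got {type(value).__name__}")
        return value
    return value


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON run configuration, filling omissions with defaults.

    Unknown keys warn; type mismatches raise :class:`ConfigError`. With no
    path, returns the all-defaults configuration (optionally overlaid with
    ``overrides``).
    """
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    if overrides:
        data = _deep_update(data, overrides)
    return _merge_dataclass(RunConfig, RunConfig(), data, "")


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def _config_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def clean(obj):
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, frozenset):
            return sorted(obj)
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return clean(d)


def run_pipeline(
    config: RunConfig, seed: int | None = None, outdir: str | Path | None = None
) -> dict:
    """Simulate, classify, analyze behavior, quantify expression, and report.

    Writes every intermediate table under ``outdir`` and returns the report
    dict (also written as report.json and report.txt). All randomness flows
    from one seed registry derived from ``seed``; a stage failure raises
    :class:`PipelineStageError` naming the stage, with earlier outputs
    preserved on disk.
    """
    seed = config.seed if seed is None else seed
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(
            ("behavior", "qpcr", "permutation"), ss.spawn(3)
        )
    }
    report: dict[str, Any] = {
        "seed": seed,
        "seed_registry": stage_seeds,
        "config": _config_dict(config),
    }

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc
        return wrap

    def _simulate():
        sessions, truth = synth.simulate_behavior_cohort(
            config.n_bees, config.learner_fraction,
            learner_params=config.learner_agent,
            nonlearner_params=config.nonlearner_agent,
            world=config.world, protocol=config.protocol,
            seed=stage_seeds["behavior"],
        )
        trials, trajectories = sessions_to_tables(sessions)
        write_table(trials, out / "trials.csv", "trials")
        write_table(trajectories, out / "trajectories.csv", "trajectories")
        truth.to_csv(out / "behavior_truth.csv", index=False)
        return sessions, trials, trajectories

    sessions, trials, trajectories = stage("simulate_behavior")(_simulate)

    def _classify():
        categories = classify_cohort(sessions, config.protocol)
        categories.to_csv(out / "categories.csv", index=False)
        counts = categories["category"].value_counts().to_dict()
        report["category_counts"] = {
            k: int(counts.get(k, 0)) for k in (LEARNER, NON_LEARNER, EXCLUDED)
        }
        return categories

    categories = stage("classify")(_classify)

    def _behavior():
        motor = behavior.motor_summary_table(trajectories, trials)
        motor.to_csv(out / "motor_summary.csv", index=False)
        curves = []
        for cat in (LEARNER, NON_LEARNER):
            ids = categories.loc[categories["category"] == cat, "bee_id"]
            sub = trials[trials["bee_id"].isin(ids)]
            if sub.empty:
                continue
            c = behavior.choice_proportions(sub)
            c.insert(0, "category", cat)
            curves.append(c)
        curve_df = pd.concat(curves, ignore_index=True) if curves else pd.DataFrame()
        curve_df.to_csv(out / "choice_curves.csv", index=False)
        stats: dict[str, Any] = {}
        kept = categories[categories["category"] != EXCLUDED]
        for cat in (LEARNER, NON_LEARNER):
            ids = categories.loc[categories["category"] == cat, "bee_id"]
            sub = trials[trials["bee_id"].isin(ids)]
            if sub["bee_id"].nunique() >= 2:
                stats[f"perm_p_cs_by_trial_{cat.lower()}"] = (
                    behavior.interaction_permutation_test(
                        sub, "cs", n_perm=999, seed=stage_seeds["permutation"]
                    )
                )
        if kept["category"].nunique() == 2:
            stats["perm_p_condition_by_trial"] = behavior.interaction_permutation_test(
                trials[trials["bee_id"].isin(kept["bee_id"])],
                "condition", categories=kept, n_perm=999,
                seed=stage_seeds["permutation"],
            )
        report["behavior_stats"] = stats
        (out / "stats_report.json").write_text(json.dumps(stats, indent=2))
        return motor, curve_df

    stage("behavior_analysis")(_behavior)

    def _simulate_qpcr():
        n_l = report["category_counts"][LEARNER]
        n_n = report["category_counts"][NON_LEARNER]
        design = config.qpcr_design
        if n_l >= 2 and n_n >= 2:
            design = dataclasses.replace(design, group_sizes=(n_l, n_n))
        cq, truth = synth.simulate_cq_dataset(design, seed=stage_seeds["qpcr"])
        write_table(cq.drop(columns=["is_outlier"]), out / "cq.csv", "cq")
        truth.to_csv(out / "qpcr_truth.csv", index=False)
        report["qpcr_group_sizes"] = list(design.group_sizes)
        return cq.drop(columns=["is_outlier"])

    cq = stage("simulate_qpcr")(_simulate_qpcr)

    def _analyze_qpcr():
        stability, policy = qpcr.reference_stability_test(
            cq, sd_threshold=config.sd_threshold
        )
        (out / "stability_report.json").write_text(
            json.dumps(
                {
                    "tests": stability.to_dict(orient="records"),
                    "policy": {r: sorted(g) for r, g in policy.items()},
                },
                indent=2,
            )
        )
        expr, qc_log = qpcr.normalized_expression_table(
            cq, policy=policy,
            sd_threshold=config.sd_threshold, nf_method=config.nf_method,
        )
        expr_out = expr.copy()
        expr_out["is_reference"] = expr_out["is_reference"].astype(str)
        write_table(expr_out, out / "expression.csv", "expression")
        discards = qc_log[qc_log["qc_status"] != qpcr.QC_PASS]
        report["qc_discard_log"] = discards.to_dict(orient="records")
        comparisons = qpcr.compare_all(expr)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        report["comparisons"] = comparisons.to_dict(orient="records")
        return expr, comparisons

    expr, comparisons = stage("analyze_qpcr")(_analyze_qpcr)

    if config.make_plots:
        def _plots():
            from . import plots
            curves = pd.read_csv(out / "choice_curves.csv")
            plots.learning_curves(curves, out / "learning_curves.png")
            plots.expression_boxplots(expr, out / "expression_boxplots.png")
        stage("plots")(_plots)

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (out / "report.txt").write_text(_format_report(report))
    return report


def _format_report(report: dict) -> str:
    lines = ["beevr pipeline report", "=====================", ""]
    lines.append(f"seed: {report['seed']}  (stage seeds: {report['seed_registry']})")
    cc = report.get("category_counts", {})
    lines.append(
        f"cohort: {cc.get(LEARNER, 0)} learners, {cc.get(NON_LEARNER, 0)} non-learners, "
        f"{cc.get(EXCLUDED, 0)} excluded"
    )
    for k, v in report.get("behavior_stats", {}).items():
        lines.append(f"  {k}: {v:.4f}")
    lines.append("")
    lines.append("gene x region comparisons (learner vs non-learner, pooled t):")
    for row in report.get("comparisons", []):
        star = " *" if row["p_value"] < 0.05 else ""
        lines.append(
            f"  {row['gene']:>8s} {row['region']:>3s}: t_{row['df']} = "
            f"{row['t_statistic']:+.2f}, p = {row['p_value']:.3f}, "
            f"fold change = {row['fold_change']:.2f}{star}"
        )
    n_disc = len(report.get("qc_discard_log", []))
    lines.append("")
    lines.append(f"QC: {n_disc} triplicates flagged (outlier dropped or discarded)")
    return "\n".join(lines) + "\n"
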