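"""End-to-end workflow: generate/load → indices → split → calibrate →
stage → evaluate → report.

A single seed governs all randomness; the generation and splitting stages
derive fixed offsets from it, so a (config, seed) pair reproduces every
artifact byte for byte. Each stage logs one structured line with its
input/output record counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .calibration import evaluate_model, fit_model, split_by_plot
from .consistency import consistency_table
from .core_data import Dataset, GROWTH_INDEX_NAMES, read_records, write_records
from .errors import ConfigError, WheatspecError
from .indices import VI_NAMES, append_indices
from .staged import (
    StagedModel,
    default_best_vi,
    default_period_map,
    evaluate_staged,
    fit_staged,
    PeriodMap,
)
from .synthetic import SyntheticConfig, generate_experiment, campaign_subsample
from .core_data import GrowthStage

__all__ = ["PipelineReport", "load_config", "run_pipeline",
           "compare_staged_vs_whole", "DEFAULT_CONFIG"]

log = logging.getLogger("wheatspec.pipeline")

#: Offset added to the master seed for the plot-split stage so that the
#: generator and the splitter never consume the same stream.
SPLIT_SEED_OFFSET = 101

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "input": {"synthetic": {}},
    "split": {"train_fraction": 0.7},
    "staged": {"fallback": "auto", "vi": {}, "period_map": {}},
}

_FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineReport:
    """All evaluation tables of one pipeline run."""

    seed: int
    config: dict
    dataset: Dataset
    whole_table: pd.DataFrame
    staged_table: pd.DataFrame
    consistency: Optional[pd.DataFrame]
    staged_models: dict[str, StagedModel]
    train_count: int
    validation_count: int


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config file must contain a mapping")
    return cfg


def _merge_config(user: Optional[dict]) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in (user or {}).items():
        # "input" is exclusive (csv XOR synthetic): replace, never merge
        if key != "input" and isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _build_dataset(cfg: dict, seed: int):
    inp = cfg.get("input") or {}
    has_csv = "csv" in inp and inp["csv"]
    has_synth = "synthetic" in inp and inp["synthetic"] is not None
    if has_csv and has_synth:
        raise ConfigError("config must specify either a csv input or a "
                          "synthetic block, not both")
    if has_csv:
        data = read_records(inp["csv"])
        log.info("stage=load input=%s records=%d", inp["csv"], len(data))
        return data, None
    synth = dict(inp.get("synthetic") or {})
    campaign_preset = bool(synth.pop("campaign_preset", False))
    valid = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(synth) - valid
    if unknown:
        raise ConfigError(f"unknown synthetic config key(s): {sorted(unknown)}")
    synth["seed"] = seed
    config = SyntheticConfig(**synth)
    data, paired = generate_experiment(config)
    if campaign_preset:
        data = campaign_subsample(data, seed=seed)
    log.info("stage=generate seed=%d records=%d plots=%d",
             seed, len(data), len(data.plot_ids))
    return data, paired


def _period_map_from_config(growth_index: str, spec: dict) -> PeriodMap:
    stages = [GrowthStage.from_token(s) for s in spec["period1"]]
    period1 = frozenset(stages)
    period2 = frozenset(set(GrowthStage) - period1)
    return PeriodMap(growth_index, period1, period2)


def run_pipeline(config: Optional[dict] = None, seed: Optional[int] = None,
                 out_dir=None) -> PipelineReport:
    """Run the full monitoring-model workflow and optionally write artifacts.

    ``seed`` overrides the config seed. Artifacts (dataset, model registry,
    evaluation tables, consistency table, JSON report, summary) are written
    when ``out_dir`` is given.
    """
    cfg = _merge_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])

    data, paired = _build_dataset(cfg, seed)
    split = split_by_plot(data, float(cfg["split"]["train_fraction"]),
                          seed=seed + SPLIT_SEED_OFFSET)
    log.info("stage=split train=%d validation=%d target=%d",
             len(split.train), len(split.validation), split.train_count_target)

    staged_cfg = cfg.get("staged") or {}
    fallback = staged_cfg.get("fallback", "auto")
    whole_rows, staged_rows = [], []
    staged_models: dict[str, StagedModel] = {}

    for gi in GROWTH_INDEX_NAMES:
        for vi_name in VI_NAMES:
            fit = fit_model(split.train, gi, vi_name)
            rep = evaluate_model(fit, split.validation)
            whole_rows.append({
                "growth_index": gi, "vi_name": vi_name,
                "coef_a": fit.coef_a, "coef_b": fit.coef_b,
                "cal_r2": fit.train_r2, "cal_rrmse": fit.train_rrmse,
                "val_r2": rep.r2, "val_rrmse": rep.rrmse,
                "n_train": fit.n_train, "n_val": rep.n,
            })
        vi_name = (staged_cfg.get("vi") or {}).get(gi) or default_best_vi(gi)
        pm_spec = (staged_cfg.get("period_map") or {}).get(gi)
        period_map = (_period_map_from_config(gi, pm_spec) if pm_spec
                      else default_period_map(gi))
        model = fit_staged(split.train, gi, vi_name, period_map,
                           fallback=fallback)
        rep = evaluate_staged(model, split.validation)
        staged_models[gi] = model
        staged_rows.append({
            "growth_index": gi, "vi_name": vi_name,
            "use_whole_in_p1": model.use_whole_in_p1,
            "use_whole_in_p2": model.use_whole_in_p2,
            "val_r2": rep.r2, "val_rrmse": rep.rrmse, "n_val": rep.n,
        })
        log.info("stage=model growth_index=%s vi=%s staged_val_r2=%.4f",
                 gi, vi_name, rep.r2)

    whole_table = pd.DataFrame(whole_rows)
    staged_table = pd.DataFrame(staged_rows)
    cons = consistency_table(paired) if paired is not None else None

    report = PipelineReport(
        seed=seed, config=cfg, dataset=data,
        whole_table=whole_table, staged_table=staged_table,
        consistency=cons, staged_models=staged_models,
        train_count=len(split.train), validation_count=len(split.validation),
    )
    if out_dir is not None:
        _write_artifacts(report, Path(out_dir))
    return report


def compare_staged_vs_whole(report: PipelineReport) -> dict[str, dict[str, float]]:
    """Per-growth-index (Δ validation R², Δ validation RRMSE): staged − whole,
    compared at the staged model's vegetation index."""
    if report.whole_table.empty or report.staged_table.empty:
        raise WheatspecError("report is missing a model family")
    out: dict[str, dict[str, float]] = {}
    for _, row in report.staged_table.iterrows():
        gi, vi = row["growth_index"], row["vi_name"]
        match = report.whole_table[
            (report.whole_table["growth_index"] == gi)
            & (report.whole_table["vi_name"] == vi)
        ]
        if match.empty:
            raise WheatspecError(f"no whole-period model for {gi}/{vi}")
        whole = match.iloc[0]
        out[gi] = {
            "delta_r2": float(row["val_r2"] - whole["val_r2"]),
            "delta_rrmse": float(row["val_rrmse"] - whole["val_rrmse"]),
        }
    return out


def _model_registry_lines(report: PipelineReport) -> list[str]:
    lines = []
    for _, row in report.whole_table.iterrows():
        key = f"whole.{row['growth_index']}.{row['vi_name']}"
        lines.append(f"{key}.a = {row['coef_a']:.10g}")
        lines.append(f"{key}.b = {row['coef_b']:.10g}")
        lines.append(f"{key}.n_train = {int(row['n_train'])}")
        lines.append(f"{key}.cal_r2 = {row['cal_r2']:.10g}")
        lines.append(f"{key}.cal_rrmse = {row['cal_rrmse']:.10g}")
    for gi, model in sorted(report.staged_models.items()):
        key = f"staged.{gi}.{model.vi_name}"
        for part, fit in (("whole", model.fit_whole), ("p1", model.fit_p1),
                          ("p2", model.fit_p2)):
            if fit is None:
                continue
            lines.append(f"{key}.{part}.a = {fit.coef_a:.10g}")
            lines.append(f"{key}.{part}.b = {fit.coef_b:.10g}")
        lines.append(f"{key}.use_whole_in_p1 = {model.use_whole_in_p1}")
        lines.append(f"{key}.use_whole_in_p2 = {model.use_whole_in_p2}")
    return lines


def _write_artifacts(report: PipelineReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_records(report.dataset, out_dir / "dataset.csv")
    append_indices(report.dataset.to_frame()).to_csv(
        out_dir / "dataset_with_indices.csv", index=False,
        float_format=_FLOAT_FORMAT)
    report.whole_table.to_csv(out_dir / "evaluation_whole.csv", index=False,
                              float_format=_FLOAT_FORMAT)
    report.staged_table.to_csv(out_dir / "evaluation_staged.csv", index=False,
                               float_format=_FLOAT_FORMAT)
    if report.consistency is not None:
        report.consistency.to_csv(out_dir / "consistency.csv", index=False,
                                  float_format=_FLOAT_FORMAT)
    (out_dir / "models.txt").write_text(
        "\n".join(_model_registry_lines(report)) + "\n", encoding="utf-8")

    deltas = compare_staged_vs_whole(report)
    machine = {
        "seed": report.seed,
        "config": report.config,
        "train_count": report.train_count,
        "validation_count": report.validation_count,
        "staged_vs_whole": deltas,
        "staged": report.staged_table.to_dict(orient="records"),
    }
    (out_dir / "report.json").write_text(
        json.dumps(machine, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8")

    lines = [
        f"wheatspec pipeline report (seed={report.seed})",
        f"records: {len(report.dataset)}  "
        f"train/validation: {report.train_count}/{report.validation_count}",
        "",
        "staged vs whole-period validation (delta = staged - whole):",
    ]
    for gi, d in deltas.items():
        row = report.staged_table[
            report.staged_table["growth_index"] == gi].iloc[0]
        lines.append(
            f"  {gi.upper():4s} vi={row['vi_name']:14s} "
            f"staged R2={row['val_r2']:.3f} RRMSE={row['val_rrmse']:.3f} "
            f"dR2={d['delta_r2']:+.3f} dRRMSE={d['delta_rrmse']:+.3f}"
        )
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n",
                                         encoding="utf-8")
    log.info("stage=write out_dir=%s", out_dir)
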