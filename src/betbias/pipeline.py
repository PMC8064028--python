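"""End-to-end pipeline: simulate -> fit -> analyze -> report.

Every stage reads and writes plain CSV so each is independently rerunnable;
a JSON manifest records seeds, versions and row counts.  All randomness
derives from one global seed: stage seeds are drawn from
``numpy.random.SeedSequence(global_seed)`` (cohort i gets child i), so the
whole run is idempotent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .task import TaskConfig, config_to_file
from .cohort import (AgentParams, CohortSpec, simulate_cohort, total_winnings,
                     write_cohort, read_cohort, control_spec, unilateral_spec,
                     bilateral_spec)
from .rwmodel import RWFit, fit_rw, fits_to_csv, traces_to_csv
from .regression import (prepare_predictors, fit_bet_model, fit_surprise_model,
                         MODEL_SPECS, results_to_csv, results_report)
from .summaries import cohort_winstay_table, bet_anova_2x2, winnings_by_bet_bin

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "demo_config",
           "load_config"]

_PRESETS = {"control": control_spec, "unilateral": unilateral_spec,
            "bilateral": bilateral_spec}


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs of earlier stages remain."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one full run.

    ``cohorts`` entries are either preset names (control / unilateral /
    bilateral, with optional ``n_subjects``) or full CohortSpec field
    mappings.  Per-cohort seeds are derived from ``seed``.
    """

    task: TaskConfig = field(default_factory=TaskConfig)
    cohorts: list[dict] = field(default_factory=list)
    n_starts: int = 10
    models: list[str] = field(default_factory=lambda: ["M1", "M2", "M3", "M4"])
    seed: int = 0

    def cohort_specs(self) -> list[CohortSpec]:
        children = np.random.SeedSequence(self.seed).spawn(max(len(self.cohorts), 1))
        specs = []
        for entry, child in zip(self.cohorts, children):
            entry = dict(entry)
            cohort_seed = int(child.generate_state(1)[0] % (2 ** 31))
            preset = entry.pop("preset", None)
            if preset is not None:
                spec = _PRESETS[preset](seed=cohort_seed, **entry)
            else:
                if "param_means" in entry:
                    entry["param_means"] = AgentParams(**entry["param_means"])
                spec = CohortSpec(seed=cohort_seed, **entry)
            specs.append(spec)
        return specs


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    task_kwargs = raw.get("task", {}) or {}
    for key in ("interval_lengths", "bet_money_values"):
        if key in task_kwargs:
            task_kwargs[key] = tuple(task_kwargs[key])
    return PipelineConfig(
        task=TaskConfig(**task_kwargs),
        cohorts=raw.get("cohorts", []),
        n_starts=int(raw.get("n_starts", 10)),
        models=list(raw.get("models", ["M1", "M2", "M3", "M4"])),
        seed=int(raw.get("seed", 0)),
    )


def demo_config(seed: int = 0) -> PipelineConfig:
    """Small three-group demonstration run (completes in well under a minute)."""
    return PipelineConfig(
        cohorts=[{"preset": "control", "n_subjects": 6},
                 {"preset": "unilateral", "n_subjects": 4},
                 {"preset": "bilateral", "n_subjects": 1}],
        n_starts=5,
        models=["M1", "M2", "M4", "M5", "S1", "S2"],
        seed=seed,
    )


def _simulate_stage(config: PipelineConfig, out: Path) -> list[pd.DataFrame]:
    sessions: list[pd.DataFrame] = []
    for spec in config.cohort_specs():
        sessions.extend(simulate_cohort(spec, config.task))
    write_cohort(sessions, out / "sessions")
    config_to_file(config.task, out / "task_config.yaml")
    return sessions


def _fit_stage(sessions: list[pd.DataFrame], config: PipelineConfig,
               out: Path) -> dict[str, RWFit]:
    fit_dir = out / "fits"
    fit_dir.mkdir(parents=True, exist_ok=True)
    fit_seed = int(np.random.SeedSequence(config.seed).generate_state(2)[1] % (2 ** 31))
    fits: dict[str, RWFit] = {}
    for s in sessions:
        sid = str(s["subject_id"].iloc[0])
        fits[sid] = fit_rw(s, n_starts=config.n_starts, seed=fit_seed)
    fits_to_csv(fits, fit_dir / "rw_fits.csv")
    traces_to_csv(fits, fit_dir / "value_traces.csv")
    return fits


def _analyze_stage(sessions: list[pd.DataFrame], fits: dict[str, RWFit],
                   config: PipelineConfig, out: Path):
    ana = out / "analysis"
    ana.mkdir(parents=True, exist_ok=True)
    traces = {sid: (f.q_chosen, f.q_unchosen) for sid, f in fits.items()}
    table = prepare_predictors(sessions, traces)
    table.to_csv(ana / "prepared_table.csv", index=False)
    results = []
    for name in config.models:
        if name not in MODEL_SPECS:
            raise ValueError(f"unknown model spec {name!r}")
        if name.startswith("S"):
            results.append(fit_surprise_model(table, group_interaction=name == "S2"))
        else:
            results.append(fit_bet_model(table, name))
    results_to_csv(results, ana / "model_results.csv")
    return table, results


def _summary_stage(sessions: list[pd.DataFrame], results, out: Path) -> str:
    summ = out / "summaries"
    summ.mkdir(parents=True, exist_ok=True)
    ws = cohort_winstay_table(sessions)
    ws.to_csv(summ / "winstay.csv", index=False)
    winnings = pd.DataFrame({
        "subject_id": [s["subject_id"].iloc[0] for s in sessions],
        "group_label": [s["group_label"].iloc[0] for s in sessions],
        "total_winnings": [total_winnings(s) for s in sessions],
        "mean_bet": [float(s["bet_level"].mean()) for s in sessions],
        "win_rate": [float(s["reward"].mean()) for s in sessions],
    })
    winnings.to_csv(summ / "winnings.csv", index=False)
    curves = pd.concat([winnings_by_bet_bin(s).rename(s["subject_id"].iloc[0])
                        for s in sessions], axis=1).T
    curves.index.name = "subject_id"
    curves.to_csv(summ / "winnings_by_bet.csv")

    lines = ["betbias pipeline report", "=" * 40, ""]
    lines.append(winnings.groupby("group_label")[["total_winnings", "mean_bet",
                                                  "win_rate"]]
                 .agg(["mean", "median"]).round(3).to_string())
    lines.append("")
    full = ws.dropna(subset=[f"mean_bet_{c}" for c in
                             ("win_stay", "win_switch", "lose_stay", "lose_switch")])
    if len(full) >= 2:
        lines.append("2x2 previous-win x stay ANOVA on bet cell means:")
        lines.append(bet_anova_2x2(ws).round(4).to_string(index=False))
        lines.append("")
    lines.append(results_report(results))
    report = "\n".join(lines)
    (out / "report.txt").write_text(report)
    return report


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run simulate -> fit -> analyze -> summarize; returns the output dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "models": config.models}
    try:
        logger.info("stage: simulate")
        sessions = _simulate_stage(config, out)
        manifest["n_subjects"] = len(sessions)
        manifest["n_trials_total"] = int(sum(len(s) for s in sessions))
    except Exception as e:  # noqa: BLE001 - stage-tagged rethrow
        raise StageError("simulate", e) from e
    try:
        logger.info("stage: fit")
        fits = _fit_stage(sessions, config, out)
    except Exception as e:
        raise StageError("fit", e) from e
    try:
        logger.info("stage: analyze")
        table, results = _analyze_stage(sessions, fits, config, out)
        manifest["analysis_rows"] = len(table)
        manifest["model_rows"] = {r.name: r.n_rows for r in results}
    except Exception as e:
        raise StageError("analyze", e) from e
    try:
        logger.info("stage: summarize")
        _summary_stage(sessions, results, out)
    except Exception as e:
        raise StageError("summarize", e) from e
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
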