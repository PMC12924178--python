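"""End-to-end orchestration on synthetic data.

``run_end_to_end`` chains every stage — simulate, feature-engineer, split,
tune/train, evaluate, inter-fraction variability, Shapley explanation,
repainting cumulative-time reconstruction, interplay phase mapping — and
writes a single JSON report plus the intermediate artifacts.  Every random
draw derives from the master seed through fixed per-stage offsets, so any
stage can be rerun in isolation and two runs with the same configuration
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import applications, explain, logio
from .config import MachineConfig, load_config
from .features import build_feature_table, stratified_split
from .machine import generate_plan, make_repainted_plan, simulate_course, simulate_fraction
from .model import DeliveryTimeModel, interfraction_variability

__all__ = ["RunConfig", "run_end_to_end", "STAGE_SEED_OFFSETS"]

#: Per-stage sub-seed offsets from the master seed.
STAGE_SEED_OFFSETS = {
    "plan": 1,
    "course": 2,
    "split": 3,
    "fit": 4,
    "explain": 5,
    "repaint_plan": 6,
    "repaint_fraction": 7,
    "interplay_plan": 8,
    "interplay_course": 9,
}


@dataclass
class RunConfig:
    """Settings for an end-to-end synthetic study."""

    seed: int = 0
    machine_config_path: str | None = None
    n_beams: int = 4
    n_layers_per_beam: int = 10
    spots_per_layer: int = 64
    n_fractions: int = 11
    train_frac: float = 0.7
    split_bins: int = 10
    cv_folds: int = 5
    n_candidates: int = 6
    explain_samples: int = 100
    explain_background: int = 64
    grouping: dict | None = None
    n_repaints: int = 5
    interplay_fractions: int = 10
    interplay_periods: tuple = (2.0, 4.0, 5.0)
    n_phases: int = 10
    output_dir: str = "protonbdt_run"

    def sub_seed(self, stage: str) -> int:
        return int(self.seed) + STAGE_SEED_OFFSETS[stage]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def run_end_to_end(run: RunConfig) -> dict:
    """Execute the full synthetic study; returns the report dictionary.

    Artifacts (plan, logs, feature table, model, report.json) are written
    under ``run.output_dir`` as each stage completes, so a failing stage
    leaves the earlier artifacts in place; failures are re-raised with the
    stage name attached.
    """
    out = Path(run.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = (load_config(run.machine_config_path)
              if run.machine_config_path else MachineConfig())
    report: dict = {"seed": run.seed, "config": config.to_dict(),
                    "stages": {}}
    stage = "simulate"
    try:
        plan = generate_plan(run.sub_seed("plan"), run.n_beams,
                             run.n_layers_per_beam, run.spots_per_layer, config)
        logio.write_plan(plan, out / "plan.csv", config)
        logs = simulate_course(plan, run.n_fractions, run.sub_seed("course"), config)
        logio.write_log(logs, out / "logs.csv", config)
        report["stages"]["simulate"] = {
            "n_spots": len(plan), "n_pulses": int(len(logs)),
            "n_fractions": run.n_fractions}

        stage = "features"
        table = build_feature_table(logs, config)
        table.to_csv(out / "features.csv", index=False)
        report["stages"]["features"] = {"n_transitions": len(table)}

        stage = "split"
        train, test = stratified_split(table, run.train_frac, run.split_bins,
                                       run.sub_seed("split"))
        report["stages"]["split"] = {"n_train": len(train), "n_test": len(test)}

        stage = "train"
        model = DeliveryTimeModel(train)
        results = model.fit(seed=run.sub_seed("fit"), cv_folds=run.cv_folds,
                            n_candidates=run.n_candidates)
        results.save(out / "model.joblib")
        report["stages"]["train"] = {"best_params": _jsonable(results.best_params)}

        stage = "evaluate"
        metrics = results.interval_metrics(test)
        report["stages"]["evaluate"] = {"interval_metrics": metrics}

        stage = "variability"
        var = interfraction_variability(logs)
        report["stages"]["variability"] = {
            "metrics": var["metrics"],
            "within_band_fraction": var["within_band_fraction"],
            "band_ms": var["band_ms"]}

        stage = "explain"
        sample = explain.sample_for_explanation(test, run.explain_samples,
                                                run.sub_seed("explain"))
        rng = np.random.default_rng(run.sub_seed("explain"))
        bg_idx = rng.choice(len(train), size=min(run.explain_background, len(train)),
                            replace=False)
        background = train.iloc[np.sort(bg_idx)]
        grouping = run.grouping or explain.DEFAULT_GROUPS
        attr = results.shapley(sample, background, grouping=grouping)
        summary = explain.importance_summary(attr, results.predict(sample))
        report["stages"]["explain"] = {
            "global_mean_abs": summary["global_mean_abs"],
            "per_bin_max_abs": summary["per_bin_max_abs"],
            "n_samples": len(sample)}

        stage = "cumulative"
        held_plan = generate_plan(run.sub_seed("repaint_plan"), 1,
                                  run.n_layers_per_beam, run.spots_per_layer,
                                  config, beam_prefix="r")
        repainted = make_repainted_plan(held_plan, run.n_repaints, config)
        ref_log = simulate_fraction(repainted, run.sub_seed("repaint_fraction"),
                                    config, fraction_id="dryrun")
        ref_table = build_feature_table(ref_log, config)
        comparison = applications.compare_timing_sources(
            ref_table["delta_t"], results.predict(ref_table),
            beam_ids=ref_table["beam_id"], pulse_index=ref_table["pulse_index"])
        report["stages"]["cumulative"] = {
            "n_repaints": run.n_repaints,
            "total_reference_ms": comparison.total_reference_ms,
            "total_predicted_ms": comparison.total_predicted_ms,
            "relative_deviation": comparison.relative_deviation}

        stage = "interplay"
        ip_plan = generate_plan(run.sub_seed("interplay_plan"), 1,
                                run.n_layers_per_beam, run.spots_per_layer,
                                config, beam_prefix="i")
        ip_logs = simulate_course(ip_plan, run.interplay_fractions,
                                  run.sub_seed("interplay_course"), config)
        ip = applications.interplay_experiment(
            ip_plan, results, ip_logs, periods_s=run.interplay_periods,
            n_phases=run.n_phases, config=config)
        report["stages"]["interplay"] = {"summary": ip}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report
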