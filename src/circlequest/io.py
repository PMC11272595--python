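"""File formats, run configuration, and the simulate/analyze drivers.

Artifact formats are plain text: stimulus files are JSON
(``{"space": {...}, "dots": [...], "true_center": [...]}``), trial logs and
fitted estimates are UTF-8 comma-separated CSV with a header row and fixed
column order, and every simulation run writes a manifest (package version,
seed, config hash) so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .agents import CohortConfig, default_cohort_config, simulate_cohort
from .analysis import (
    fit_choice_sensitivities,
    group_contrast,
    oversampling_metrics,
    uncertainty_estimation_accuracy,
)
from .geometry import SampleObservation, SearchSpace
from .schedules import PassiveStimulus, TrialSpec

__all__ = [
    "RunConfig",
    "write_stimulus_json",
    "read_stimulus_json",
    "schedule_to_frame",
    "run_simulation",
    "run_analysis",
]


class RunConfig(BaseModel):
    """Configuration of one simulation run; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    experiment: str = "exp2"
    width: float = 1280.0
    height: float = 715.0
    circle_radius: float = 130.0
    grid_step: float = 4.0
    n_per_group: int = Field(default=19, ge=1)
    seed: int = 0
    out_dir: str = "runs/default"
    verbose: bool = False

    def space(self) -> SearchSpace:
        return SearchSpace(
            width=self.width,
            height=self.height,
            circle_radius=self.circle_radius,
            grid_step=self.grid_step,
        )

    def cohort(self) -> CohortConfig:
        return default_cohort_config(n_per_group=self.n_per_group, seed=self.seed)


def write_stimulus_json(path: str | Path, stimulus: PassiveStimulus,
                        space: SearchSpace) -> None:
    payload = {
        "space": {
            "width": space.width,
            "height": space.height,
            "radius": space.circle_radius,
        },
        "dots": [
            {"x": d.x, "y": d.y, "label": d.label} for d in stimulus.dots
        ],
        "true_center": list(stimulus.true_center),
        "achieved_ee": stimulus.achieved_ee,
        "ee_band": list(stimulus.ee_band),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_stimulus_json(path: str | Path) -> tuple[SearchSpace, list[SampleObservation], dict]:
    """Read a stimulus file; returns (space, dots, extras)."""
    payload = json.loads(Path(path).read_text())
    sp = payload["space"]
    space = SearchSpace(
        width=sp["width"], height=sp["height"], circle_radius=sp["radius"]
    )
    dots = [
        SampleObservation(d["x"], d["y"], d["label"]) for d in payload["dots"]
    ]
    extras = {k: v for k, v in payload.items() if k not in ("space", "dots")}
    return space, dots, extras


_SCHEDULE_COLUMNS = [
    "trial_index", "experiment", "block", "reward", "effort", "ee_lo",
    "ee_hi", "ee_nominal", "uncertainty_present", "reserve", "sampling_cost",
    "is_catch",
]


def schedule_to_frame(trials: list[TrialSpec]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append(
            {
                "trial_index": t.trial_index,
                "experiment": t.experiment,
                "block": t.block,
                "reward": t.reward,
                "effort": t.effort,
                "ee_lo": t.ee_band[0] if t.ee_band else None,
                "ee_hi": t.ee_band[1] if t.ee_band else None,
                "ee_nominal": t.ee_nominal,
                "uncertainty_present": t.uncertainty_present,
                "reserve": t.reserve,
                "sampling_cost": t.sampling_cost,
                "is_catch": t.is_catch,
            }
        )
    return pd.DataFrame(rows, columns=_SCHEDULE_COLUMNS)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_simulation(config: RunConfig) -> Path:
    """Simulate a cohort and write all artefact tables plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = simulate_cohort(
        config.cohort(), config.experiment, space=config.space()
    )
    for name, df in tables.items():
        _write_csv(df, out / f"{name}.csv")
    manifest = {
        "package": "circlequest",
        "version": __version__,
        "experiment": config.experiment,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "tables": sorted(tables),
        "n_per_group": config.n_per_group,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def run_analysis(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Analyze a simulation directory; writes and returns report tables."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    experiment = manifest["experiment"]
    reports: dict[str, pd.DataFrame] = {}
    contrasts: list[dict] = []

    choices_path = run_dir / "choices.csv"
    if choices_path.exists():
        choices = pd.read_csv(choices_path)
        _require_columns(choices, ["subject_id", "accepted", "reward"], "choices.csv")
        sens = fit_choice_sensitivities(choices, experiment)
        reports["sensitivities"] = sens
        for coef in ("reward", "uncertainty", "effort"):
            if coef in sens.columns and sens[coef].notna().any():
                c = group_contrast(
                    sens[coef], sens["group"], metric=f"{coef}_sensitivity"
                )
                contrasts.append(_contrast_row(c))

    conf_path = run_dir / "confidence.csv"
    if conf_path.exists():
        conf = pd.read_csv(conf_path)
        _require_columns(conf, ["subject_id", "ee", "confidence"], "confidence.csv")
        acc = uncertainty_estimation_accuracy(conf)
        reports["estimation_accuracy"] = acc
        c = group_contrast(acc["slope"], acc["group"], metric="estimation_accuracy")
        contrasts.append(_contrast_row(c))

    sampling_path = run_dir / "sampling.csv"
    if sampling_path.exists():
        sampling = pd.read_csv(sampling_path)
        _require_columns(
            sampling,
            ["subject_id", "trial_id", "sample_index", "ee_after"],
            "sampling.csv",
        )
        cells, index = oversampling_metrics(sampling)
        reports["oversampling_cells"] = cells
        reports["cost_sensitivity"] = index
        c = group_contrast(
            index["cost_sensitivity_index"], index["group"],
            metric="cost_sensitivity_index",
        )
        contrasts.append(_contrast_row(c))

    if contrasts:
        reports["contrasts"] = pd.DataFrame(contrasts)
    for name, df in reports.items():
        _write_csv(df, run_dir / f"{name}.csv")
    return reports


def _contrast_row(c) -> dict:
    return {
        "metric": c.metric,
        "group_a": c.group_names[0],
        "group_b": c.group_names[1],
        "mean_a": c.means[0],
        "mean_b": c.means[1],
        "test": c.test,
        "statistic": c.statistic,
        "p_value": c.p_value,
        "effect_size": c.effect_size,
    }


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing required column(s): {missing}")
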