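"""Declarative configuration, analysis driver, and report writing.

A :class:`Config` document captures everything needed to reproduce an
experiment (experiment preset, training hyperparameters, classifier
thresholds, observation geometry) and round-trips losslessly through YAML.
Unknown keys are rejected and validation errors name the offending key.

:func:`analyze_experiment` runs the complete analysis stack over a
collection of run logs (CR scoring, cell-type classification, pooled
population-vector correlations), and :func:`write_report` persists tidy CSV
tables, figures, and a machine-readable metrics file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import behavior
from .agent import TrainingConfig
from .maze import MazeGraph, ObservationSpec, build_tmaze
from .placefields import CELL_LABELS, ClassifierParams, label_fractions
from .protocols import (
    RECORDING_POINTS,
    ExperimentSpec,
    RunLog,
    classify_run,
    cr_matrix,
    standard_spec,
)
from .remapping import DEFAULT_PAIRS, pooled_pv_correlations

__all__ = ["Config", "load_config", "save_config", "analyze_experiment", "write_report"]

SCHEMA_VERSION = "1.0"


class _ExperimentSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str = "aba_extinction"
    salience: float = Field(1.0, ge=0.0, le=1.0)
    n_trials_per_phase: int = Field(200, gt=0)
    n_runs: int = Field(20, gt=0)
    base_seed: int = 1234
    trial_cap: int = Field(400, gt=0)
    context_mode: str = "lighting"
    replay_mode: str = "full_history"


class _TrainingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gamma: float = Field(0.8, gt=0.0, lt=1.0)
    epsilon: float = Field(0.3, ge=0.0, le=1.0)
    adam_learning_rate: float = Field(1e-4, gt=0.0)
    batch_size: int = Field(32, gt=0)
    updates_per_env_step: int = Field(1, gt=0)


class _ClassifierSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    context_tolerance: float = Field(0.0005, gt=0.0)
    smoothing_sd: float = Field(2.0, gt=0.0)
    cluster_activity_threshold: float = Field(0.5, gt=0.0)
    max_cluster_count: int = Field(2, gt=0)
    max_active_fraction: float = Field(0.5, gt=0.0)
    center_coherence_limit: float = Field(4.0, gt=0.0)


class _ObservationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    width: int = 80
    height: int = 20
    channels: int = 3
    fov_deg: float = 240.0
    pos_jitter_sd: float = 0.01
    ang_jitter_sd: float = 10.0


class Config(BaseModel):
    """Full declarative experiment configuration."""

    model_config = ConfigDict(extra="forbid")
    version: str = SCHEMA_VERSION
    experiment: _ExperimentSection = _ExperimentSection()
    training: _TrainingSection = _TrainingSection()
    classifier: _ClassifierSection = _ClassifierSection()
    observation: _ObservationSection = _ObservationSection()

    def experiment_spec(self) -> ExperimentSpec:
        e = self.experiment
        return standard_spec(
            e.name,
            salience=e.salience,
            n_trials_per_phase=e.n_trials_per_phase,
            n_runs=e.n_runs,
            base_seed=e.base_seed,
            trial_cap=e.trial_cap,
            training=TrainingConfig(**self.training.model_dump()),
            obs_spec=ObservationSpec(**self.observation.model_dump()),
            **({"context_mode": e.context_mode} if e.name != "explicit_context" else {}),
            **({"replay_mode": e.replay_mode} if e.name != "no_replay" else {}),
        )

    def classifier_params(self) -> ClassifierParams:
        return ClassifierParams(**self.classifier.model_dump())


def load_config(path) -> Config:
    """Read and validate a YAML config; defaults fill missing sections."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return Config(**data)
    except ValidationError:
        raise


def save_config(cfg: Config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Analysis driver
# ---------------------------------------------------------------------------


def analyze_experiment(
    logs: Sequence[RunLog],
    params: ClassifierParams = ClassifierParams(),
    maze: Optional[MazeGraph] = None,
    pairs=DEFAULT_PAIRS,
) -> dict:
    """Run behavior, classification, and remapping analyses over run logs.

    Returns a dict with the CRC, per-run renewal indices, per-run cell-type
    classifications, per-layer pooled :class:`RemapSummary`, and a tidy
    cell-fraction table.
    """
    if not logs:
        raise ValueError("empty run collection")
    maze = maze if maze is not None else build_tmaze()
    ind = cr_matrix(logs)
    crc = behavior.cumulative_response_curve(ind)
    phase_lengths = logs[0].spec.phase_lengths
    renewal = None
    if len(phase_lengths) == 3 and min(phase_lengths[1:]) >= behavior.RENEWAL_WINDOW_TRIALS:
        renewal = behavior.renewal_index(ind, phase_lengths)

    classifications = [classify_run(lg, params, maze) for lg in logs]
    n_layers = len(logs[0].activity[(1, "A")])

    summaries = []
    for layer in range(1, n_layers + 1):
        maps_by_run = [
            {lab: lg.maps(lab, layer) for lab in RECORDING_POINTS}
            for lg in logs
        ]
        cls_by_run = [
            {lab: cls[lab][layer - 1] for lab in RECORDING_POINTS}
            for cls in classifications
        ]
        summaries.append(
            pooled_pv_correlations(maps_by_run, cls_by_run, layer, maze, pairs=pairs)
        )

    rows = []
    for run_i, cls in enumerate(classifications):
        for lab in RECORDING_POINTS:
            for layer in range(1, n_layers + 1):
                fr = label_fractions(cls[lab][layer - 1])
                for cell_type, frac in fr.items():
                    rows.append(
                        (run_i, lab, layer, cell_type, frac)
                    )
    fractions = pd.DataFrame(
        rows, columns=["run", "condition", "layer", "cell_type", "fraction"]
    )

    return {
        "crc": crc,
        "renewal": renewal,
        "classifications": classifications,
        "remap": summaries,
        "fractions": fractions,
        "phase_lengths": phase_lengths,
    }


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------


def _crc_frame(crc, phase_lengths) -> pd.DataFrame:
    n = len(crc.response_rate)
    phase = np.empty(n, dtype=int)
    start = 0
    for i, w in enumerate(phase_lengths, start=1):
        phase[start : start + w] = i
        start += w
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "phase": phase,
            "mean_cr": crc.response_rate,
            "sd_cr": crc.indicator.std(axis=0),
            "cum_mean": crc.cum_mean,
            "cum_sd": crc.cum_sd,
        }
    )


def write_report(logs: Sequence[RunLog], analysis: dict, outdir,
                 figures: bool = True) -> list:
    """Persist CSV tables, figures, and metrics.json; returns written paths.

    Fails before writing anything if the run collection is empty.
    """
    if not logs:
        raise ValueError("empty run collection: nothing to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    crc_df = _crc_frame(analysis["crc"], analysis["phase_lengths"])
    p = outdir / "crc.csv"
    crc_df.to_csv(p, index=False)
    written.append(p)

    p = outdir / "cell_fractions.csv"
    analysis["fractions"].to_csv(p, index=False)
    written.append(p)

    rows = []
    for summ in analysis["remap"]:
        for pair, mean_r in summ.mean_correlation.items():
            rows.append(
                (summ.layer_index, f"{pair[0]}-{pair[1]}", mean_r,
                 summ.n_dropped_nodes[pair], len(summ.distances[pair]),
                 float(np.mean(summ.distances[pair])) if len(summ.distances[pair]) else np.nan)
            )
    corr_df = pd.DataFrame(
        rows,
        columns=["layer", "pair", "mean_corr", "n_dropped_nodes",
                 "n_shared_place_cells", "mean_center_distance"],
    )
    p = outdir / "correlations.csv"
    corr_df.to_csv(p, index=False)
    written.append(p)

    metrics = {
        "version": SCHEMA_VERSION,
        "n_runs": len(logs),
        "renewal_index": (
            None if analysis["renewal"] is None
            else [float(x) for x in analysis["renewal"]]
        ),
        "mean_correlations": {
            f"layer{summ.layer_index}": {
                f"{a}-{b}": float(summ.mean_correlation[(a, b)])
                for (a, b) in summ.mean_correlation
            }
            for summ in analysis["remap"]
        },
        "cell_fractions": _fraction_metrics(analysis["fractions"]),
    }
    p = outdir / "metrics.json"
    with open(p, "w") as fh:
        json.dump(metrics, fh, indent=2)
    written.append(p)

    if figures:
        written.extend(_write_figures(analysis, outdir))
    return written


def _fraction_metrics(fractions: pd.DataFrame) -> dict:
    means = fractions.groupby(["layer", "condition", "cell_type"])["fraction"].mean()
    out: dict = {}
    for (layer, cond, ct), val in means.items():
        out.setdefault(f"layer{layer}", {}).setdefault(cond, {})[ct] = float(val)
    return out


def _write_figures(analysis: dict, outdir: Path) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    crc = analysis["crc"]
    fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    trials = np.arange(len(crc.cum_mean))
    axes[0].plot(trials, crc.cum_mean, color="C0")
    axes[0].fill_between(trials, crc.cum_mean - crc.cum_sd,
                         crc.cum_mean + crc.cum_sd, alpha=0.3)
    axes[0].set_ylabel("cumulative CR")
    axes[1].plot(trials, crc.response_rate, color="C1")
    axes[1].set_ylabel("CR rate")
    axes[1].set_xlabel("trial")
    b = 0
    for w in analysis["phase_lengths"][:-1]:
        b += w
        for ax in axes:
            ax.axvline(b, color="k", ls="--", lw=0.8)
    fig.tight_layout()
    p = outdir / "crc.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(7, 4))
    pairs = list(analysis["remap"][0].mean_correlation)
    x = np.arange(len(pairs))
    width = 0.8 / len(analysis["remap"])
    for i, summ in enumerate(analysis["remap"]):
        vals = [summ.mean_correlation[pr] for pr in pairs]
        ax.bar(x + i * width, vals, width, label=f"layer {summ.layer_index}")
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels([f"{a}-{b}" for a, b in pairs])
    ax.set_ylabel("mean PV correlation")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = outdir / "pv_correlations.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
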