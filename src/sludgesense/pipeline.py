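"""End-to-end reproducible pipeline: simulate -> dataset -> train -> evaluate.

Each stage writes its artifacts under an output directory and records them in
``manifest.json`` (config hash, stage seeds, library versions, content hash
per file), so a run is reproducible from its manifest and configuration
alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asm1 import write_trajectory, read_trajectory
from .config import RunConfig, derive_seed
from .dataset import apply_measurement_noise, build_datasets
from .influent import dataset_stats, simulate_from_config
from .metrics import comparison_table, evaluate_model
from .model import SoftSensorModel
from .nn import ffnn as ffnn_mod
from .nn import lstm as lstm_mod

__all__ = ["run_simulate", "run_make_dataset", "run_train", "run_evaluate",
           "full_run", "Manifest"]

logger = logging.getLogger(__name__)


class Manifest:
    """Accumulates artifact hashes and run metadata for one output directory."""

    def __init__(self, out: Path, config: RunConfig):
        self.out = Path(out)
        self.out.mkdir(parents=True, exist_ok=True)
        cfg_yaml = json.dumps(config.to_dict(), sort_keys=True, default=float)
        self.data = {
            "package_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
            "seed": config.seed,
            "stage_seeds": {
                "influent": config.influent.seed,
                "lstm": config.lstm.seed,
                "ffnn": config.ffnn.seed,
            },
            "files": {},
        }

    def record(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.data["files"][str(Path(path).relative_to(self.out))] = digest

    def save(self) -> None:
        (self.out / "manifest.json").write_text(
            json.dumps(self.data, indent=2, sort_keys=True))


def run_simulate(config: RunConfig, out) -> pd.DataFrame:
    """Simulate the plant and write ``trajectory.csv`` plus its statistics."""
    out = Path(out)
    manifest = Manifest(out, config)
    traj = simulate_from_config(config)
    write_trajectory(traj, out / "trajectory.csv")
    stats = dataset_stats(traj.iloc[1:])
    stats.to_csv(out / "dataset_stats.csv")
    manifest.record(out / "trajectory.csv")
    manifest.record(out / "dataset_stats.csv")
    manifest.save()
    logger.info("simulated %d steps -> %s", len(traj) - 1, out)
    return traj


def _recorded_rows(config: RunConfig, traj: pd.DataFrame) -> pd.DataFrame:
    return apply_measurement_noise(
        traj.reset_index(drop=True),
        config.influent.measurement_noise_sd,
        derive_seed(config.influent.seed, "measurement-noise"))


def run_make_dataset(config: RunConfig, out, traj: pd.DataFrame | None = None):
    """Window the recorded (noisy) dataset and export the supervised pairs."""
    out = Path(out)
    if traj is None:
        traj_path = out / "trajectory.csv"
        traj = (read_trajectory(traj_path) if traj_path.exists()
                else run_simulate(config, out))
    rows = _recorded_rows(config, traj)
    splits = build_datasets(rows, config.dataset)
    manifest = Manifest(out, config)
    for name, ds in zip(("train", "val", "test"), splits):
        ds.export(out / name)
        for f in ("inputs.csv", "targets.csv", "scaler.json"):
            manifest.record(out / name / f)
    manifest.save()
    logger.info("dataset windows: train=%d val=%d test=%d",
                *(d.n_samples for d in splits))
    return splits


def _build_model(config: RunConfig) -> SoftSensorModel:
    model = SoftSensorModel.from_config(config)
    return model


def run_train(config: RunConfig, model_kind: str, out):
    """Train one estimator; write weights (HDF5) and training history (CSV)."""
    out = Path(out)
    manifest = Manifest(out, config)
    model = _build_model(config)
    if model_kind == "lstm":
        hp = replace(config.lstm, lookback=config.dataset.lookback)
        results = model.fit("lstm", hyperparams=hp)
        lstm_mod.save_weights_h5(results.trained, out / "lstm_weights.h5")
        results.history.to_csv(out / "lstm_history.csv", index=False)
        manifest.record(out / "lstm_history.csv")
    elif model_kind == "ffnn":
        results = model.fit("ffnn", hyperparams=config.ffnn)
        ffnn_mod.save_weights_h5(results.trained[0], out / "ffnn_weights.h5")
        results.history.to_csv(out / "ffnn_history.csv", index=False)
        manifest.record(out / "ffnn_history.csv")
    else:
        raise ValueError(f"unknown model kind: {model_kind!r}")
    manifest.save()
    return results


def run_evaluate(config: RunConfig, results_list, out):
    """Write the metrics report and per-model predictions."""
    out = Path(out)
    manifest = Manifest(out, config)
    report = pd.concat([r.metrics for r in results_list], ignore_index=True)
    report.to_csv(out / "metrics.csv", index=False, float_format="%.10g")
    manifest.record(out / "metrics.csv")
    for r in results_list:
        pred = pd.DataFrame(r.predictions, columns=["X1_hat", "X2_hat"])
        pred["X1"] = r.observations[:, 0]
        pred["X2"] = r.observations[:, 1]
        series, frac, _ = r.tcod_prediction()
        pred["TCOD_hat"] = series
        pred.to_csv(out / f"predictions_{r.method}.csv", index=False)
        manifest.record(out / f"predictions_{r.method}.csv")
        logger.info("%s: TCOD compliance fraction %.3f", r.method, frac)
    manifest.save()
    print(comparison_table(report))
    return report


def full_run(config: RunConfig, out, make_plots: bool = True):
    """Chain all stages: simulate, window, train both estimators, evaluate."""
    out = Path(out)
    traj = run_simulate(config, out)
    run_make_dataset(config, out, traj)
    results = [run_train(config, kind, out) for kind in ("lstm", "ffnn")]
    report = run_evaluate(config, results, out)
    if make_plots:
        from .plots import make_figures
        make_figures(results, out)
    return report, results
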