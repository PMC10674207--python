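"""Model/Results interface over the soft-sensor estimators.

Follows the statsmodels convention: a :class:`SoftSensorModel` is built from
data (a state frame with columns X1..X5, typically produced by the plant
simulator), ``fit()`` trains the requested estimator and returns a
:class:`SoftSensorResults` carrying predictions, per-variable metrics, the
training history and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .config import (DatasetConfig, EvaluationConfig, FFNNConfig, RunConfig,
                     SoftSensorHyperparams)
from .dataset import TARGET_CHANNELS, WindowedDataset, build_datasets, denormalize
from .metrics import evaluate_model, tcod_track
from .nn import ffnn as ffnn_mod
from .nn import lstm as lstm_mod

__all__ = ["SoftSensorModel", "SoftSensorResults"]


def _ffnn_inputs(windows: WindowedDataset, hp: FFNNConfig) -> np.ndarray:
    """Baseline inputs: the current measurement (a feed-forward net has no
    notion of history) or, optionally, the full flattened window."""
    if hp.input_mode == "current":
        return windows.inputs[:, -1, :]
    return windows.flattened_inputs()


class SoftSensorModel:
    """Soft sensor for the unmeasured substrates of an activated-sludge plant.

    Parameters
    ----------
    data
        State frame in original units with columns ``X1..X5`` (one row per
        sampling instant, chronological).  Use
        :func:`sludgesense.influent.simulate_from_config` +
        :func:`sludgesense.dataset.apply_measurement_noise` to produce one,
        or :meth:`from_config` to do both.
    dataset
        Windowing/split settings (lookback, chronological split sizes).
    """

    def __init__(self, data: pd.DataFrame,
                 dataset: DatasetConfig | None = None,
                 evaluation: EvaluationConfig | None = None):
        missing = {"X1", "X2", "X3", "X4", "X5"} - set(data.columns)
        if missing:
            raise ValueError(f"data lacks state column(s) {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        self.dataset_config = dataset or DatasetConfig(n_samples=len(data))
        self.evaluation = evaluation or EvaluationConfig()
        self.train, self.val, self.test = build_datasets(
            self.data, self.dataset_config)

    @classmethod
    def from_config(cls, config: RunConfig) -> "SoftSensorModel":
        """Simulate the plant under ``config`` and wrap the recorded dataset."""
        from .dataset import apply_measurement_noise
        from .influent import simulate_from_config
        from .config import derive_seed

        traj = simulate_from_config(config)
        rows = apply_measurement_noise(
            traj, config.influent.measurement_noise_sd,
            derive_seed(config.influent.seed, "measurement-noise"))
        model = cls(rows, config.dataset,
                    replace(config.evaluation, Is=config.plant.Is))
        model.trajectory = traj
        return model

    def fit(self, method: Literal["lstm", "ffnn"] = "lstm",
            hyperparams: SoftSensorHyperparams | FFNNConfig | None = None,
            **overrides) -> "SoftSensorResults":
        """Train an estimator and evaluate it on the held-out test block.

        ``overrides`` update individual hyperparameter fields (e.g.
        ``epochs=200``).
        """
        if method == "lstm":
            hp = hyperparams or SoftSensorHyperparams(
                lookback=self.dataset_config.lookback)
            if overrides:
                hp = replace(hp, **overrides)
            trained = lstm_mod.build_and_train(self.train, self.val, hp)
            pred = lstm_mod.predict(trained, self.test)
            history = trained.history
        elif method == "ffnn":
            hp = hyperparams or FFNNConfig()
            if overrides:
                hp = replace(hp, **overrides)
            weights, losses = ffnn_mod.train_lm(
                _ffnn_inputs(self.train, hp), self.train.targets, hp)
            trained = (weights, hp)
            y_norm = ffnn_mod.ffnn_predict(_ffnn_inputs(self.test, hp),
                                           weights, hp.hidden_activation)
            pred = denormalize(y_norm, self.test.scaler_out)
            history = pd.DataFrame({"iteration": np.arange(len(losses)),
                                    "train_loss": losses})
        else:
            raise ValueError(f"unknown method: {method!r}")
        obs = denormalize(self.test.targets, self.test.scaler_out)
        report = evaluate_model(pred, obs, TARGET_CHANNELS, model=method)
        return SoftSensorResults(self, method, hp, trained, pred, obs,
                                 report, history)


@dataclass
class SoftSensorResults:
    """Fitted soft sensor: test-block predictions, metrics and diagnostics."""

    model: SoftSensorModel
    method: str
    hyperparams: object
    trained: object
    predictions: np.ndarray        # (n_test, 2) mg COD/L
    observations: np.ndarray       # (n_test, 2) mg COD/L
    metrics: pd.DataFrame
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    def predict(self, windows: WindowedDataset | None = None) -> np.ndarray:
        """Denormalized predictions on a windowed dataset (default: test block)."""
        windows = windows if windows is not None else self.model.test
        if self.method == "lstm":
            return lstm_mod.predict(self.trained, windows)
        weights, hp = self.trained
        y = ffnn_mod.ffnn_predict(_ffnn_inputs(windows, hp), weights,
                                  hp.hidden_activation)
        return denormalize(y, windows.scaler_out)

    def tcod_prediction(self):
        """Predicted effluent TCOD on the test block and its compliance
        fraction against the configured limit."""
        ev = self.model.evaluation
        return tcod_track(self.predictions[:, 0], self.predictions[:, 1],
                          ev.Is, ev.COD_max)

    def summary(self) -> str:
        """Aligned text summary of the fit, in the spirit of statsmodels."""
        ev = self.model.evaluation
        _, frac_pred, _ = self.tcod_prediction()
        _, frac_obs, _ = tcod_track(self.observations[:, 0],
                                    self.observations[:, 1], ev.Is, ev.COD_max)
        lines = [
            "Soft Sensor Results",
            "=" * 64,
            f"estimator:            {self.method}",
            f"test samples:         {len(self.predictions)}",
            f"inputs:               X3, X4, X5 "
            f"(lookback {self.model.dataset_config.lookback})",
            "targets:              X1, X2",
            "-" * 64,
            f"{'variable':<10}{'MSE':>12}{'R2':>10}{'R2(std)':>10}{'MAPE%':>10}",
        ]
        for _, row in self.metrics.iterrows():
            lines.append(f"{row['variable']:<10}{row['mse']:>12.2f}"
                         f"{row['r2_paper']:>10.3f}{row['r2_standard']:>10.3f}"
                         f"{row['mape_paper']:>10.2f}")
        lines += [
            "-" * 64,
            f"TCOD compliance (pred) vs limit {ev.COD_max:g} mg/L: "
            f"{frac_pred:.3f} (observed {frac_obs:.3f})",
        ]
        return "\n".join(lines)
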