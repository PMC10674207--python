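"""Prediction-performance metrics and the model-comparison report.

Two of the metrics are implemented in the exact (non-standard) form used in
the soft-sensor literature this package follows, with the conventional
definitions reported alongside:

* ``r2_paper`` normalizes the residual sum of squares by the spread of the
  observations around the **predicted** mean, ``1 - SS_res / sum((y - mean(yhat))^2)``,
  whereas ``r2_standard`` uses the observed mean.  The two coincide whenever
  ``mean(yhat) == mean(y)``.
* ``mape_paper`` divides each absolute error by the **predicted** value,
  ``mean(|y - yhat| / yhat) * 100``, and is therefore not symmetric in its
  arguments.

Metrics are computed on denormalized series in original units (mg COD/L).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .asm1 import effluent_compliance, tcod

__all__ = [
    "mse",
    "r2_paper",
    "r2_standard",
    "mape_paper",
    "evaluate_model",
    "tcod_track",
    "comparison_table",
]

REPORT_COLUMNS = ["model", "variable", "mse", "r2_paper", "r2_standard",
                  "mape_paper", "n"]


def _pair(y, yhat, min_len: int = 1):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < min_len:
        raise ValueError(f"need at least {min_len} samples, got {y.size}")
    return y, yhat


def mse(y, yhat) -> float:
    """Mean squared error, in squared units of the inputs."""
    y, yhat = _pair(y, yhat)
    return float(np.mean((y - yhat) ** 2))


def r2_paper(y, yhat) -> float:
    """Coefficient of determination with the predicted-mean denominator."""
    y, yhat = _pair(y, yhat, min_len=2)
    denom = float(np.sum((y - yhat.mean()) ** 2))
    if denom == 0.0:
        raise ZeroDivisionError(
            "r2_paper undefined: observations equal the predicted mean")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / denom


def r2_standard(y, yhat) -> float:
    """Conventional coefficient of determination (observed-mean denominator)."""
    y, yhat = _pair(y, yhat, min_len=2)
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0.0:
        raise ZeroDivisionError("r2_standard undefined: constant observations")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / denom


def mape_paper(y, yhat) -> float:
    """Mean absolute percentage error with the predicted value as denominator."""
    y, yhat = _pair(y, yhat)
    zeros = np.nonzero(yhat == 0.0)[0]
    if zeros.size:
        raise ZeroDivisionError(
            f"mape_paper undefined: predicted value is zero at index {zeros[0]}")
    return float(np.mean(np.abs(y - yhat) / np.abs(yhat))) * 100.0


def evaluate_model(predictions, observations, variables=("X1", "X2"),
                   model: str = "model") -> pd.DataFrame:
    """Per-variable metrics for one model, as one report row per variable.

    ``predictions`` and ``observations`` are (n_samples, n_variables) arrays
    in original units.
    """
    pred = np.atleast_2d(np.asarray(predictions, dtype=float))
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    if pred.shape != obs.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {obs.shape}")
    if pred.shape[1] != len(variables):
        raise ValueError("number of variables does not match columns")
    rows = []
    for k, var in enumerate(variables):
        y, yh = obs[:, k], pred[:, k]
        rows.append({
            "model": model, "variable": var,
            "mse": mse(y, yh),
            "r2_paper": r2_paper(y, yh),
            "r2_standard": r2_standard(y, yh),
            "mape_paper": mape_paper(y, yh),
            "n": int(y.size),
        })
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if not np.isfinite(report[["mse", "r2_paper", "r2_standard",
                               "mape_paper"]].to_numpy()).all():
        raise FloatingPointError("non-finite metric value in report")
    return report


def tcod_track(X1hat, X2hat, Is, cod_max: float = 150.0):
    """Predicted effluent-quality index and its compliance fraction.

    Applies ``TCOD = X1 + X2 + Is`` element-wise to the predicted substrates
    and checks the series against the effluent limit.  Returns
    ``(tcod_series, compliance_fraction, flags)``.
    """
    series = tcod(X1hat, X2hat, Is)
    fraction, flags = effluent_compliance(series, cod_max)
    return series, fraction, flags


def comparison_table(report: pd.DataFrame) -> str:
    """Aligned text table of a multi-model report (models x metrics x variables)."""
    lines = [f"{'Method':<12} {'Metric':<12} " + " ".join(
        f"{v:>10}" for v in report["variable"].unique())]
    for model in report["model"].unique():
        sub = report[report["model"] == model]
        for metric, label in [("mse", "MSE"), ("r2_paper", "R2"),
                              ("mape_paper", "MAPE (%)")]:
            vals = " ".join(f"{sub[sub.variable == v][metric].iloc[0]:>10.4g}"
                            for v in report["variable"].unique())
            lines.append(f"{model:<12} {label:<12} {vals}")
    return "\n".join(lines)
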