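"""Diagnostic figures: loss curves, prediction overlays with error traces,
observed-vs-predicted scatter with the fitted regression line, and the
predicted-vs-real effluent TCOD track."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .metrics import r2_standard  # noqa: E402

__all__ = ["plot_loss", "plot_predictions", "plot_scatter", "plot_tcod",
           "make_figures"]


def plot_loss(history, path) -> None:
    """One curve per split (training and, when present, validation)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    xcol = "epoch" if "epoch" in history.columns else "iteration"
    ax.plot(history[xcol], history["train_loss"], label="training")
    if "val_loss" in history.columns:
        ax.plot(history[xcol], history["val_loss"], label="validation")
    ax.set_xlabel(xcol)
    ax.set_ylabel("MSE (normalized)")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_predictions(obs, pred, variable: str, path, Ts: float = 1.0) -> None:
    """Observed and predicted series with the error trace below."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    t = np.arange(len(obs)) * Ts
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 5), sharex=True,
                                   height_ratios=[3, 1])
    ax1.plot(t, obs, label="observed", lw=1)
    ax1.plot(t, pred, label="predicted", lw=1)
    ax1.set_ylabel(f"{variable} (mg COD/L)")
    ax1.legend()
    ax2.plot(t, obs - pred, lw=0.8, color="tab:red")
    ax2.axhline(0, color="k", lw=0.5)
    ax2.set_xlabel("time (h)")
    ax2.set_ylabel("error")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scatter(obs, pred, variable: str, path) -> None:
    """Observed vs predicted scatter with least-squares fit line and R2."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    slope, intercept = np.polyfit(obs, pred, 1)
    r2 = r2_standard(obs, pred)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(obs, pred, s=8, alpha=0.5)
    xs = np.array([obs.min(), obs.max()])
    ax.plot(xs, slope * xs + intercept, "r-",
            label=f"fit: y = {slope:.3f}x + {intercept:.2f}\nR$^2$ = {r2:.3f}")
    ax.plot(xs, xs, "k--", lw=0.7, label="identity")
    ax.set_xlabel(f"observed {variable} (mg COD/L)")
    ax.set_ylabel(f"predicted {variable} (mg COD/L)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_tcod(tcod_obs, tcod_pred, cod_max: float, path, Ts: float = 1.0):
    fig, ax = plt.subplots(figsize=(7, 4))
    t = np.arange(len(tcod_obs)) * Ts
    ax.plot(t, tcod_obs, label="real", lw=1)
    ax.plot(t, tcod_pred, label="predicted", lw=1)
    ax.axhline(cod_max, color="r", ls=":", label=f"limit {cod_max:g} mg/L")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("TCOD (mg COD/L)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def make_figures(results_list, out) -> list[Path]:
    """One image per figure analogue for each fitted estimator."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for res in results_list:
        tag = res.method
        Ts = getattr(res.model.dataset_config, "lookback", 1) and \
            res.model.data.shape[0] and 120.0 / max(len(res.model.data), 1)
        if len(res.history):
            p = out / f"loss_{tag}.png"
            plot_loss(res.history, p)
            written.append(p)
        for k, var in enumerate(("X1", "X2")):
            p = out / f"prediction_{var}_{tag}.png"
            plot_predictions(res.observations[:, k], res.predictions[:, k],
                             var, p, Ts)
            written.append(p)
            p = out / f"scatter_{var}_{tag}.png"
            plot_scatter(res.observations[:, k], res.predictions[:, k], var, p)
            written.append(p)
        ev = res.model.evaluation
        series_pred, _, _ = res.tcod_prediction()
        tcod_obs = res.observations[:, 0] + res.observations[:, 1] + ev.Is
        p = out / f"tcod_{tag}.png"
        plot_tcod(tcod_obs, series_pred, ev.COD_max, p, Ts)
        written.append(p)
    return written
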