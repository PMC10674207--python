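"""Single-hidden-layer feed-forward baseline trained with Levenberg-Marquardt.

The network is ``y = W2 @ act(W1 @ x + b1) + b2`` with a sigmoidal hidden
layer (tanh by default) and linear outputs, fitted by the classic damped
Gauss-Newton loop on the full residual vector: analytic Jacobian, normal
equations with Marquardt scaling ``J'J + lambda * diag(J'J)``, multiplicative
damping updates on accept/reject.  This is the textbook trainer for small
shallow networks and serves as the comparison baseline for the LSTM soft
sensor, consuming the same flattened input windows.
"""

from __future__ import annotations

import logging

import h5py
import numpy as np
from scipy import linalg

from ..config import FFNNConfig

__all__ = ["init_weights", "ffnn_forward", "ffnn_predict", "ffnn_jacobian",
           "train_lm", "pack", "unpack", "save_weights_h5"]

logger = logging.getLogger(__name__)


def _activation(name: str):
    if name == "tanh":
        return np.tanh, lambda a: 1.0 - a**2          # derivative from output
    if name == "logistic":
        return (lambda z: 1.0 / (1.0 + np.exp(-z))), lambda a: a * (1.0 - a)
    if name == "identity":      # diagnostics: makes the net an affine map
        return (lambda z: z), lambda a: np.ones_like(a)
    raise ValueError(f"unknown activation: {name}")


def init_weights(n_inputs: int, n_hidden: int, n_outputs: int,
                 seed: int = 0) -> dict:
    """Nguyen-Widrow-flavoured small random initialization."""
    rng = np.random.default_rng(seed)
    s1 = np.sqrt(6.0 / (n_inputs + n_hidden))
    s2 = np.sqrt(6.0 / (n_hidden + n_outputs))
    return {
        "W1": rng.uniform(-s1, s1, size=(n_hidden, n_inputs)),
        "b1": np.zeros(n_hidden),
        "W2": rng.uniform(-s2, s2, size=(n_outputs, n_hidden)),
        "b2": np.zeros(n_outputs),
    }


def pack(weights: dict) -> np.ndarray:
    return np.concatenate([weights[k].ravel() for k in ("W1", "b1", "W2", "b2")])


def unpack(theta: np.ndarray, n_inputs: int, n_hidden: int,
           n_outputs: int) -> dict:
    sizes = [n_hidden * n_inputs, n_hidden, n_outputs * n_hidden, n_outputs]
    if theta.size != sum(sizes):
        raise ValueError("parameter vector has wrong length")
    parts = np.split(theta, np.cumsum(sizes)[:-1])
    return {"W1": parts[0].reshape(n_hidden, n_inputs), "b1": parts[1],
            "W2": parts[2].reshape(n_outputs, n_hidden), "b2": parts[3]}


def ffnn_forward(x, weights: dict, activation: str = "tanh") -> np.ndarray:
    """Prediction for a single flattened window (1-D input)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != weights["W1"].shape[1]:
        raise ValueError(f"input must be 1-D with {weights['W1'].shape[1]} "
                         f"features, got shape {x.shape}")
    act, _ = _activation(activation)
    return weights["W2"] @ act(weights["W1"] @ x + weights["b1"]) + weights["b2"]


def ffnn_predict(X, weights: dict, activation: str = "tanh") -> np.ndarray:
    """Batch prediction for (N, inputs) flattened windows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    act, _ = _activation(activation)
    return act(X @ weights["W1"].T + weights["b1"]) @ weights["W2"].T + weights["b2"]


def ffnn_jacobian(X, weights: dict, activation: str = "tanh") -> np.ndarray:
    """Analytic Jacobian of the stacked residual vector w.r.t. the packed
    parameters; rows ordered sample-major then output-major."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    act, dact = _activation(activation)
    N, I = X.shape
    H = weights["W1"].shape[0]
    O = weights["W2"].shape[0]
    A = act(X @ weights["W1"].T + weights["b1"])     # (N, H)
    D = dact(A)                                      # (N, H)
    P = H * I + H + O * H + O
    J = np.zeros((N, O, P))
    for k in range(O):
        WD = weights["W2"][k] * D                    # (N, H)
        J[:, k, :H * I] = (WD[:, :, None] * X[:, None, :]).reshape(N, H * I)
        J[:, k, H * I:H * I + H] = WD
        J[:, k, H * I + H + k * H: H * I + H + (k + 1) * H] = A
        J[:, k, H * I + H + O * H + k] = 1.0
    return J.reshape(N * O, P)


def train_lm(X, Y, cfg: FFNNConfig, weights: dict | None = None):
    """Levenberg-Marquardt training on (N, inputs) / (N, outputs) data.

    Returns ``(weights, losses)`` where ``losses`` is the sequence of
    accepted mean-squared errors (non-increasing by construction).  Stops on
    the gradient tolerance, ``max_iters`` accepted steps, or when the
    damping hits its upper bound.
    """
    cfg.validate()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if len(X) != len(Y):
        raise ValueError("X and Y must have the same number of rows")
    if cfg.max_train_samples and len(X) > cfg.max_train_samples:
        rng = np.random.default_rng(cfg.seed)
        idx = rng.choice(len(X), cfg.max_train_samples, replace=False)
        X, Y = X[idx], Y[idx]
    n_in, n_out = X.shape[1], Y.shape[1]
    if weights is None:
        weights = init_weights(n_in, cfg.n_hidden, n_out, cfg.seed)
    theta = pack(weights)
    act = cfg.hidden_activation

    def residuals(th):
        w = unpack(th, n_in, cfg.n_hidden, n_out)
        return (ffnn_predict(X, w, act) - Y).ravel()

    r = residuals(theta)
    loss = float(np.mean(r**2))
    losses = [loss]
    lam = cfg.lm_lambda0
    for it in range(cfg.max_iters):
        w = unpack(theta, n_in, cfg.n_hidden, n_out)
        J = ffnn_jacobian(X, w, act)
        g = J.T @ r
        if np.max(np.abs(g)) < cfg.tol_grad:
            logger.info("LM converged at iteration %d (gradient)", it)
            break
        JTJ = J.T @ J
        diag = np.maximum(np.diag(JTJ), 1e-12)
        accepted = False
        while lam <= cfg.lm_lambda_max:
            try:
                cho = linalg.cho_factor(JTJ + lam * np.diag(diag), lower=True)
                delta = linalg.cho_solve(cho, -g)
            except linalg.LinAlgError:
                lam *= cfg.lm_lambda_factor
                continue
            r_new = residuals(theta + delta)
            loss_new = float(np.mean(r_new**2))
            if np.isfinite(loss_new) and loss_new < loss:
                theta = theta + delta
                r, loss = r_new, loss_new
                lam = max(lam / cfg.lm_lambda_factor, cfg.lm_lambda_min)
                losses.append(loss)
                accepted = True
                break
            lam *= cfg.lm_lambda_factor
        if not accepted:
            logger.info("LM stopped at iteration %d (damping saturated)", it)
            break
        if it % 10 == 0:
            logger.info("LM iteration %d: mse %.3g lambda %.1g", it, loss, lam)
    if lam > cfg.lm_lambda_max:
        raise RuntimeError("Levenberg-Marquardt failed: repeated singular or "
                           "non-improving damped systems")
    return unpack(theta, n_in, cfg.n_hidden, n_out), losses


def save_weights_h5(weights: dict, path) -> None:
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("ffnn")
        for name in ("W1", "b1", "W2", "b2"):
            grp.create_dataset(name, data=weights[name])
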