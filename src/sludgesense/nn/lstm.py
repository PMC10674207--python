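"""Trainable stacked-LSTM soft sensor: NumPy forward pass, backpropagation
through time, Adam optimizer, dropout.

The network follows the reference deep-learning-toolkit conventions so that
the independent gate-equation oracle (:mod:`sludgesense.nn.oracle`) can
verify its inference: standard (non-peephole) cells with gate order
``[input, forget, candidate, output]``, Glorot-uniform input kernels,
orthogonal recurrent kernels, unit forget-gate bias, float32 arithmetic,
Adam with ``eps = 1e-7`` and mean-squared-error loss on normalized targets.

Architecture (fixed by hyperparameters): ``LSTM(H1, return sequences) ->
dropout -> LSTM(H2) -> dropout -> [optional dense-ReLU ->] dense(2,
linear)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from ..config import SoftSensorHyperparams
from ..dataset import WindowedDataset, denormalize
from . import oracle

__all__ = ["LSTMNetwork", "TrainedSoftSensor", "build_and_train", "predict",
           "export_weights", "forward_equivalence", "save_weights_h5"]

logger = logging.getLogger(__name__)

DTYPE = np.float32


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def _orthogonal_blocks(rng, hidden, n_blocks=4):
    """(hidden, n_blocks*hidden) recurrent kernel of orthogonal blocks."""
    blocks = []
    for _ in range(n_blocks):
        a = rng.standard_normal((hidden, hidden))
        q, r = np.linalg.qr(a)
        blocks.append((q * np.sign(np.diag(r))).astype(DTYPE))
    return np.concatenate(blocks, axis=1)


@dataclass
class _LSTMLayer:
    Wx: np.ndarray     # (input, 4H) gate order i, f, g(candidate), o
    Wh: np.ndarray     # (H, 4H)
    b: np.ndarray      # (4H,)

    @property
    def hidden(self) -> int:
        return self.Wh.shape[0]


class LSTMNetwork:
    """Two-(or more-)layer LSTM regressor operating on normalized windows."""

    def __init__(self, input_size: int, cells_per_layer=(128, 64),
                 n_outputs: int = 2, dense_relu_head: bool = False,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.layers: list[_LSTMLayer] = []
        size = input_size
        for H in cells_per_layer:
            b = np.zeros(4 * H, dtype=DTYPE)
            b[H: 2 * H] = 1.0          # unit forget-gate bias
            self.layers.append(_LSTMLayer(
                _glorot(rng, (size, 4 * H)), _orthogonal_blocks(rng, H), b))
            size = H
        self.relu_head = None
        if dense_relu_head:
            self.relu_head = [_glorot(rng, (size, size)),
                              np.zeros(size, dtype=DTYPE)]
        self.Wd = _glorot(rng, (size, n_outputs))
        self.bd = np.zeros(n_outputs, dtype=DTYPE)
        self.input_size = input_size
        self.n_outputs = n_outputs

    # -- parameter plumbing ------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        params = []
        for layer in self.layers:
            params += [layer.Wx, layer.Wh, layer.b]
        if self.relu_head is not None:
            params += self.relu_head
        params += [self.Wd, self.bd]
        return params

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, dropout_rate: float = 0.0,
                rng: np.random.Generator | None = None):
        """Forward pass over a (N, T, input) batch.

        With ``dropout_rate > 0`` (training mode) inverted dropout is applied
        after each LSTM layer; ``rng`` then supplies the masks.  Returns
        ``(predictions, cache)``.
        """
        x = np.ascontiguousarray(x, dtype=DTYPE)
        N, T, _ = x.shape
        cache: dict = {"x": x, "layers": [], "masks": []}
        seq = x
        for li, layer in enumerate(self.layers):
            H = layer.hidden
            h = np.zeros((N, H), dtype=DTYPE)
            c = np.zeros((N, H), dtype=DTYPE)
            hs = np.empty((T, N, H), dtype=DTYPE)
            cs = np.empty((T, N, H), dtype=DTYPE)
            gates = np.empty((T, N, 4 * H), dtype=DTYPE)
            for t in range(T):
                z = seq[:, t] @ layer.Wx + h @ layer.Wh + layer.b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                c = f * c + i * g
                h = o * np.tanh(c)
                gates[t, :, :H] = i
                gates[t, :, H:2 * H] = f
                gates[t, :, 2 * H:3 * H] = g
                gates[t, :, 3 * H:] = o
                cs[t] = c
                hs[t] = h
            cache["layers"].append({"in": seq, "hs": hs, "cs": cs,
                                    "gates": gates})
            last = li == len(self.layers) - 1
            out = h if last else hs.transpose(1, 0, 2)
            if dropout_rate > 0.0:
                if rng is None:
                    raise ValueError("dropout requires an rng")
                keep = 1.0 - dropout_rate
                mask = (rng.random(out.shape) < keep).astype(DTYPE) / DTYPE(keep)
                out = out * mask
                cache["masks"].append(mask)
            else:
                cache["masks"].append(None)
            seq = out
        h_final = seq
        if self.relu_head is not None:
            Wr, br = self.relu_head
            pre = h_final @ Wr + br
            h_final = np.maximum(pre, 0.0)
            cache["relu"] = (seq, pre)
        cache["h_final"] = h_final
        y = h_final @ self.Wd + self.bd
        return y, cache

    def backward(self, cache: dict, dy: np.ndarray) -> list[np.ndarray]:
        """Gradients of the loss w.r.t. :meth:`parameters` given dL/dy."""
        dy = dy.astype(DTYPE)
        h_final = cache["h_final"]
        dWd = h_final.T @ dy
        dbd = dy.sum(axis=0)
        dh = dy @ self.Wd.T
        relu_grads: list[np.ndarray] = []
        if self.relu_head is not None:
            seq_in, pre = cache["relu"]
            dh = dh * (pre > 0)
            relu_grads = [seq_in.T @ dh, dh.sum(axis=0)]
            dh = dh @ self.relu_head[0].T

        grads_layers: list[list[np.ndarray]] = []
        # dh currently is gradient w.r.t. the (possibly dropped-out) output
        # of the last layer (its final hidden state).
        d_out: np.ndarray | None = None   # (N, T, H) grad for seq outputs
        d_last = dh                        # (N, H) grad at final timestep only
        for li in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[li]
            lc = cache["layers"][li]
            mask = cache["masks"][li]
            H = layer.hidden
            seq_in, hs, cs, gates = lc["in"], lc["hs"], lc["cs"], lc["gates"]
            T, N, _ = hs.shape
            if d_out is None:
                d_hs = np.zeros((T, N, H), dtype=DTYPE)
                d_hs[T - 1] = d_last * (mask if mask is not None else 1.0)
            else:
                d_hs = (d_out * (mask if mask is not None else 1.0)
                        ).transpose(1, 0, 2).astype(DTYPE)
            dWx = np.zeros_like(layer.Wx)
            dWh = np.zeros_like(layer.Wh)
            db = np.zeros_like(layer.b)
            d_in = np.empty((N, T, seq_in.shape[-1]), dtype=DTYPE)
            dh_next = np.zeros((N, H), dtype=DTYPE)
            dc_next = np.zeros((N, H), dtype=DTYPE)
            for t in range(T - 1, -1, -1):
                i = gates[t, :, :H]
                f = gates[t, :, H:2 * H]
                g = gates[t, :, 2 * H:3 * H]
                o = gates[t, :, 3 * H:]
                c = cs[t]
                c_prev = cs[t - 1] if t > 0 else np.zeros_like(c)
                h_prev = hs[t - 1] if t > 0 else np.zeros_like(hs[0])
                tanh_c = np.tanh(c)
                dh_t = d_hs[t] + dh_next
                dc = dh_t * o * (1.0 - tanh_c**2) + dc_next
                dz = np.empty((N, 4 * H), dtype=DTYPE)
                dz[:, :H] = dc * g * i * (1.0 - i)
                dz[:, H:2 * H] = dc * c_prev * f * (1.0 - f)
                dz[:, 2 * H:3 * H] = dc * i * (1.0 - g**2)
                dz[:, 3 * H:] = dh_t * tanh_c * o * (1.0 - o)
                dWx += seq_in[:, t].T @ dz
                dWh += h_prev.T @ dz
                db += dz.sum(axis=0)
                d_in[:, t] = dz @ layer.Wx.T
                dh_next = dz @ layer.Wh.T
                dc_next = dc * f
            grads_layers.append([dWx, dWh, db])
            d_out = d_in
            d_last = None
        grads: list[np.ndarray] = []
        for layer_grads in reversed(grads_layers):
            grads += layer_grads
        grads += relu_grads
        grads += [dWd, dbd]
        return grads

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference (dropout disabled) on a (N, T, input) batch."""
        y, _ = self.forward(x)
        return y


@dataclass
class TrainedSoftSensor:
    """A fitted network plus everything needed to use and audit it."""

    network: LSTMNetwork
    hyperparams: SoftSensorHyperparams
    scaler_in: object
    scaler_out: object
    history: pd.DataFrame = field(default_factory=pd.DataFrame)
    seed: int = 0


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.b2**self.t) / (1.0 - self.b1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(p.dtype)


def build_and_train(train: WindowedDataset, val: WindowedDataset,
                    hp: SoftSensorHyperparams) -> TrainedSoftSensor:
    """Train the stacked-LSTM soft sensor on normalized windowed data.

    Minimizes MSE on the normalized targets with Adam for ``hp.epochs`` full
    epochs (no early stopping); the per-epoch training loss (mean over
    batches) and full validation loss are recorded in ``history``.  All
    randomness (weight init, batch shuffling, dropout masks) derives from
    ``hp.seed``.
    """
    hp.validate()
    if train.lookback != hp.lookback:
        raise ValueError(f"dataset lookback {train.lookback} does not match "
                         f"hyperparameters ({hp.lookback})")
    net = LSTMNetwork(train.inputs.shape[-1], hp.cells_per_layer,
                      train.targets.shape[-1], hp.dense_relu_head,
                      seed=hp.seed)
    params = net.parameters()
    opt = _Adam(params, lr=hp.learning_rate)
    rng = np.random.default_rng(hp.seed + 1)
    x = train.inputs.astype(DTYPE)
    y = train.targets.astype(DTYPE)
    xv = val.inputs.astype(DTYPE)
    yv = val.targets.astype(DTYPE)
    n = len(x)
    history = []
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, hp.batch_size):
            idx = order[start: start + hp.batch_size]
            xb, yb = x[idx], y[idx]
            pred, cache = net.forward(xb, hp.dropout_rate, rng)
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            dy = (2.0 / err.size) * err
            grads = net.backward(cache, dy)
            opt.step(params, grads)
            batch_losses.append(loss)
        val_loss = float(np.mean((net.predict(xv) - yv) ** 2))
        history.append({"epoch": epoch, "train_loss": float(np.mean(batch_losses)),
                        "val_loss": val_loss})
        if epoch % 25 == 0 or epoch == hp.epochs - 1:
            logger.info("epoch %d: train %.3g val %.3g", epoch,
                        history[-1]["train_loss"], val_loss)
    return TrainedSoftSensor(net, hp, train.scaler_in, train.scaler_out,
                             pd.DataFrame(history), hp.seed)


def predict(model: TrainedSoftSensor, windows: WindowedDataset) -> np.ndarray:
    """Denormalized predictions (mg COD/L) on a windowed dataset."""
    if windows.scaler_out.to_json() != model.scaler_out.to_json():
        raise ValueError("dataset was normalized with a different scaler "
                         "than the model was trained with")
    y_norm = model.network.predict(windows.inputs.astype(DTYPE))
    return denormalize(y_norm.astype(float), model.scaler_out)


def export_weights(model: TrainedSoftSensor):
    """Per-layer gate matrices in the oracle's convention.

    Returns ``(cells, dense)`` where ``cells`` is a list of
    :class:`~sludgesense.nn.oracle.LSTMCellWeights` (peephole weights zero,
    since the trained cells are the standard variant) and ``dense`` is the
    ``(W, b)`` output head (plus the optional ReLU layer, exposed as
    ``dense[2]`` when present).
    """
    cells = []
    for layer in model.network.layers:
        H = layer.hidden
        Wx, Wh, b = (np.asarray(layer.Wx, float), np.asarray(layer.Wh, float),
                     np.asarray(layer.b, float))
        cells.append(oracle.LSTMCellWeights(
            Wxi=Wx[:, :H].T, Wxf=Wx[:, H:2 * H].T, Wxc=Wx[:, 2 * H:3 * H].T,
            Wxo=Wx[:, 3 * H:].T,
            Whi=Wh[:, :H].T, Whf=Wh[:, H:2 * H].T, Whc=Wh[:, 2 * H:3 * H].T,
            Who=Wh[:, 3 * H:].T,
            Wci=np.zeros(H), Wcf=np.zeros(H), Wco=np.zeros(H),
            bi=b[:H], bf=b[H:2 * H], bc=b[2 * H:3 * H], bo=b[3 * H:]))
    dense = [np.asarray(model.network.Wd, float).T,
             np.asarray(model.network.bd, float)]
    if model.network.relu_head is not None:
        dense.append([np.asarray(model.network.relu_head[0], float).T,
                      np.asarray(model.network.relu_head[1], float)])
    return cells, dense


def forward_equivalence(model: TrainedSoftSensor, weights, samples) -> float:
    """Max absolute difference between the oracle forward pass and the
    network's inference over a batch of normalized windows."""
    cells, dense = weights
    relu = dense[2] if len(dense) > 2 else None
    backend = model.network.predict(np.asarray(samples, dtype=DTYPE))
    diffs = []
    for k, window in enumerate(np.asarray(samples, dtype=float)):
        ref = oracle.stacked_lstm_forward(window, cells, dense[0], dense[1],
                                          relu_hidden=relu)
        diffs.append(np.max(np.abs(ref - backend[k])))
    return float(np.max(diffs))


def save_weights_h5(model: TrainedSoftSensor, path) -> None:
    """Write the exported weights to HDF5 (groups ``lstm_1``, ``lstm_2``, ...,
    ``dense``), peepholes zero-filled, with meta attributes."""
    cells, dense = export_weights(model)
    with h5py.File(path, "w") as fh:
        for k, cell in enumerate(cells, start=1):
            grp = fh.create_group(f"lstm_{k}")
            for name in ("Wxi", "Wxf", "Wxc", "Wxo", "Whi", "Whf", "Whc",
                         "Who", "Wci", "Wcf", "Wco", "bi", "bf", "bc", "bo"):
                grp.create_dataset(name, data=getattr(cell, name))
        grp = fh.create_group("dense")
        grp.create_dataset("W", data=dense[0])
        grp.create_dataset("b", data=dense[1])
        meta = fh.create_group("meta")
        meta.attrs["hidden_sizes"] = [c.hidden_size for c in cells]
        meta.attrs["lookback"] = model.hyperparams.lookback
        meta.attrs["seed"] = model.seed
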