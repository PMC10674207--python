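"""Reference forward pass of the peephole LSTM cell, written from the
gate equations.

This module is deliberately independent of the trainable network in
:mod:`sludgesense.nn.lstm`: it implements the cell arithmetic gate by gate,
with explicit per-gate matrices, and serves as the verification oracle that
the trained network's inference is the mathematics it claims to be.

The cell is the peephole variant: the input and forget gates see the
previous cell state ``C_{t-1}`` through diagonal weights ``Wci``/``Wcf``,
and the output gate sees the freshly updated ``C_t`` through ``Wco``::

    i_t = sigma(Wxi x_t + Whi h_{t-1} + Wci * C_{t-1} + bi)
    f_t = sigma(Wxf x_t + Whf h_{t-1} + Wcf * C_{t-1} + bf)
    Ctil = tanh(Wxc x_t + Whc h_{t-1} + bc)
    C_t  = f_t * C_{t-1} + i_t * Ctil
    o_t  = sigma(Wxo x_t + Who h_{t-1} + Wco * C_t + bo)
    h_t  = o_t * tanh(C_t)

With all peephole weights zero this reduces exactly to the standard LSTM
cell used by mainstream deep-learning backends.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = ["LSTMCellWeights", "lstm_cell_forward", "lstm_layer_forward",
           "stacked_lstm_forward"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class LSTMCellWeights:
    """All gate/cell weights of one LSTM layer.

    Input-to-gate matrices are (hidden, input); hidden-to-gate matrices are
    (hidden, hidden); peephole weights are diagonal, stored as length-hidden
    vectors; biases are length-hidden vectors.
    """

    Wxi: np.ndarray
    Wxf: np.ndarray
    Wxc: np.ndarray
    Wxo: np.ndarray
    Whi: np.ndarray
    Whf: np.ndarray
    Whc: np.ndarray
    Who: np.ndarray
    Wci: np.ndarray
    Wcf: np.ndarray
    Wco: np.ndarray
    bi: np.ndarray
    bf: np.ndarray
    bc: np.ndarray
    bo: np.ndarray

    def __post_init__(self):
        for f in fields(self):
            setattr(self, f.name, np.asarray(getattr(self, f.name), dtype=float))
        H, I = self.Wxi.shape
        for name in ("Wxi", "Wxf", "Wxc", "Wxo"):
            if getattr(self, name).shape != (H, I):
                raise ValueError(f"{name} must have shape {(H, I)}, "
                                 f"got {getattr(self, name).shape}")
        for name in ("Whi", "Whf", "Whc", "Who"):
            if getattr(self, name).shape != (H, H):
                raise ValueError(f"{name} must have shape {(H, H)}, "
                                 f"got {getattr(self, name).shape}")
        for name in ("Wci", "Wcf", "Wco", "bi", "bf", "bc", "bo"):
            if getattr(self, name).shape != (H,):
                raise ValueError(f"{name} must have shape {(H,)}, "
                                 f"got {getattr(self, name).shape}")
        if not all(np.isfinite(getattr(self, f.name)).all() for f in fields(self)):
            raise ValueError("LSTMCellWeights contain non-finite values")

    @property
    def hidden_size(self) -> int:
        return self.Wxi.shape[0]

    @property
    def input_size(self) -> int:
        return self.Wxi.shape[1]

    @classmethod
    def zeros(cls, hidden: int, inputs: int) -> "LSTMCellWeights":
        H, I = hidden, inputs
        return cls(*[np.zeros((H, I)) for _ in range(4)],
                   *[np.zeros((H, H)) for _ in range(4)],
                   *[np.zeros(H) for _ in range(7)])


def lstm_cell_forward(x_t, h_prev, c_prev, W: LSTMCellWeights):
    """One step of the peephole cell; returns ``(h_t, c_t)``."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    if x_t.shape != (W.input_size,):
        raise ValueError(f"x_t must have shape {(W.input_size,)} to match Wxi, "
                         f"got {x_t.shape}")
    if h_prev.shape != (W.hidden_size,) or c_prev.shape != (W.hidden_size,):
        raise ValueError(f"h_prev/c_prev must have shape {(W.hidden_size,)} "
                         "to match Whi")
    i = _sigmoid(W.Wxi @ x_t + W.Whi @ h_prev + W.Wci * c_prev + W.bi)
    f = _sigmoid(W.Wxf @ x_t + W.Whf @ h_prev + W.Wcf * c_prev + W.bf)
    c_tilde = np.tanh(W.Wxc @ x_t + W.Whc @ h_prev + W.bc)
    c_t = f * c_prev + i * c_tilde
    o = _sigmoid(W.Wxo @ x_t + W.Who @ h_prev + W.Wco * c_t + W.bo)
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def lstm_layer_forward(sequence, W: LSTMCellWeights, h0=None, c0=None,
                       return_sequence: bool = False):
    """Left-to-right recurrence over a (T, input) sequence.

    Returns the final hidden vector, or the full (T, hidden) hidden sequence
    when ``return_sequence`` is set.
    """
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ValueError("sequence must be a non-empty (T, input) array")
    h = np.zeros(W.hidden_size) if h0 is None else np.asarray(h0, float)
    c = np.zeros(W.hidden_size) if c0 is None else np.asarray(c0, float)
    out = np.empty((seq.shape[0], W.hidden_size))
    for t, x_t in enumerate(seq):
        h, c = lstm_cell_forward(x_t, h, c, W)
        out[t] = h
    return out if return_sequence else h


def stacked_lstm_forward(sequence, layers, dense_W, dense_b,
                         relu_hidden=None):
    """Stacked LSTM layers followed by the linear output head.

    ``layers`` is a list of :class:`LSTMCellWeights`; each layer consumes the
    previous layer's full hidden sequence; the head maps the last hidden
    vector of the final layer to the outputs.  ``relu_hidden`` optionally
    holds ``(W, b)`` of a rectified-linear dense layer inserted before the
    output.
    """
    seq = np.asarray(sequence, dtype=float)
    for k, W in enumerate(layers):
        last = k == len(layers) - 1
        seq = lstm_layer_forward(seq, W, return_sequence=not last)
    h = seq
    if relu_hidden is not None:
        Wr, br = relu_hidden
        h = np.maximum(np.asarray(Wr) @ h + np.asarray(br), 0.0)
    return np.asarray(dense_W) @ h + np.asarray(dense_b)
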