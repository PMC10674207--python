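"""Gate-equation oracle and its equivalence with the trainable network.

The oracle implements the peephole cell exactly as the gate equations read;
the trainable network uses the standard (peephole-free) cell.  With zero
peephole weights the two must agree to numerical precision — that
equivalence is the core verification of the soft sensor's inference path.
"""

import math

import numpy as np
import pytest

from sludgesense.config import SoftSensorHyperparams
from sludgesense.dataset import ScalingParams
from sludgesense.nn import lstm as L
from sludgesense.nn.oracle import (LSTMCellWeights, lstm_cell_forward,
                                   lstm_layer_forward, stacked_lstm_forward)


def random_cell(rng, hidden, inputs, peepholes=True) -> LSTMCellWeights:
    def m(*shape):
        return rng.normal(0, 0.5, size=shape)
    return LSTMCellWeights(
        m(hidden, inputs), m(hidden, inputs), m(hidden, inputs), m(hidden, inputs),
        m(hidden, hidden), m(hidden, hidden), m(hidden, hidden), m(hidden, hidden),
        m(hidden) if peepholes else np.zeros(hidden),
        m(hidden) if peepholes else np.zeros(hidden),
        m(hidden) if peepholes else np.zeros(hidden),
        m(hidden), m(hidden), m(hidden), m(hidden))


class TestCellForward:
    def test_all_zero_weights(self):
        W = LSTMCellWeights.zeros(3, 2)
        h, c = lstm_cell_forward(np.zeros(2), np.zeros(3), np.zeros(3), W)
        np.testing.assert_allclose(c, 0.0)
        np.testing.assert_allclose(h, 0.0)
        # gates sit at sigmoid(0) = 1/2; candidate at tanh(0) = 0
        i = 1.0 / (1.0 + np.exp(-(W.Wxi @ np.zeros(2))))
        np.testing.assert_allclose(i, 0.5)

    def test_gates_strictly_inside_unit_interval(self, rng):
        W = random_cell(rng, 4, 3)
        for _ in range(200):
            x = rng.normal(0, 2, 3)
            h_prev = rng.normal(0, 1, 4)
            c_prev = rng.normal(0, 1, 4)
            i = 1 / (1 + np.exp(-(W.Wxi @ x + W.Whi @ h_prev
                                  + W.Wci * c_prev + W.bi)))
            assert ((i > 0) & (i < 1)).all()
            h, c = lstm_cell_forward(x, h_prev, c_prev, W)
            assert np.isfinite(h).all() and np.isfinite(c).all()
            assert (np.abs(np.tanh(c)) < 1).all()

    def test_hand_computed_two_unit_cell(self):
        """Scalar hand evaluation of every gate for a 2-unit, 1-input cell."""
        W = LSTMCellWeights(
            Wxi=[[0.5], [-0.2]], Wxf=[[0.3], [0.1]], Wxc=[[1.0], [0.4]],
            Wxo=[[-0.6], [0.2]],
            Whi=[[0.1, 0.0], [0.0, 0.2]], Whf=[[0.2, 0.1], [0.0, -0.1]],
            Whc=[[0.3, 0.0], [0.1, 0.1]], Who=[[0.0, 0.4], [0.2, 0.0]],
            Wci=[0.05, -0.1], Wcf=[0.2, 0.3], Wco=[-0.15, 0.25],
            bi=[0.1, -0.1], bf=[0.2, 0.0], bc=[0.0, 0.1], bo=[-0.2, 0.3])
        x, h0, c0 = np.array([0.8]), np.array([0.1, -0.3]), np.array([0.2, 0.4])

        def sig(z):
            return 1.0 / (1.0 + math.exp(-z))

        i0 = sig(0.5 * 0.8 + 0.1 * 0.1 + 0.0 * -0.3 + 0.05 * 0.2 + 0.1)
        i1 = sig(-0.2 * 0.8 + 0.0 * 0.1 + 0.2 * -0.3 + -0.1 * 0.4 + -0.1)
        f0 = sig(0.3 * 0.8 + 0.2 * 0.1 + 0.1 * -0.3 + 0.2 * 0.2 + 0.2)
        f1 = sig(0.1 * 0.8 + 0.0 * 0.1 + -0.1 * -0.3 + 0.3 * 0.4 + 0.0)
        g0 = math.tanh(1.0 * 0.8 + 0.3 * 0.1 + 0.0 * -0.3 + 0.0)
        g1 = math.tanh(0.4 * 0.8 + 0.1 * 0.1 + 0.1 * -0.3 + 0.1)
        c_0 = f0 * 0.2 + i0 * g0
        c_1 = f1 * 0.4 + i1 * g1
        o0 = sig(-0.6 * 0.8 + 0.0 * 0.1 + 0.4 * -0.3 + -0.15 * c_0 + -0.2)
        o1 = sig(0.2 * 0.8 + 0.2 * 0.1 + 0.0 * -0.3 + 0.25 * c_1 + 0.3)
        h_expected = [o0 * math.tanh(c_0), o1 * math.tanh(c_1)]

        h, c = lstm_cell_forward(x, h0, c0, W)
        np.testing.assert_allclose(c, [c_0, c_1], rtol=1e-14)
        np.testing.assert_allclose(h, h_expected, rtol=1e-14)

    def test_shape_mismatch_names_offender(self, rng):
        W = random_cell(rng, 4, 3)
        with pytest.raises(ValueError, match="Wxi"):
            lstm_cell_forward(np.zeros(5), np.zeros(4), np.zeros(4), W)
        with pytest.raises(ValueError, match="Whi"):
            lstm_cell_forward(np.zeros(3), np.zeros(2), np.zeros(2), W)


class TestLayerForward:
    def test_single_step_equals_cell(self, rng):
        W = random_cell(rng, 4, 3)
        x = rng.normal(size=(1, 3))
        h_layer = lstm_layer_forward(x, W)
        h_cell, _ = lstm_cell_forward(x[0], np.zeros(4), np.zeros(4), W)
        np.testing.assert_allclose(h_layer, h_cell)

    def test_zero_weights_give_zero_hidden(self, rng):
        W = LSTMCellWeights.zeros(4, 3)
        seq = rng.normal(size=(7, 3))
        np.testing.assert_allclose(lstm_layer_forward(seq, W), 0.0)

    def test_sequence_content_matters(self, rng):
        W = random_cell(rng, 4, 3)
        seq = rng.normal(size=(4, 3))
        doubled = np.repeat(seq, 2, axis=0)
        assert not np.allclose(lstm_layer_forward(seq, W),
                               lstm_layer_forward(doubled, W))

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            lstm_layer_forward(np.empty((0, 3)), random_cell(rng, 4, 3))


def tiny_trained_sensor(rng, epochs=2, hidden=(6, 5)):
    """Train a small network on synthetic windows; returns the wrapper."""
    from sludgesense.dataset import WindowedDataset

    n, T = 64, 7
    x = rng.uniform(0, 1, size=(n, T, 3))
    y = np.column_stack([x[:, -1, 0] * 0.5 + 0.2,
                         x[:, :, 1].mean(axis=1)])
    scaler_in = ScalingParams(["X3", "X4", "X5"], np.zeros(3), np.ones(3))
    scaler_out = ScalingParams(["X1", "X2"], np.zeros(2), np.ones(2))
    ds = WindowedDataset(x, y, T, scaler_in, scaler_out, np.arange(n))
    hp = SoftSensorHyperparams(batch_size=16, lookback=7, epochs=epochs,
                               cells_per_layer=hidden, seed=3)
    return L.build_and_train(ds, ds, hp), ds


class TestBackendEquivalence:
    def test_trained_network_matches_oracle(self, rng):
        model, ds = tiny_trained_sensor(rng)
        weights = L.export_weights(model)
        cells, dense = weights
        assert [c.hidden_size for c in cells] == [6, 5]
        for cell in cells:
            np.testing.assert_array_equal(cell.Wci, 0.0)
            np.testing.assert_array_equal(cell.Wco, 0.0)
        diff = L.forward_equivalence(model, weights, ds.inputs[:20])
        assert diff <= 1e-5

    def test_peepholes_change_the_output(self, rng):
        """The peephole terms are real: non-zero Wc* alters the cell."""
        W = random_cell(rng, 4, 3, peepholes=True)
        W0 = random_cell(rng, 4, 3, peepholes=True)
        for name in ("Wci", "Wcf", "Wco"):
            setattr(W0, name, np.zeros(4))
        for f in ("Wxi", "Wxf", "Wxc", "Wxo", "Whi", "Whf", "Whc", "Who",
                  "bi", "bf", "bc", "bo"):
            setattr(W0, f, getattr(W, f))
        x = rng.normal(size=3)
        h_prev, c_prev = rng.normal(size=4), rng.normal(size=4)
        h_peep, _ = lstm_cell_forward(x, h_prev, c_prev, W)
        h_std, _ = lstm_cell_forward(x, h_prev, c_prev, W0)
        assert not np.allclose(h_peep, h_std)

    def test_stacked_forward_with_relu_head(self, rng):
        cells = [random_cell(rng, 4, 3, peepholes=False),
                 random_cell(rng, 3, 4, peepholes=False)]
        seq = rng.normal(size=(7, 3))
        Wd, bd = rng.normal(size=(2, 3)), rng.normal(size=2)
        Wr, br = rng.normal(size=(3, 3)), rng.normal(size=3)
        y = stacked_lstm_forward(seq, cells, Wd, bd, relu_hidden=(Wr, br))
        h = lstm_layer_forward(seq, cells[0], return_sequence=True)
        h = lstm_layer_forward(h, cells[1])
        np.testing.assert_allclose(y, Wd @ np.maximum(Wr @ h + br, 0) + bd)


class TestTraining:
    def test_single_epoch_history(self, rng):
        model, _ = tiny_trained_sensor(rng, epochs=1)
        assert len(model.history) == 1
        assert {"epoch", "train_loss", "val_loss"} <= set(model.history)

    def test_seeded_reruns_are_identical(self, rng):
        m1, ds = tiny_trained_sensor(np.random.default_rng(0), epochs=3)
        m2, _ = tiny_trained_sensor(np.random.default_rng(0), epochs=3)
        assert m1.history["train_loss"].tolist() == \
            m2.history["train_loss"].tolist()
        np.testing.assert_array_equal(m1.network.Wd, m2.network.Wd)

    def test_loss_decreases_on_learnable_task(self, rng):
        model, _ = tiny_trained_sensor(rng, epochs=30)
        h = model.history["train_loss"]
        assert h.iloc[-1] < h.iloc[0]

    def test_predictions_roundtrip_through_scalers(self, rng):
        model, ds = tiny_trained_sensor(rng)
        pred = L.predict(model, ds)
        assert pred.shape == (ds.n_samples, 2)
        assert np.isfinite(pred).all()

    def test_gradients_match_finite_differences(self, monkeypatch, rng):
        monkeypatch.setattr(L, "DTYPE", np.float64)
        net = L.LSTMNetwork(3, (4, 3), 2, seed=5)
        x = rng.standard_normal((5, 7, 3))
        y = rng.standard_normal((5, 2))

        def loss_and_grads():
            pred, cache = net.forward(x)
            err = pred - y
            return (float(np.mean(err**2)), cache,
                    (2.0 / err.size) * err)

        loss, cache, dy = loss_and_grads()
        grads = net.backward(cache, dy)
        params = net.parameters()
        eps = 1e-6
        for p, g in zip(params, grads):
            for _ in range(3):
                ix = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[ix]
                p[ix] = orig + eps
                up, _, _ = loss_and_grads()
                p[ix] = orig - eps
                dn, _, _ = loss_and_grads()
                p[ix] = orig
                fd = (up - dn) / (2 * eps)
                assert g[ix] == pytest.approx(fd, rel=1e-4, abs=1e-9)

    def test_weight_export_to_hdf5(self, tmp_path, rng):
        import h5py
        model, _ = tiny_trained_sensor(rng)
        L.save_weights_h5(model, tmp_path / "w.h5")
        with h5py.File(tmp_path / "w.h5") as fh:
            assert set(fh) == {"lstm_1", "lstm_2", "dense", "meta"}
            assert fh["lstm_1/Wxi"].shape == (6, 3)
            assert fh["lstm_2/Whf"].shape == (5, 5)
            np.testing.assert_array_equal(fh["lstm_1/Wco"][...], 0.0)
            assert list(fh["meta"].attrs["hidden_sizes"]) == [6, 5]
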