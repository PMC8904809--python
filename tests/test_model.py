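import itertools
import math

import numpy as np
import pytest

from _oracles import bce_oracle, residual_block_oracle, sigmoid_oracle
from hidti import nn
from hidti.model import (
    GRID_BLOCKS,
    GRID_HIDDEN,
    GRID_LEARNING_RATES,
    HIDTIConfig,
    HIDTIModel,
    ResidualBlock,
    bce_loss,
    forward,
    grid_search,
    load_hidti,
    residual_block_forward,
    save_hidti,
    train_hidti,
)


def _set_block(block, W1, b1, W2, b2, W3, b3):
    """Load explicit weights; arguments use the (out, in) convention."""
    block.lin1.W.value[...] = W1.T
    block.lin1.b.value[...] = b1
    block.lin2.W.value[...] = W2.T
    block.lin2.b.value[...] = b2
    block.lin3.W.value[...] = W3.T
    block.lin3.b.value[...] = b3


class TestResidualBlock:
    def test_hand_computed_identity_example(self, rng):
        # identity weights, unit gains, zero biases:
        # [1,-1] -> LN -> [1,-1] -> ReLU -> [1,0] -> +x=[2,-1] -> LN -> [1,-1] -> ReLU -> [1,0]
        block = ResidualBlock(2, 2, 2, rng, eps=1e-5)
        eye = np.eye(2)
        zero = np.zeros(2)
        _set_block(block, eye, zero, eye, zero, eye, zero)
        y = residual_block_forward(np.array([1.0, -1.0]), block)
        np.testing.assert_allclose(y, [1.0, 0.0], atol=1e-4)

    def test_all_zero_weights_give_zero_output(self, rng):
        block = ResidualBlock(3, 2, 2, rng)
        z = np.zeros
        _set_block(block, z((2, 3)), z(2), z((2, 2)), z(2), z((2, 3)), z(2))
        y = residual_block_forward(np.array([0.3, -0.7, 2.0]), block)
        np.testing.assert_array_equal(y, np.zeros(2))

    def test_matches_dense_algebra_oracle_on_random_instances(self, rng):
        for _ in range(100):
            block = ResidualBlock(5, 3, 4, rng)
            x = rng.standard_normal(5)
            expected = residual_block_oracle(
                x,
                block.lin1.W.value.T, block.lin1.b.value,
                block.lin2.W.value.T, block.lin2.b.value,
                block.lin3.W.value.T, block.lin3.b.value,
                block.ln1.gain.value, block.ln1.bias.value,
                block.ln2.gain.value, block.ln2.bias.value,
                1e-5,
            )
            np.testing.assert_allclose(
                residual_block_forward(x, block), expected, atol=1e-5
            )

    def test_dimension_mismatch_rejected(self, rng):
        block = ResidualBlock(5, 3, 4, rng)
        with pytest.raises(ValueError):
            residual_block_forward(np.zeros(4), block)


class TestForward:
    def _tiny(self, seed=0, **kw):
        cfg = HIDTIConfig(
            m1=3, m2=4, classifier_hidden=3, seed=seed,
            n_residual_blocks=kw.pop("blocks", 1), **kw
        )
        return HIDTIModel(5, cfg)

    def test_zero_weights_give_half_probability(self, rng):
        model = self._tiny()
        for p in model.parameters():
            p.value[...] = 0.0
        # layer-norm gains back to 1 so the chain is well-defined
        for b in model.blocks:
            b.ln1.gain.value[...] = 1.0
            b.ln2.gain.value[...] = 1.0
        assert forward(model, np.zeros(5)) == pytest.approx(0.5)

    def test_probability_strictly_inside_unit_interval(self, rng):
        model = self._tiny(seed=1)
        X = rng.standard_normal((50, 5)) * 10
        probs = model.predict_proba(X)
        assert np.all(probs > 0) and np.all(probs < 1)

    def test_monotone_in_final_logit(self):
        model = self._tiny(seed=2)
        x = np.ones(5)
        p0 = forward(model, x)
        model.classifier.layers[-1].b.value += 1.0
        assert forward(model, x) > p0

    def test_composition_matches_chained_oracle(self, rng):
        for _ in range(100):
            model = self._tiny(seed=int(rng.integers(1 << 30)))
            x = rng.standard_normal(5)
            block = model.blocks[0]
            h = residual_block_oracle(
                x,
                block.lin1.W.value.T, block.lin1.b.value,
                block.lin2.W.value.T, block.lin2.b.value,
                block.lin3.W.value.T, block.lin3.b.value,
                block.ln1.gain.value, block.ln1.bias.value,
                block.ln2.gain.value, block.ln2.bias.value,
                1e-5,
            )
            lin_h, _, lin_out = model.classifier.layers
            z = np.maximum(lin_h.W.value.T @ h + lin_h.b.value, 0.0)
            logit = float((lin_out.W.value.T @ z + lin_out.b.value)[0])
            assert forward(model, x) == pytest.approx(sigmoid_oracle(logit), abs=1e-5)

    def test_without_residual_classifier_consumes_raw_input(self):
        model = self._tiny(use_residual=False, n_classifier_hidden=2)
        assert model.blocks == []
        assert model.classifier.layers[0].W.value.shape[0] == 5
        hidden_linears = [
            l for l in model.classifier.layers[:-1] if isinstance(l, nn.Linear)
        ]
        assert len(hidden_linears) == 2


class TestBCE:
    def test_matches_closed_forms(self):
        assert bce_loss([1.0], [1]) == pytest.approx(0.0, abs=1e-6)
        assert bce_loss([0.5], [1]) == pytest.approx(math.log(2), abs=1e-9)
        assert bce_loss([0.5], [0]) == pytest.approx(math.log(2), abs=1e-9)

    def test_matches_elementwise_oracle(self, rng):
        probs = rng.random(20)
        labels = (rng.random(20) < 0.5).astype(int)
        assert bce_loss(probs, labels) == pytest.approx(bce_oracle(probs, labels))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss([0.5, 0.5], [1])


def _separable_data(rng, n=120, d=6):
    w = rng.standard_normal(d)
    X = rng.standard_normal((n, d))
    y = (X @ w > 0).astype(float)
    return X, y


class TestTraining:
    CFG = dict(m1=8, m2=8, classifier_hidden=8, batch_size=32, learning_rate=1e-2)

    def test_loss_decreases_on_separable_data(self, rng):
        X, y = _separable_data(rng)
        cfg = HIDTIConfig(max_epochs=50, patience=50, seed=0, **self.CFG)
        model = HIDTIModel(X.shape[1], cfg)
        hist = train_hidti(model, X[:100], y[:100], X[100:], y[100:], cfg)
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_same_seed_gives_identical_history(self, rng):
        X, y = _separable_data(rng)
        cfg = HIDTIConfig(max_epochs=10, patience=10, seed=7, **self.CFG)
        h1 = train_hidti(HIDTIModel(6, cfg), X[:100], y[:100], X[100:], y[100:], cfg)
        h2 = train_hidti(HIDTIModel(6, cfg), X[:100], y[:100], X[100:], y[100:], cfg)
        assert h1 == h2

    def test_empty_validation_rejected(self, rng):
        X, y = _separable_data(rng)
        cfg = HIDTIConfig(max_epochs=5, seed=0, **self.CFG)
        with pytest.raises(ValueError, match="validation"):
            train_hidti(HIDTIModel(6, cfg), X, y, X[:0], y[:0], cfg)

    def test_patience_one_stops_after_one_non_improving_epoch(self, rng):
        # constant validation labels with probability-insensitive metric
        # cannot improve, so training should stop after patience epochs
        X, y = _separable_data(rng)
        cfg = HIDTIConfig(
            max_epochs=100, patience=1, seed=0, learning_rate=1e-12,
            m1=8, m2=8, classifier_hidden=8, batch_size=32,
            early_stopping_metric="auc",
        )
        model = HIDTIModel(6, cfg)
        hist = train_hidti(model, X[:100], y[:100], X[100:], y[100:], cfg)
        # epoch 0 sets the best; epoch 1 fails to improve; stop
        assert len(hist) == 2

    def test_restored_weights_match_best_validation_epoch(self, rng):
        X, y = _separable_data(rng)
        cfg = HIDTIConfig(max_epochs=30, patience=5, seed=3, **self.CFG)
        model = HIDTIModel(6, cfg)
        hist = train_hidti(model, X[:100], y[:100], X[100:], y[100:], cfg)
        best = min(h["val_loss"] for h in hist)
        final = bce_loss(model.predict_proba(X[100:]), y[100:])
        assert final == pytest.approx(best, abs=1e-9)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = HIDTIConfig(m1=4, m2=4, classifier_hidden=4, seed=0)
        model = HIDTIModel(5, cfg)
        x = rng.standard_normal(5)
        save_hidti(model, tmp_path / "m.npz")
        clone = load_hidti(tmp_path / "m.npz")
        assert forward(clone, x) == pytest.approx(forward(model, x))


class TestGridSearch:
    def test_default_lattice_has_54_points(self):
        lattice = list(itertools.product(GRID_BLOCKS, GRID_HIDDEN, GRID_LEARNING_RATES))
        assert len(lattice) == 54

    def test_single_point_grid_returns_that_point(self, rng):
        X, y = _separable_data(rng)
        base = HIDTIConfig(max_epochs=3, patience=3, seed=0,
                           m1=8, m2=8, classifier_hidden=8, batch_size=32)
        cfg, table, model = grid_search(
            X[:100], y[:100], X[100:], y[100:], base,
            blocks=(1,), hidden=(2,), learning_rates=(1e-2,),
        )
        assert (cfg.n_residual_blocks, cfg.n_classifier_hidden) == (1, 2)
        assert cfg.learning_rate == 1e-2
        assert len(table) == 1

    def test_enumeration_order_and_tie_break(self, rng):
        X, y = _separable_data(rng)
        base = HIDTIConfig(max_epochs=1, patience=1, seed=0, learning_rate=1e-12,
                           m1=8, m2=8, classifier_hidden=8, batch_size=32)
        # lr so small that all points share (nearly) the same val AUC:
        # enumeration order must decide
        cfg, table, _ = grid_search(
            X[:100], y[:100], X[100:], y[100:], base,
            blocks=(1, 2), hidden=(1,), learning_rates=(1e-12,),
        )
        assert list(table.columns) == [
            "n_residual_blocks", "n_classifier_hidden", "learning_rate", "val_auc"
        ]
        if table.val_auc.iloc[0] >= table.val_auc.iloc[1]:
            assert cfg.n_residual_blocks == 1
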