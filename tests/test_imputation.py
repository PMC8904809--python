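import numpy as np
import pytest

from hidti.core_data import EmbeddingTable, EntityRegistry, HeteroMatrix
from hidti.imputation import (
    ImputerTrainConfig,
    build_imputer,
    impute,
    load_imputer,
    reconstruction_auc,
    save_imputer,
    train_imputer,
)
from hidti.nn import sigmoid


class TestConstruction:
    def test_ddi_imputer_dimensions_at_benchmark_scale(self):
        model = build_imputer("DDI", 300, 707, seed=0)
        assert model.input_dim == 1007
        assert model.hidden_dims == (1024, 512, 128)
        assert model.net.layers[0].W.value.shape == (1007, 1024)
        assert model.net.layers[-1].W.value.shape == (128, 707)

    def test_pdis_imputer_dimensions(self):
        model = build_imputer("PDIS", 100, 5603, hidden_dims=(8, 8, 8), seed=0)
        assert model.input_dim == 5703
        assert model.target_dim == 5603

    def test_dsie_output_length_at_benchmark_scale(self):
        model = build_imputer("DSIE", 300, 4192, hidden_dims=(8, 8, 8), seed=0)
        out = impute(model, np.zeros(300))
        assert out.shape == (4192,)

    def test_same_seed_gives_identical_initial_weights(self):
        m1 = build_imputer("DDIS", 16, 20, (8, 8, 8), seed=5)
        m2 = build_imputer("DDIS", 16, 20, (8, 8, 8), seed=5)
        for p1, p2 in zip(m1.net.parameters(), m2.net.parameters()):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            build_imputer("PPI", 16, 20, (8, 8, 8))
        with pytest.raises(ValueError):
            build_imputer("DDI", 0, 20, (8, 8, 8))
        with pytest.raises(ValueError):
            build_imputer("DDI", 16, 20, (8, 8))


def _toy_problem(rng, n=40, emb_dim=10, cols=12):
    reg = EntityRegistry("drug", [f"d{i}" for i in range(n)])
    emb = EmbeddingTable(reg, rng.standard_normal((n, emb_dim)))
    rows = (rng.random((n, cols)) < 0.3).astype(float)
    matrix = HeteroMatrix("DSIE", reg, EntityRegistry("side_effect", [f"s{i}" for i in range(cols)]), rows)
    return reg, emb, matrix


class TestTraining:
    def test_single_entity_overfits_to_its_row(self, rng):
        reg, emb, matrix = _toy_problem(rng)
        model = build_imputer("DSIE", 10, 12, (32, 32, 32), seed=0, dropout_rate=0.0)
        cfg = ImputerTrainConfig(
            learning_rate=1e-2, max_epochs=400, batch_size=4,
            validation_fraction=0.0, weight_decay=0.0, input_mask_rate=0.0, seed=0,
        )
        train_imputer(model, emb, matrix, [reg.ids[0]], cfg)
        X = np.concatenate([emb.values[0], matrix.values[0]])[None, :]
        recon = model.predict_from_full_input(X)[0]
        assert np.max(np.abs(recon - matrix.values[0])) < 0.1

    def test_zero_epochs_leaves_model_unchanged(self, rng):
        reg, emb, matrix = _toy_problem(rng)
        model = build_imputer("DSIE", 10, 12, (8, 8, 8), seed=1)
        before = [p.value.copy() for p in model.net.parameters()]
        hist = train_imputer(
            model, emb, matrix, list(reg.ids), ImputerTrainConfig(max_epochs=0)
        )
        assert hist == []
        for p, b in zip(model.net.parameters(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_training_is_deterministic_given_seed(self, rng):
        reg, emb, matrix = _toy_problem(rng)
        cfg = ImputerTrainConfig(max_epochs=10, seed=9)
        runs = []
        for _ in range(2):
            model = build_imputer("DSIE", 10, 12, (8, 8, 8), seed=2)
            train_imputer(model, emb, matrix, list(reg.ids), cfg)
            runs.append([p.value.copy() for p in model.net.parameters()])
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)

    def test_duplicate_entities_are_deduplicated(self, rng):
        reg, emb, matrix = _toy_problem(rng)
        cfg = ImputerTrainConfig(max_epochs=3, seed=0)
        m1 = build_imputer("DSIE", 10, 12, (8, 8, 8), seed=2)
        train_imputer(m1, emb, matrix, [reg.ids[0], reg.ids[1]], cfg)
        m2 = build_imputer("DSIE", 10, 12, (8, 8, 8), seed=2)
        train_imputer(m2, emb, matrix, [reg.ids[0], reg.ids[1], reg.ids[0]], cfg)
        for p1, p2 in zip(m1.net.parameters(), m2.net.parameters()):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_empty_subset_rejected(self, rng):
        reg, emb, matrix = _toy_problem(rng)
        model = build_imputer("DSIE", 10, 12, (8, 8, 8), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_imputer(model, emb, matrix, [], ImputerTrainConfig())


class TestImpute:
    def test_zero_embedding_is_deterministic_constant(self):
        model = build_imputer("DDI", 6, 9, (8, 8, 8), seed=3)
        out1 = impute(model, np.zeros(6))
        out2 = impute(model, np.zeros(6))
        np.testing.assert_array_equal(out1, out2)
        # equals the plain forward pass of an all-zero input vector
        expected = model.predict_from_full_input(np.zeros((1, 15)))[0]
        np.testing.assert_array_equal(out1, expected)

    def test_outputs_lie_in_unit_interval(self, rng):
        model = build_imputer("DDI", 6, 9, (8, 8, 8), seed=3)
        out = impute(model, rng.standard_normal((20, 6)) * 5)
        assert np.all(out >= 0) and np.all(out <= 1)

    def test_dimension_mismatch_rejected(self):
        model = build_imputer("DDI", 6, 9, (8, 8, 8), seed=3)
        with pytest.raises(ValueError):
            impute(model, np.zeros(7))

    def test_masking_invariant_output_independent_of_true_rows(self, rng):
        """impute() never reads the query entity's association values."""
        reg, emb, matrix = _toy_problem(rng)
        model = build_imputer("DSIE", 10, 12, (8, 8, 8), seed=4)
        train_imputer(model, emb, matrix, list(reg.ids[:30]), ImputerTrainConfig(max_epochs=5, seed=0))
        query = emb.values[35]
        before = impute(model, query)
        matrix.values[35] = 1.0 - matrix.values[35]  # corrupt the truth
        after = impute(model, query)
        np.testing.assert_array_equal(before, after)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = build_imputer("DDIS", 6, 9, (8, 8, 8), seed=3)
        x = rng.standard_normal(6)
        save_imputer(model, tmp_path / "imp.npz")
        clone = load_imputer(tmp_path / "imp.npz")
        np.testing.assert_array_equal(impute(model, x), impute(clone, x))


class TestReconstructionAUC:
    def test_perfect_imputer_scores_auc_one(self, rng, monkeypatch):
        reg, emb, matrix = _toy_problem(rng)
        model = build_imputer("DSIE", 10, 12, (8, 8, 8), seed=0)
        import hidti.imputation as imp_mod

        monkeypatch.setattr(
            imp_mod,
            "impute",
            lambda m, E: matrix.values[-10:],
        )
        auc, per_row = imp_mod.reconstruction_auc(model, emb, matrix, list(reg.ids[-10:]))
        assert auc == 1.0
        assert all(v == 1.0 for v in per_row.values())

    def test_constant_imputer_scores_auc_half(self, rng, monkeypatch):
        reg, emb, matrix = _toy_problem(rng)
        model = build_imputer("DSIE", 10, 12, (8, 8, 8), seed=0)
        import hidti.imputation as imp_mod

        monkeypatch.setattr(
            imp_mod, "impute", lambda m, E: np.full((10, 12), 0.5)
        )
        auc, _ = imp_mod.reconstruction_auc(model, emb, matrix, list(reg.ids[-10:]))
        assert auc == 0.5

    def test_single_class_rows_are_excluded_from_per_row_table(self, rng):
        reg, emb, matrix = _toy_problem(rng)
        matrix.values[-1] = 0.0  # all-negative row: per-row AUC undefined
        model = build_imputer("DSIE", 10, 12, (8, 8, 8), seed=0)
        _, per_row = reconstruction_auc(model, emb, matrix, list(reg.ids[-5:]))
        assert reg.ids[-1] not in per_row

    def test_planted_logistic_structure_recovered_above_chance(self):
        """Held-out reconstruction AUC > 0.8 when rows follow a logistic
        model on the embeddings (~100 entities, 50 columns)."""
        rng = np.random.default_rng(0)
        n, emb_dim, cols, latent = 100, 12, 50, 4
        u = rng.standard_normal((n, latent))
        w = rng.standard_normal((cols, latent))
        logits = 3.0 * u @ w.T / np.sqrt(latent) - 1.5
        rows = (rng.random((n, cols)) < sigmoid(logits)).astype(float)
        A = rng.standard_normal((latent, emb_dim)) / np.sqrt(latent)
        embs = u @ A + 0.3 * rng.standard_normal((n, emb_dim))
        reg = EntityRegistry("drug", [f"d{i}" for i in range(n)])
        emb = EmbeddingTable(reg, embs)
        matrix = HeteroMatrix(
            "DSIE", reg, EntityRegistry("side_effect", [f"s{i}" for i in range(cols)]), rows
        )
        model = build_imputer("DSIE", emb_dim, cols, (64, 32, 16), seed=0, dropout_rate=0.2)
        train_imputer(model, emb, matrix, list(reg.ids[:80]), ImputerTrainConfig(seed=0, max_epochs=300))
        auc, _ = reconstruction_auc(model, emb, matrix, list(reg.ids[80:]))
        assert auc > 0.8
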