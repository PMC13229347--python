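"""Presets, the hyperparameter grid, metrics, and the training loop."""

import hashlib

import numpy as np
import pytest

import quadnet as q
from quadnet.pairs import DatasetSplits, SplitSizes
from quadnet.training import (
    GRID_BATCH_SIZES,
    GRID_LEARNING_RATES,
    GRID_WEIGHT_DECAYS,
    OPTIMIZERS,
    SCHEDULERS,
    grid_space,
    preset_config,
)


class TestPresets:
    def test_tuned_balanced(self):
        cfg = preset_config("tuned-balanced")
        assert (cfg.optimizer, cfg.learning_rate, cfg.weight_decay) == ("adamw", 0.0005, 1e-4)
        assert cfg.scheduler == "plateau" and cfg.batch_size == 128

    def test_tuned_oversampled(self):
        cfg = preset_config("tuned-oversampled")
        assert (cfg.optimizer, cfg.learning_rate, cfg.weight_decay) == ("rmsprop", 0.0001, 1e-5)
        assert cfg.scheduler == "step" and cfg.batch_size == 256

    def test_named_presets(self):
        assert preset_config("conservative").learning_rate == 0.0005
        assert preset_config("aggressive").optimizer == "adam"
        assert preset_config("balanced").scheduler == "step"

    def test_aliases(self):
        assert preset_config("table1-balanced") == preset_config("tuned-balanced")

    def test_unknown_name_lists_valid(self):
        with pytest.raises(ValueError, match="conservative"):
            preset_config("nonsense")


class TestGrid:
    def test_full_cartesian_size(self):
        assert len(list(grid_space())) == 4 * 3 * 3 * 3 * 4

    def test_values_from_printed_sets(self):
        for cfg in grid_space():
            assert cfg.learning_rate in GRID_LEARNING_RATES
            assert cfg.weight_decay in GRID_WEIGHT_DECAYS
            assert cfg.optimizer in OPTIMIZERS
            assert cfg.scheduler in SCHEDULERS
            assert cfg.batch_size in GRID_BATCH_SIZES

    def test_budgeted_subset_deterministic(self):
        a = list(grid_space(budget=10, seed=3))
        b = list(grid_space(budget=10, seed=3))
        assert len(a) == 10 and a == b


class TestMetrics:
    def test_perfect_separation_all_hundred(self):
        y = np.array([1, 0, 1, 0, 1])
        p = np.array([0.9, 0.1, 0.8, 0.2, 0.99])
        rep = q.metrics_from_probabilities(p, y)
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 100.0
        assert rep.auc_roc == 100.0

    def test_random_scores_near_chance_auc(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 5000)
        p = rng.random(10_000)
        rep = q.metrics_from_probabilities(p, y)
        assert 48.0 <= rep.auc_roc <= 52.0

    def test_ten_pair_manual_fixture(self):
        p = np.array([0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.9, 0.2, 0.6, 0.1])
        y = np.array([1, 1, 0, 1, 1, 0, 0, 0, 0, 0])
        rep = q.metrics_from_probabilities(p, y)
        # thresholded: TP=3 FP=3 FN=1 TN=3
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (3, 3, 1, 3)
        assert rep.accuracy == pytest.approx(60.0)
        assert rep.precision == pytest.approx(50.0)
        assert rep.recall == pytest.approx(75.0)
        assert rep.f1 == pytest.approx(60.0)

    def test_f1_harmonic_identity(self):
        rng = np.random.default_rng(1)
        rep = q.metrics_from_probabilities(rng.random(200), rng.integers(0, 2, 200))
        if rep.precision + rep.recall > 0:
            assert rep.f1 == pytest.approx(
                2 * rep.precision * rep.recall / (rep.precision + rep.recall)
            )

    def test_single_class_auc_undefined(self):
        rep = q.metrics_from_probabilities(np.array([0.2, 0.8]), np.array([1, 1]))
        assert rep.auc_roc is None


def _toy_training_setup(n_pairs=600, dim=12, seed=5):
    spec = q.SyntheticSpec(n_proteins=120, dim=dim, rule_rank=3, seed=seed)
    store = q.generate_protein_embeddings(spec)
    oracle = q.plant_interaction_rule(store, spec)
    pairs = q.sample_pair_dataset(store, oracle, n_pairs, seed=seed)
    scaler = q.fit_robust_scaler(store.matrix)
    sizes = q.compute_split_sizes(n_pairs)
    splits = q.two_stage_stratified_split(pairs, sizes, seed=seed)
    return store, scaler, splits


class TestTrainLoop:
    def test_learning_happens_and_history_contract(self):
        store, scaler, splits = _toy_training_setup()
        cfg = q.TrainingConfig(max_epochs=10, patience=10, seed=0, batch_size=64)
        model = q.QuadNet(q.ModelConfig(input_dim=12, hidden_dim=32, n_tokens=4,
                                        num_heads=4, seed=0))
        model, hist = q.train_model(model, splits, store, scaler, cfg)
        accs = [r.val_accuracy for r in hist.records]
        assert hist.best_val_accuracy == max(accs)
        assert hist.best_val_accuracy > accs[0]
        assert len(hist.records) <= cfg.max_epochs

    def test_memorizes_random_pairs(self):
        """Capacity check: the model overfits random labels to >99%."""
        rng = np.random.default_rng(0)
        n, dim = 512, 32
        ids = [f"P{i:06d}" for i in range(2 * n)]
        store = q.EmbeddingStore(ids, rng.standard_normal((2 * n, dim)))
        pairs = q.PairTable.from_arrays(
            [ids[2 * i] for i in range(n)],
            [ids[2 * i + 1] for i in range(n)],
            rng.integers(0, 2, n),
        )
        scaler = q.fit_robust_scaler(store.matrix)
        splits = DatasetSplits(pairs, pairs, pairs, 0, SplitSizes(n, n, n))
        cfg = q.TrainingConfig(
            optimizer="adam", learning_rate=0.001, scheduler="cosine",
            max_epochs=200, patience=5, seed=0, batch_size=64, augment_sigma=0.0,
        )
        model = q.QuadNet(q.ModelConfig(input_dim=dim, hidden_dim=64, seed=0, dropout=0.0))
        model, hist = q.train_model(model, splits, store, scaler, cfg)
        assert hist.best_val_accuracy > 99.0

    def test_seeded_runs_identical(self, tmp_path):
        store, scaler, splits = _toy_training_setup(n_pairs=300)
        cfg = q.TrainingConfig(max_epochs=3, seed=9, batch_size=64)
        digests, histories = [], []
        for run in range(2):
            model = q.QuadNet(q.ModelConfig(input_dim=12, hidden_dim=32, n_tokens=4,
                                            num_heads=4, seed=9))
            model, hist = q.train_model(model, splits, store, scaler, cfg)
            state = model.state_dict()
            h = hashlib.sha256()
            for k in sorted(state):
                h.update(k.encode())
                h.update(state[k].tobytes())
            digests.append(h.hexdigest())
            histories.append([(r.loss.total, r.val_accuracy) for r in hist.records])
        assert digests[0] == digests[1]
        assert histories[0] == histories[1]

    def test_history_csv(self, tmp_path):
        store, scaler, splits = _toy_training_setup(n_pairs=300)
        cfg = q.TrainingConfig(max_epochs=2, seed=1, batch_size=64)
        model = q.QuadNet(q.ModelConfig(input_dim=12, hidden_dim=32, n_tokens=4,
                                        num_heads=4, seed=1))
        model, hist = q.train_model(model, splits, store, scaler, cfg)
        path = tmp_path / "history.csv"
        hist.to_csv(path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("epoch,L_interact")
        assert len(lines) == len(hist.records) + 1

    def test_evaluate_report(self):
        store, scaler, splits = _toy_training_setup(n_pairs=300)
        model = q.QuadNet(q.ModelConfig(input_dim=12, hidden_dim=32, n_tokens=4,
                                        num_heads=4, seed=2))
        rep = q.evaluate(model, splits.test, store, scaler)
        assert rep.n == len(splits.test)
        assert 0 <= rep.accuracy <= 100

    def test_config_validation(self):
        with pytest.raises(ValueError, match="optimizer"):
            q.TrainingConfig(optimizer="sgd")
        with pytest.raises(ValueError, match="scheduler"):
            q.TrainingConfig(scheduler="exponential")
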