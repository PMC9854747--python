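"""SOM classifier: training, winner search, labeling, balancing."""

import numpy as np
import pandas as pd
import pytest

from _oracles import quantization_error_bruteforce, winning_neuron_bruteforce
from fecgsqa.exceptions import ConfigurationError, NotTrainedError
from fecgsqa.som_classifier import (SOMModel, balance_dataset, classify,
                                    label_neurons, load_som,
                                    quantization_error, save_som, train_som,
                                    winning_neuron)
from fecgsqa.synthetic_fecg import QualityLevel


def gaussian_clusters(seed, n_per_class=60, dim=5, separation=6.0):
    rng = np.random.default_rng(seed)
    centers = separation * np.eye(dim)[:3]
    X = np.vstack([c + rng.standard_normal((n_per_class, dim))
                   for c in centers])
    labels = ([QualityLevel.HIGH] * n_per_class
              + [QualityLevel.MEDIUM] * n_per_class
              + [QualityLevel.LOW] * n_per_class)
    return pd.DataFrame(X), labels


def identity_model(weights):
    """SOM with unit scaler so weights live in raw feature space."""
    rows, cols, d = weights.shape
    return SOMModel(weights=weights, scaler_mean=np.zeros(d),
                    scaler_std=np.ones(d), feature_names=list(range(d)),
                    learning_rate_initial=0.5, iterations=0,
                    neighborhood="bubble", seed=0)


class TestBalanceDataset:
    def test_undersamples_to_minority(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((1071, 4)))
        labels = ([QualityLevel.MEDIUM] * 500 + [QualityLevel.HIGH] * 300
                  + [QualityLevel.LOW] * 271)
        out = balance_dataset(X, labels, seed=1)
        assert len(out.X) == 813
        for level in QualityLevel:
            assert sum(l == level for l in out.labels) == 271

    def test_already_balanced_identity(self):
        X, labels = gaussian_clusters(1, n_per_class=10)
        out = balance_dataset(X, labels, seed=0)
        assert sorted(out.kept_indices.tolist()) == list(range(30))

    def test_deterministic(self):
        X, labels = gaussian_clusters(2, n_per_class=15)
        labels = labels[:-5] + [QualityLevel.MEDIUM] * 5   # unbalance
        a = balance_dataset(X, labels, seed=3)
        b = balance_dataset(X, labels, seed=3)
        np.testing.assert_array_equal(a.kept_indices, b.kept_indices)

    def test_absent_class_rejected(self):
        X = pd.DataFrame(np.zeros((4, 2)))
        with pytest.raises(ConfigurationError):
            balance_dataset(X, [QualityLevel.HIGH] * 4, seed=0)


class TestTrainSOM:
    def test_quantization_error_improves(self):
        X, _ = gaussian_clusters(3)
        for seed in range(3):
            model = train_som(X, grid=(6, 6), iterations=5000, seed=seed)
            trace = model.qe_trace
            assert trace[-1][1] <= trace[0][1]

    def test_same_seed_identical_weights(self):
        X, _ = gaussian_clusters(4)
        a = train_som(X, iterations=2000, seed=9)
        b = train_som(X, iterations=2000, seed=9)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_nan_rejected(self):
        X = np.full((10, 3), np.nan)
        with pytest.raises(ConfigurationError):
            train_som(X, iterations=10)

    def test_non_bubble_rejected(self):
        X, _ = gaussian_clusters(5, n_per_class=5)
        with pytest.raises(ConfigurationError):
            train_som(X, neighborhood="gaussian")


class TestWinningNeuron:
    def test_single_neuron_grid(self):
        model = identity_model(np.zeros((1, 1, 3)))
        assert winning_neuron(model, np.array([5.0, 1.0, -2.0])) == (0, 0)

    def test_exact_weight_match(self, rng):
        weights = rng.standard_normal((4, 4, 3))
        model = identity_model(weights)
        assert winning_neuron(model, weights[2, 3]) == (2, 3)

    def test_matches_exhaustive_scan(self, rng):
        weights = rng.standard_normal((5, 7, 4))
        model = identity_model(weights)
        for _ in range(100):
            x = rng.standard_normal(4)
            assert winning_neuron(model, x) == \
                winning_neuron_bruteforce(weights, x)

    def test_dimension_mismatch_rejected(self, rng):
        model = identity_model(rng.standard_normal((2, 2, 3)))
        with pytest.raises(ConfigurationError):
            winning_neuron(model, np.zeros(4))


class TestQuantizationError:
    def test_zero_on_weight_vectors(self, rng):
        weights = rng.standard_normal((3, 3, 2))
        model = identity_model(weights)
        X = weights.reshape(-1, 2)
        assert quantization_error(model, X) == pytest.approx(0.0, abs=1e-12)

    def test_single_sample_distance(self):
        weights = np.zeros((2, 2, 2))
        weights[1, 1] = [3.0, 4.0]
        model = identity_model(weights)
        assert quantization_error(model, np.array([[0.0, 0.1]])) == \
            pytest.approx(0.1)

    def test_matches_bruteforce(self, rng):
        weights = rng.standard_normal((4, 4, 3))
        model = identity_model(weights)
        Z = rng.standard_normal((20, 3))
        assert quantization_error(model, Z) == pytest.approx(
            quantization_error_bruteforce(weights, Z), abs=1e-9)

    def test_empty_rejected(self, rng):
        model = identity_model(rng.standard_normal((2, 2, 2)))
        with pytest.raises(ConfigurationError):
            quantization_error(model, np.empty((0, 2)))


class TestLabelNeurons:
    def test_majority_of_three(self):
        weights = np.zeros((1, 2, 1))
        weights[0, 0] = -5.0
        weights[0, 1] = 5.0
        model = identity_model(weights)
        X = np.array([[-5.0]] * 3 + [[5.0]] * 3)
        labels = [QualityLevel.LOW, QualityLevel.LOW, QualityLevel.HIGH,
                  QualityLevel.HIGH, QualityLevel.HIGH, QualityLevel.HIGH]
        model = label_neurons(model, X, labels, seed=0)
        assert model.neuron_labels[0, 0] == QualityLevel.LOW
        assert model.neuron_labels[0, 1] == QualityLevel.HIGH

    def test_single_winner_label(self):
        weights = np.zeros((1, 2, 1))
        weights[0, 0] = -5.0
        weights[0, 1] = 5.0
        model = identity_model(weights)
        model = label_neurons(model, np.array([[-5.0]]),
                              [QualityLevel.MEDIUM], seed=0)
        assert model.neuron_labels[0, 0] == QualityLevel.MEDIUM
        # empty neuron inherits from nearest labeled neighbor
        assert model.neuron_labels[0, 1] == QualityLevel.MEDIUM

    def test_three_way_tie_resolves_low(self):
        model = identity_model(np.zeros((1, 1, 1)))
        X = np.array([[0.0], [0.0], [0.0]])
        labels = [QualityLevel.HIGH, QualityLevel.MEDIUM, QualityLevel.LOW]
        model = label_neurons(model, X, labels, seed=0)
        assert model.neuron_labels[0, 0] == QualityLevel.LOW

    def test_replay_matches_seeded_simulation(self, rng):
        """Full labeling equals a scripted replay with the same seed."""
        X, labels = gaussian_clusters(6, n_per_class=30)
        model = train_som(X, grid=(4, 4), iterations=3000, seed=1)
        model = label_neurons(model, X, labels, seed=7)

        # replay by hand
        Z = model.standardize(X.to_numpy(dtype=float))
        flat = model.weights.reshape(-1, model.weights.shape[-1])
        winners = ((Z[:, None, :] - flat[None]) ** 2).sum(2).argmin(1)
        replay_rng = np.random.default_rng(7)
        for neuron in range(16):
            members = np.flatnonzero(winners == neuron)
            if len(members) == 0:
                continue
            chosen = replay_rng.choice(members, 3, replace=False) \
                if len(members) >= 3 else members
            votes = {}
            for i in chosen:
                votes[int(labels[i])] = votes.get(int(labels[i]), 0) + 1
            ranked = sorted(votes.items(), key=lambda kv: -kv[1])
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                expected = int(QualityLevel.LOW)
            else:
                expected = ranked[0][0]
            assert model.neuron_labels.reshape(-1)[neuron] == expected


class TestClassify:
    def test_weight_vector_classified_as_neuron_label(self, rng):
        X, labels = gaussian_clusters(7, n_per_class=30)
        model = train_som(X, grid=(4, 4), iterations=3000, seed=2)
        model = label_neurons(model, X, labels, seed=2)
        raw = model.weights[1, 2] * model.scaler_std + model.scaler_mean
        assert classify(model, raw) == QualityLevel(model.neuron_labels[1, 2])

    def test_unlabeled_model_rejected(self):
        X, _ = gaussian_clusters(8, n_per_class=10)
        model = train_som(X, iterations=500, seed=0)
        with pytest.raises(NotTrainedError):
            classify(model, X)

    def test_cluster_recovery_accuracy(self):
        """Well-separated clusters are recovered almost perfectly."""
        for seed in (0, 1):
            X, labels = gaussian_clusters(seed + 10)
            model = train_som(X, grid=(8, 8), iterations=20_000, seed=seed)
            model = label_neurons(model, X, labels, seed=seed)
            preds = classify(model, X)
            acc = np.mean([p == t for p, t in zip(preds, labels)])
            assert acc >= 0.95
            for level in QualityLevel:
                idx = [i for i, t in enumerate(labels) if t == level]
                recall = np.mean([preds[i] == level for i in idx])
                assert recall >= 0.9


class TestSerialization:
    def test_roundtrip(self, tmp_path):
        X, labels = gaussian_clusters(9, n_per_class=20)
        model = train_som(X, grid=(4, 4), iterations=1000, seed=3)
        model = label_neurons(model, X, labels, seed=3)
        save_som(model, tmp_path / "som.json")
        back = load_som(tmp_path / "som.json")
        np.testing.assert_allclose(back.weights, model.weights)
        np.testing.assert_array_equal(back.neuron_labels, model.neuron_labels)
        assert classify(back, X) == classify(model, X)
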