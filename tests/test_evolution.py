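"""Genome codec, dominance/Pareto front, variation operators and the
optimization loop."""

import numpy as np
import pytest

import paretoppi as pp
from paretoppi import evolution as evo


def obj(*values):
    return evo.ObjectiveVector(names=tuple(f"o{i}" for i in range(len(values))),
                               values=tuple(float(v) for v in values))


def brute_force_front(vectors):
    """Independent O(n^2) dominance filter (plain double loop)."""
    keep = []
    for i, a in enumerate(vectors):
        dominated = False
        for j, b in enumerate(vectors):
            if i == j:
                continue
            if all(x >= y for x, y in zip(b.values, a.values)) and any(
                    x > y for x, y in zip(b.values, a.values)):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return keep


class TestDecode:
    config = evo.EAConfig(seed=0)

    def test_threshold_mask(self):
        genes = np.array([0.9, 0.1, 0.6, 0.5, 0.2, 0.3, 0.4])  # 3 features
        g = evo.decode_genome(genes, 3, "classification", self.config)
        assert g.feature_mask == (True, False, True)

    def test_all_off_repaired_to_argmax(self):
        genes = np.array([0.2, 0.45, 0.1, 0.5, 0.2, 0.3, 0.4])
        g = evo.decode_genome(genes, 3, "classification", self.config)
        assert g.feature_mask == (False, True, False)

    def test_deterministic_and_length_checked(self):
        genes = np.random.default_rng(0).random(evo.n_genes_for(10))
        g1 = evo.decode_genome(genes, 10, "regression", self.config)
        g2 = evo.decode_genome(genes, 10, "regression", self.config)
        assert g1 == g2
        with pytest.raises(ValueError, match="genes"):
            evo.decode_genome(genes[:-1], 10, "regression", self.config)

    def test_hyperparameters_within_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            g = evo.decode_genome(rng.random(evo.n_genes_for(5)), 5,
                                  "classification", self.config)
            h = g.hyperparameters
            assert self.config.c_bounds[0] <= h["C"] <= self.config.c_bounds[1]
            assert self.config.gamma_bounds[0] <= h["gamma"] <= self.config.gamma_bounds[1]
            assert self.config.trees_bounds[0] <= h["n_trees"] <= self.config.trees_bounds[1]
            assert g.estimator in evo.CLASSIFICATION_ESTIMATORS

    def test_nn_regressor_only_when_enabled(self):
        rng = np.random.default_rng(5)
        kinds = {evo.decode_genome(rng.random(evo.n_genes_for(4)), 4,
                                   "regression", self.config).estimator
                 for _ in range(60)}
        assert evo.NN_REGRESSOR not in kinds
        cfg = evo.EAConfig(seed=0, enable_nn_regressor=True)
        kinds_nn = {evo.decode_genome(rng.random(evo.n_genes_for(4)), 4,
                                      "regression", cfg).estimator
                    for _ in range(120)}
        assert evo.NN_REGRESSOR in kinds_nn


class TestDominance:
    def test_examples(self):
        assert evo.dominates(obj(0.9, -5), obj(0.8, -10))
        assert not evo.dominates(obj(0.9, -5), obj(0.9, -5))  # identical
        assert not evo.dominates(obj(0.9, -10), obj(0.8, -5))  # trade-off

    def test_mismatched_objectives_error(self):
        a = evo.ObjectiveVector(names=("x",), values=(1.0,))
        b = evo.ObjectiveVector(names=("y",), values=(1.0,))
        with pytest.raises(ValueError):
            evo.dominates(a, b)

    def test_front_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            vectors = [obj(*rng.random(3)) for _ in range(60)]
            assert evo.pareto_front(vectors) == brute_force_front(vectors)

    def test_degenerate_fronts(self):
        assert evo.pareto_front([obj(1, 2)]) == [0]
        same = [obj(1, 2)] * 4
        assert evo.pareto_front(same) == [0, 1, 2, 3]
        with pytest.raises(ValueError):
            evo.pareto_front([])


class TestOperators:
    rng = np.random.default_rng(0)

    def test_two_point_membership_and_boundary(self):
        p1, p2 = np.zeros(10), np.ones(10)
        for _ in range(20):
            c1, c2 = evo.two_point_crossover(p1, p2, self.rng)
            assert set(np.unique(c1)) <= {0.0, 1.0}
            np.testing.assert_array_equal(c1 + c2, np.ones(10))
        # cut points (0, n) swap the parents entirely
        class FixedRng:
            def integers(self, lo, hi, size):
                return np.array([0, 10])
        c1, c2 = evo.two_point_crossover(p1, p2, FixedRng())
        np.testing.assert_array_equal(c1, p2)
        np.testing.assert_array_equal(c2, p1)

    def test_arithmetic_children_are_convex_combinations(self):
        p1, p2 = np.zeros(6), np.ones(6)
        c1, c2 = evo.arithmetic_crossover(p1, p2, self.rng)
        assert np.all((0 <= c1) & (c1 <= 1))
        np.testing.assert_allclose(c1 + c2, 1.0)

    def test_mutation_extremes(self):
        genes = self.rng.random(50)
        np.testing.assert_array_equal(evo.mutate(genes, 0.0, self.rng), genes)
        mutated = evo.mutate(genes, 1.0, np.random.default_rng(1))
        assert not np.array_equal(mutated, genes)


class TestWeightedFitness:
    def test_all_ones_gives_sum_of_weights(self):
        names = tuple(n for n, _ in evo.CLASSIFICATION_OBJECTIVES)
        v = evo.ObjectiveVector(names=names, values=(1.0,) * len(names))
        w = evo.objective_weights("classification")
        assert evo.weighted_fitness(v, w) == sum(w.values()) == 27.0

    def test_zero_weights_and_negative_error(self):
        v = obj(0.5, 0.7)
        assert evo.weighted_fitness(v, {"o0": 0, "o1": 0}) == 0.0
        with pytest.raises(ValueError):
            evo.weighted_fitness(v, {"o0": -1, "o1": 0})

    def test_accuracy_and_f1_weighted_tenfold(self):
        w = evo.objective_weights("classification")
        assert w["accuracy"] == w["f1"] == 10.0
        assert w["precision"] == 1.0


def separable_data(n=120, d=8, seed=0, informative=(0, 1)):
    """Two well-separated Gaussian blobs on the informative columns."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, d))
    for col in informative:
        X[:, col] += 4.0 * y
    return X, y


class TestEvaluateIndividual:
    config = evo.EAConfig(seed=0, trees_bounds=(10, 40))

    def genome(self, d, mask_idx, estimator_gene=0.9):
        genes = np.full(evo.n_genes_for(d), 0.1)
        genes[list(mask_idx)] = 0.9
        genes[d] = estimator_gene  # random forest
        genes[d + 3] = 0.5
        return evo.decode_genome(genes, d, "classification", self.config)

    def test_separable_fixture_high_accuracy(self):
        X, y = separable_data()
        g = self.genome(8, [0, 1])
        objv, metrics = evo.evaluate_individual(g, X, y, 5, 0, "classification",
                                                self.config)
        assert metrics["cv_accuracy"] >= 0.95
        assert dict(zip(objv.names, objv.values))["accuracy"] >= 0.95

    def test_shuffled_labels_null_auc(self):
        X, y = separable_data(seed=1)
        y = np.random.default_rng(2).permutation(y)
        g = self.genome(8, [0, 1])
        _, metrics = evo.evaluate_individual(g, X, y, 5, 0, "classification",
                                             self.config)
        assert abs(metrics["cv_auc"] - 0.5) < 0.1

    def test_noise_only_mask_near_majority_rate(self):
        X, y = separable_data(seed=3)
        g = self.genome(8, [4, 5, 6])  # pure-noise columns
        _, metrics = evo.evaluate_individual(g, X, y, 5, 0, "classification",
                                             self.config)
        assert abs(metrics["cv_accuracy"] - 0.5) < 0.12  # balanced classes

    def test_regression_objectives(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 6))
        y01 = 1 / (1 + np.exp(-(X[:, 0] + 0.5 * X[:, 1])))
        genes = np.full(evo.n_genes_for(6), 0.1)
        genes[[0, 1]] = 0.9
        genes[6] = 0.95  # rf regressor
        g = evo.decode_genome(genes, 6, "regression", self.config)
        objv, metrics = evo.evaluate_individual(g, X, y01, 4, 0, "regression",
                                                self.config)
        assert metrics["cv_spearman_rho"] > 0.7
        assert set(objv.names) == {n for n, _ in evo.REGRESSION_OBJECTIVES}


class TestRunOptimization:
    def test_determinism_and_logs(self):
        X, y = separable_data(n=80, d=6, seed=7)
        cfg = evo.EAConfig(population_size=8, max_generations=3, cv_folds=3,
                           seed=13, trees_bounds=(10, 30))
        f1 = evo.run_optimization(X, y, cfg, task="classification")
        f2 = evo.run_optimization(X, y, cfg, task="classification")
        assert f1.manifest() == f2.manifest()
        assert [m.genes for m in f1.members] == [m.genes for m in f2.members]
        assert len(f1.history) == cfg.max_generations + 1
        # elitism: best weighted fitness never decreases
        fits = [h["best_fitness"] for h in f1.history]
        assert all(a <= b + 1e-12 for a, b in zip(fits, fits[1:]))

    def test_front_is_mutually_non_dominated(self, tiny_classifier_front):
        members = tiny_classifier_front.members
        for i, a in enumerate(members):
            for j, b in enumerate(members):
                if i != j:
                    assert not evo.dominates(a.objectives, b.objectives)

    def test_members_have_fitted_models_and_nonempty_masks(self, tiny_classifier_front,
                                                           small_matrix):
        X, M, y = small_matrix
        for m in tiny_classifier_front.members:
            assert len(m.feature_indices) >= 1
            probs = m.predict_proba(X.to_numpy()[:5])
            assert np.all((0 <= probs) & (probs <= 1))

    def test_too_small_dataset_errors(self):
        X, y = separable_data(n=8, d=4)
        with pytest.raises(ValueError):
            evo.run_optimization(X, y, evo.EAConfig(cv_folds=10, seed=0),
                                 task="classification")

    def test_regression_run_small(self, tiny_regressor_front):
        front, scaler = tiny_regressor_front
        assert len(front.members) >= 1
        best = front.best()
        assert best.metrics["cv_rmse"] is not None
        preds = best.predict(np.random.default_rng(0).random((3, 61)))
        assert np.all((0 <= preds) & (preds <= 1))
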