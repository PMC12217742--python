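import numpy as np
import pytest

import paretoppi as pp

# Three expression datasets keep the small worlds fast; the remaining
# co-expression features are then genuinely missing, which exercises the
# missingness mask throughout the suite.
SMALL_EXPR = ("GDS531", "GDS534", "GDS596")


@pytest.fixture(scope="session")
def small_world():
    return pp.generate_world(n_proteins=40, n_positive=30, n_negative=60,
                             noise=0.05, seed=7, expression_datasets=SMALL_EXPR)


@pytest.fixture(scope="session")
def small_matrix(small_world):
    X, M, y = small_world.feature_matrix()
    return X, M, y


@pytest.fixture(scope="session")
def tiny_config():
    return pp.EAConfig(population_size=10, max_generations=4, cv_folds=3,
                       seed=5, trees_bounds=(10, 40))


@pytest.fixture(scope="session")
def tiny_classifier_front(small_matrix, tiny_config):
    X, M, y = small_matrix
    return pp.run_optimization(X.to_numpy(), y, tiny_config, task="classification")


@pytest.fixture(scope="session")
def tiny_regressor_front(small_world, small_matrix):
    X, M, y = small_matrix
    raw, truth = pp.generate_affinity_table(small_world, n_records=30, sd=0.5,
                                            seed=5, include_decoys=False)
    records, _ = pp.curate(raw)
    pair_keys = ["|".join(r.pair) for r in records]
    endpoint, scaler = pp.normalize_endpoint([r.delta_g_kj for r in records])
    Xr = X.loc[pair_keys].to_numpy()
    config = pp.EAConfig(population_size=10, max_generations=4, cv_folds=3,
                         seed=9, trees_bounds=(10, 40))
    front = pp.run_optimization(Xr, endpoint, config, task="regression")
    return front, scaler


class StubMember:
    """Hand-built front member for ensemble-rule tests (no EA involved)."""

    def __init__(self, proba=None, pred=None, cv_accuracy=0.9,
                 cv_correlation=0.5, feature_indices=(0,), genes=(0.5,),
                 weighted_fitness=1.0):
        self._proba = proba
        self._pred = pred
        self.cv_accuracy = cv_accuracy
        self.cv_correlation = cv_correlation
        self.feature_indices = np.asarray(feature_indices, dtype=int)
        self.genes = tuple(genes)
        self.weighted_fitness = weighted_fitness

    def predict_proba(self, X):
        return np.full(len(X), self._proba)

    def predict(self, X):
        return np.full(len(X), self._pred)


@pytest.fixture
def stub_member():
    return StubMember
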