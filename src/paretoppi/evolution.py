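"""Multi-objective Pareto-based evolutionary model optimization.

A real-vector genome jointly encodes (a) a feature-subset mask, (b) the
estimator kind, and (c) its hyperparameters. Individuals are scored by
stratified cross-validation on the training set against a weighted set of
objectives (prediction quality, feature-count minimization, model-size
minimization); selection pressure uses the weighted scalar fitness while
the returned result is the Pareto front over every individual evaluated
during the run (archive-based), with each front member refitted on the
full training data.

Evolutionary operators follow the stated defaults: population 50,
two-point crossover probability 0.9, arithmetic crossover probability 0,
per-gene mutation probability 0.01; maximum generations 100 for
classification and 1000 for regression. Elitism copies front members into
the next generation, so the best weighted fitness is non-decreasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.impute import SimpleImputer
from sklearn.metrics import explained_variance_score, roc_auc_score
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC, SVR

from .evaluation import (
    ConfusionCounts,
    metrics_from_counts,
    regression_metrics,
    stratified_kfold,
)

CLASSIFICATION_ESTIMATORS = ("svm_rbf", "random_forest")
REGRESSION_ESTIMATORS = ("svr_linear", "svr_rbf", "rf_regressor")
NN_REGRESSOR = "nn_regressor"

#: Objective weights, in objective order (all objectives are stored
#: maximize-oriented and normalized to [0, 1] before weighting).
CLASSIFICATION_OBJECTIVES: tuple[tuple[str, float], ...] = (
    ("n_features_min", 1.0),
    ("accuracy", 10.0),
    ("f1", 10.0),
    ("f2", 1.0),
    ("precision", 1.0),
    ("recall", 1.0),
    ("auc", 1.0),
    ("model_size_min", 1.0),
    ("manhattan_min", 1.0),
)
REGRESSION_OBJECTIVES: tuple[tuple[str, float], ...] = (
    ("feature_significance", 1.0),
    ("neg_mse", 10.0),
    ("mae_min", 1.0),
    ("explained_variance", 1.0),
    ("model_complexity_min", 1.0),
    ("rmse_min", 1.0),
    ("correlation", 1.0),
)


@dataclass
class EAConfig:
    """Evolutionary-algorithm settings (defaults follow the method)."""

    population_size: int = 50
    max_generations: int = 100  # 1000 is the regression default
    p_mutation: float = 0.01
    p_two_point: float = 0.9
    p_arithmetic: float = 0.0
    n_runs: int = 3
    cv_folds: int = 10
    seed: int = 0
    c_bounds: tuple[float, float] = (2.0 ** -5, 2.0 ** 15)
    gamma_bounds: tuple[float, float] = (2.0 ** -15, 2.0 ** 3)
    trees_bounds: tuple[int, int] = (10, 500)
    enable_nn_regressor: bool = False

    def __post_init__(self):
        for p in (self.p_mutation, self.p_two_point, self.p_arithmetic):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class ModelGenome:
    """Decoded form of a real-vector genome."""

    genes: tuple[float, ...]
    feature_mask: tuple[bool, ...]
    estimator: str
    hyperparameters: dict

    @property
    def feature_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.feature_mask))


@dataclass(frozen=True)
class ObjectiveVector:
    """Maximize-oriented normalized objective values with their names."""

    names: tuple[str, ...]
    values: tuple[float, ...]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def _log_uniform(gene: float, bounds: tuple[float, float]) -> float:
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    return math.exp(lo + gene * (hi - lo))


def n_genes_for(n_features: int) -> int:
    """Feature genes + estimator selector + 3 hyperparameter genes."""
    return n_features + 4


def decode_genome(genes: np.ndarray, n_features: int, task: str,
                  config: EAConfig) -> ModelGenome:
    """Map a [0,1] real vector to (feature mask, estimator, hyperparameters).

    Feature i is selected iff its gene >= 0.5; an all-off mask is repaired
    by enabling the argmax gene. The selector gene is binned over the
    estimator list; C and gamma decode log-uniformly onto their bounds and
    the tree count affinely onto its bounds.
    """
    genes = np.asarray(genes, dtype=float)
    if genes.shape != (n_genes_for(n_features),):
        raise ValueError(
            f"expected {n_genes_for(n_features)} genes, got {genes.shape}"
        )
    mask = genes[:n_features] >= 0.5
    if not mask.any():
        mask = mask.copy()
        mask[int(np.argmax(genes[:n_features]))] = True
    if task == "classification":
        estimators = CLASSIFICATION_ESTIMATORS
    elif task == "regression":
        estimators = REGRESSION_ESTIMATORS + (
            (NN_REGRESSOR,) if config.enable_nn_regressor else ()
        )
    else:
        raise ValueError(f"unknown task {task!r}")
    sel = min(int(genes[n_features] * len(estimators)), len(estimators) - 1)
    estimator = estimators[sel]
    g_c, g_gamma, g_trees = genes[n_features + 1:n_features + 4]
    lo_t, hi_t = config.trees_bounds
    hyper = {
        "C": _log_uniform(g_c, config.c_bounds),
        "gamma": _log_uniform(g_gamma, config.gamma_bounds),
        "n_trees": int(round(lo_t + g_trees * (hi_t - lo_t))),
    }
    return ModelGenome(
        genes=tuple(genes), feature_mask=tuple(bool(b) for b in mask),
        estimator=estimator, hyperparameters=hyper,
    )


def dominates(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    """Standard Pareto dominance on maximize-oriented vectors."""
    if a.names != b.names:
        raise ValueError("objective sets differ")
    av, bv = a.as_array(), b.as_array()
    return bool(np.all(av >= bv) and np.any(av > bv))


def pareto_front(objectives: list[ObjectiveVector]) -> list[int]:
    """Indices of the non-dominated subset (ties kept)."""
    if not objectives:
        raise ValueError("empty population")
    vals = np.asarray([o.as_array() for o in objectives])
    n = len(objectives)
    keep = []
    for i in range(n):
        ge = np.all(vals >= vals[i], axis=1)
        gt = np.any(vals > vals[i], axis=1)
        if not np.any(ge & gt):
            keep.append(i)
    return keep


def weighted_fitness(objectives: ObjectiveVector, weights: dict[str, float]) -> float:
    """Weighted sum of normalized maximize-oriented objectives."""
    total = 0.0
    for name, value in zip(objectives.names, objectives.values):
        w = weights[name]
        if w < 0:
            raise ValueError(f"negative weight for objective {name!r}")
        total += w * value
    return total


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------


def two_point_crossover(parent1: np.ndarray, parent2: np.ndarray,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Children exchange the segment between two cut points."""
    if parent1.shape != parent2.shape:
        raise ValueError("parents must have equal gene length")
    n = parent1.size
    i, j = sorted(rng.integers(0, n + 1, size=2))
    c1, c2 = parent1.copy(), parent2.copy()
    c1[i:j], c2[i:j] = parent2[i:j], parent1[i:j]
    return c1, c2


def arithmetic_crossover(parent1: np.ndarray, parent2: np.ndarray,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Children are complementary convex combinations of the parents."""
    if parent1.shape != parent2.shape:
        raise ValueError("parents must have equal gene length")
    alpha = rng.random()
    return (alpha * parent1 + (1 - alpha) * parent2,
            alpha * parent2 + (1 - alpha) * parent1)


def mutate(genes: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Each gene independently resampled uniformly on [0,1) with prob p."""
    out = genes.copy()
    hit = rng.random(genes.size) < p
    if hit.any():
        out[hit] = rng.random(int(hit.sum()))
    return out


# ---------------------------------------------------------------------------
# Individual evaluation
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _build_estimator(genome: ModelGenome, seed: int):
    h = genome.hyperparameters
    kind = genome.estimator
    if kind == "svm_rbf":
        return SVC(C=h["C"], gamma=h["gamma"], kernel="rbf")
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=h["n_trees"],
                                      random_state=seed, n_jobs=1)
    if kind == "svr_linear":
        return SVR(kernel="linear", C=h["C"])
    if kind == "svr_rbf":
        return SVR(kernel="rbf", C=h["C"], gamma=h["gamma"])
    if kind == "rf_regressor":
        return RandomForestRegressor(n_estimators=h["n_trees"],
                                     random_state=seed, n_jobs=1)
    if kind == NN_REGRESSOR:
        return MLPRegressor(hidden_layer_sizes=(32,), max_iter=500,
                            random_state=seed)
    raise ValueError(f"unknown estimator {kind!r}")


def _make_pipeline(genome: ModelGenome, seed: int) -> Pipeline:
    # Imputation and scaling are fitted fold-internally (or on the full
    # training set at refit time), never on data the model will predict.
    return Pipeline([
        ("impute", SimpleImputer(strategy="mean", keep_empty_features=True)),
        ("scale", MinMaxScaler(clip=True)),
        ("estimator", _build_estimator(genome, seed)),
    ])


def _positive_probability(pipe: Pipeline, X: np.ndarray) -> np.ndarray:
    est = pipe.named_steps["estimator"]
    Xt = pipe[:-1].transform(X)
    if hasattr(est, "predict_proba"):
        classes = list(est.classes_)
        return est.predict_proba(Xt)[:, classes.index(1)]
    # SVM: logistic squashing of the signed margin.
    return _sigmoid(est.decision_function(Xt))


def _model_size(pipe: Pipeline) -> float:
    est = pipe.named_steps["estimator"]
    if hasattr(est, "n_support_"):  # SVC
        return float(np.sum(est.n_support_))
    if hasattr(est, "support_"):  # SVR
        return float(len(est.support_))
    if hasattr(est, "n_estimators"):
        return float(est.n_estimators)
    return 0.0


def _size_ceiling(genome: ModelGenome, n_train: int, config: EAConfig) -> float:
    if genome.estimator in ("random_forest", "rf_regressor"):
        return float(config.trees_bounds[1])
    return float(n_train)


def _clip01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def evaluate_individual(
    genome: ModelGenome,
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int,
    seed: int,
    task: str = "classification",
    config: EAConfig | None = None,
) -> tuple[ObjectiveVector, dict]:
    """Cross-validated objective vector and raw CV metrics for one genome.

    Per fold the pipeline (mean imputation -> [0,1] scaling -> estimator)
    is fitted on the training part only, restricted to the genome's
    selected features. Objective values are means over folds, normalized
    to maximize-oriented [0, 1].
    """
    config = config or EAConfig(cv_folds=cv_folds, seed=seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    sel = genome.feature_indices
    Xs = X[:, sel]
    n_feat_total = len(genome.feature_mask)
    feature_frac = 1.0 - len(sel) / n_feat_total

    if task == "classification":
        folds = stratified_kfold(y, cv_folds, seed)
    else:
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = [test for _, test in kf.split(Xs)]

    all_idx = np.arange(len(y))
    per_fold: list[dict] = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        if task == "classification" and len(np.unique(y[train_idx])) < 2:
            raise ValueError(f"degenerate fold {f}: single class in training part")
        pipe = _make_pipeline(genome, seed)
        pipe.fit(Xs[train_idx], y[train_idx])
        size_ratio = _model_size(pipe) / _size_ceiling(genome, len(train_idx), config)
        if task == "classification":
            prob = _positive_probability(pipe, Xs[test_idx])
            pred = (prob >= 0.5).astype(int)
            yt = y[test_idx].astype(int)
            cm = metrics_from_counts(ConfusionCounts(
                tp=float(np.sum((pred == 1) & (yt == 1))),
                fp=float(np.sum((pred == 1) & (yt == 0))),
                tn=float(np.sum((pred == 0) & (yt == 0))),
                fn=float(np.sum((pred == 0) & (yt == 1))),
            ))
            auc = roc_auc_score(yt, prob) if len(np.unique(yt)) == 2 else None
            per_fold.append({
                "accuracy": cm.accuracy, "specificity": cm.specificity,
                "sensitivity": cm.sensitivity, "precision": cm.precision,
                "f1": cm.f1, "f2": cm.f2, "auc": auc,
                "manhattan": float(np.mean(np.abs(prob - yt))),
                "size_ratio": _clip01(size_ratio),
            })
        else:
            pred = pipe.predict(Xs[test_idx])
            yt = y[test_idx].astype(float)
            rm = regression_metrics(yt, pred)
            per_fold.append({
                "mse": float(np.mean((yt - pred) ** 2)),
                "mae": float(np.mean(np.abs(yt - pred))),
                "explained_variance": float(explained_variance_score(yt, pred)),
                "rmse": rm.rmse, "rae": rm.rae, "rrse": rm.rrse,
                "spearman_rho": rm.spearman_rho, "spearman_p": rm.spearman_p,
                "size_ratio": _clip01(size_ratio),
            })

    def mean_of(key: str, default: float | None = None) -> float | None:
        vals = [f[key] for f in per_fold if f[key] is not None]
        return float(np.mean(vals)) if vals else default

    if task == "classification":
        metrics = {f"cv_{k}": mean_of(k) for k in
                   ("accuracy", "specificity", "sensitivity", "precision",
                    "f1", "f2", "auc", "manhattan")}
        metrics["cv_model_size_ratio"] = mean_of("size_ratio")
        metrics["n_selected_features"] = int(len(sel))
        obj = ObjectiveVector(
            names=tuple(n for n, _ in CLASSIFICATION_OBJECTIVES),
            values=(
                feature_frac,
                mean_of("accuracy", 0.0),
                mean_of("f1", 0.0) or 0.0,
                mean_of("f2", 0.0) or 0.0,
                mean_of("precision", 0.0) or 0.0,
                mean_of("sensitivity", 0.0) or 0.0,
                mean_of("auc", 0.0) or 0.0,
                1.0 - mean_of("size_ratio", 1.0),
                1.0 - mean_of("manhattan", 1.0),
            ),
        )
    else:
        metrics = {f"cv_{k}": mean_of(k) for k in
                   ("mse", "mae", "explained_variance", "rmse", "rae",
                    "rrse", "spearman_rho", "spearman_p")}
        metrics["cv_model_size_ratio"] = mean_of("size_ratio")
        metrics["n_selected_features"] = int(len(sel))
        rho = mean_of("spearman_rho")
        obj = ObjectiveVector(
            names=tuple(n for n, _ in REGRESSION_OBJECTIVES),
            values=(
                feature_frac,
                _clip01(1.0 - mean_of("mse", 1.0)),
                _clip01(1.0 - mean_of("mae", 1.0)),
                _clip01(mean_of("explained_variance", 0.0)),
                1.0 - mean_of("size_ratio", 1.0),
                _clip01(1.0 - mean_of("rmse", 1.0)),
                _clip01(((rho if rho is not None else 0.0) + 1.0) / 2.0),
            ),
        )
    return obj, metrics


# ---------------------------------------------------------------------------
# Front members and the optimization loop
# ---------------------------------------------------------------------------


@dataclass
class FrontMember:
    """A non-dominated model refitted on the full training data."""

    genome: ModelGenome
    objectives: ObjectiveVector
    metrics: dict
    weighted_fitness: float
    model: Pipeline
    task: str

    @property
    def genes(self) -> tuple[float, ...]:
        return self.genome.genes

    @property
    def feature_indices(self) -> np.ndarray:
        return self.genome.feature_indices

    @property
    def cv_accuracy(self) -> float | None:
        return self.metrics.get("cv_accuracy")

    @property
    def cv_correlation(self) -> float | None:
        return self.metrics.get("cv_spearman_rho")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability on full-width feature matrices."""
        Xs = np.asarray(X, dtype=float)[:, self.feature_indices]
        return _positive_probability(self.model, Xs)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Prediction on the [0,1] endpoint scale (regression members)."""
        Xs = np.asarray(X, dtype=float)[:, self.feature_indices]
        return np.clip(self.model.predict(Xs), 0.0, 1.0)

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


@dataclass
class ParetoFront:
    members: list[FrontMember]
    task: str
    config: EAConfig
    history: list[dict] = field(default_factory=list)  # per-generation log

    def best(self) -> FrontMember:
        from .evaluation import select_best_model

        return select_best_model(self.members)

    def manifest(self) -> list[dict]:
        """JSON-serializable description of every front member."""
        out = []
        for m in self.members:
            out.append({
                "estimator": m.genome.estimator,
                "hyperparameters": {
                    k: (round(v, 6) if isinstance(v, float) else v)
                    for k, v in m.genome.hyperparameters.items()
                },
                "n_selected_features": int(len(m.feature_indices)),
                "selected_feature_indices": [int(i) for i in m.feature_indices],
                "weighted_fitness": m.weighted_fitness,
                "metrics": {k: v for k, v in m.metrics.items()},
            })
        return out


def objective_weights(task: str) -> dict[str, float]:
    table = CLASSIFICATION_OBJECTIVES if task == "classification" else REGRESSION_OBJECTIVES
    return dict(table)


def run_optimization(
    X: np.ndarray,
    y: np.ndarray,
    config: EAConfig,
    task: str = "classification",
    weights: dict[str, float] | None = None,
) -> ParetoFront:
    """Evolve feature subsets, estimator choice and hyperparameters.

    Returns the archive-based Pareto front (non-dominated set over all
    individuals evaluated during the run), with members refitted on the
    full training data. Reproducible under ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(y) < config.cv_folds:
        raise ValueError("dataset smaller than cv_folds")
    n_features = X.shape[1]
    n_genes = n_genes_for(n_features)
    weights = weights or objective_weights(task)
    rng = np.random.default_rng(config.seed)
    eval_seed = int(config.seed) % (2 ** 31 - 1)

    cache: dict[bytes, tuple[ObjectiveVector, dict, float]] = {}
    archive: dict[bytes, tuple[np.ndarray, ObjectiveVector, dict, float]] = {}

    def evaluate(genes: np.ndarray) -> float:
        key = genes.tobytes()
        if key not in cache:
            genome = decode_genome(genes, n_features, task, config)
            obj, metrics = evaluate_individual(
                genome, X, y, config.cv_folds, eval_seed, task, config
            )
            fit = weighted_fitness(obj, weights)
            cache[key] = (obj, metrics, fit)
            archive[key] = (genes.copy(), obj, metrics, fit)
        return cache[key][2]

    population = rng.random((config.population_size, n_genes))
    fitnesses = np.array([evaluate(g) for g in population])
    history = [{"generation": 0, "best_fitness": float(max(f for *_, f in archive.values()))}]

    def tournament() -> np.ndarray:
        i, j = rng.integers(0, len(population), size=2)
        return population[i] if fitnesses[i] >= fitnesses[j] else population[j]

    for gen in range(1, config.max_generations + 1):
        # Elitism: current archive front re-enters the next generation.
        arch = list(archive.values())
        front_idx = pareto_front([a[1] for a in arch])
        elite_sorted = sorted(front_idx, key=lambda i: -arch[i][3])
        elites = [arch[i][0] for i in elite_sorted[: config.population_size // 2]]
        children: list[np.ndarray] = list(elites)
        while len(children) < config.population_size:
            p1, p2 = tournament(), tournament()
            r = rng.random()
            if r < config.p_two_point:
                c1, c2 = two_point_crossover(p1, p2, rng)
            elif r < config.p_two_point + config.p_arithmetic:
                c1, c2 = arithmetic_crossover(p1, p2, rng)
            else:
                c1, c2 = p1.copy(), p2.copy()
            children.append(mutate(c1, config.p_mutation, rng))
            if len(children) < config.population_size:
                children.append(mutate(c2, config.p_mutation, rng))
        population = np.asarray(children)
        fitnesses = np.array([evaluate(g) for g in population])
        history.append({
            "generation": gen,
            "best_fitness": float(max(f for *_, f in archive.values())),
        })

    arch = list(archive.values())
    front_idx = pareto_front([a[1] for a in arch])
    members = []
    for i in front_idx:
        genes, obj, metrics, fit = arch[i]
        genome = decode_genome(genes, n_features, task, config)
        pipe = _make_pipeline(genome, eval_seed)
        pipe.fit(X[:, genome.feature_indices], y)
        members.append(FrontMember(genome=genome, objectives=obj, metrics=metrics,
                                   weighted_fitness=fit, model=pipe, task=task))
    return ParetoFront(members=members, task=task, config=config, history=history)
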