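"""Subject-dependent leave-one-out classification and cohort aggregation.

Each subject gets their own model: every trial is predicted by a
classifier trained on that subject's remaining trials (LOOCV), and the
cohort-level figure is the unweighted mean of the per-subject accuracies.

Two classifiers are provided. kNN (k = 5, Euclidean) with fully
deterministic tie handling: distance ties are broken by lower training
index and vote ties by the label of the single nearest neighbor among the
tied classes. RBF-kernel SVM with per-fold hyperparameter search for
(C, gamma) over log2 ranges, either on a deterministic grid or by a
Gaussian-process expected-improvement (Bayesian) search; the search
objective is inner stratified k-fold accuracy on the training fold only,
with ties resolved toward smaller C then smaller gamma (the smoother
model).

Leakage discipline: the feature scaler and any hyperparameter search are
fit on the n-1 training trials of each fold only — the held-out trial can
never influence them. Every random choice derives from ``tuner_seed`` and
the fold index, so runs are bit-reproducible and a fold's tuning is
unchanged when an unrelated held-out trial is perturbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateTaskError


@dataclass(frozen=True)
class ClassifierConfig:
    """Configuration of the per-subject classifier."""

    kind: str = "knn"  # "knn" | "svm_rbf"
    k: int = 5
    distance: str = "euclidean"
    cost_log2_range: tuple[float, float] = (-5.0, 15.0)
    gamma_log2_range: tuple[float, float] = (-15.0, 3.0)
    tuner: str = "bayesian"  # "bayesian" | "grid"
    tuner_iters: int = 30
    tuner_seed: int = 0
    inner_folds: int = 5
    standardize: bool = True
    log_transform_power_features: bool = False

    def __post_init__(self) -> None:
        if self.kind not in {"knn", "svm_rbf"}:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.distance != "euclidean":
            raise ValueError("only the Euclidean distance is supported")
        if self.tuner not in {"bayesian", "grid"}:
            raise ValueError(f"unknown tuner {self.tuner!r}")
        if self.tuner_iters < 1:
            raise ValueError("tuner_iters must be >= 1")
        for lo, hi in (self.cost_log2_range, self.gamma_log2_range):
            if not lo < hi:
                raise ValueError("hyperparameter ranges must be nonempty")


@dataclass
class SubjectEval:
    """LOOCV outcome for one subject."""

    subject_id: str
    predictions: list[str]
    labels: list[str]
    accuracy: float  # percent
    fold_details: list[dict] = field(default_factory=list)


@dataclass
class EvalResult:
    """Cohort-level evaluation: per-subject folds plus the aggregate."""

    per_subject: dict[str, SubjectEval]
    mean_accuracy: float  # percent, unweighted over subjects
    config: ClassifierConfig
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "seed": self.seed,
            "per_subject": [
                {
                    "id": ev.subject_id,
                    "accuracy": ev.accuracy,
                    "predictions": list(ev.predictions),
                }
                for ev in self.per_subject.values()
            ],
            "mean_accuracy": self.mean_accuracy,
        }


# ---------------------------------------------------------------------------
# kNN


def knn_predict(
    train_X: np.ndarray,
    train_y: Sequence[str],
    query: np.ndarray,
    k: int = 5,
) -> str:
    """Majority label among the k Euclidean-nearest training rows.

    Distance ties are broken by lower training index (stable sort); vote
    ties by the label of the nearest neighbor belonging to a tied class.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    train_y = list(train_y)
    if k > train_X.shape[0]:
        raise ValueError(f"k={k} exceeds {train_X.shape[0]} training rows")
    query = np.asarray(query, dtype=float).ravel()
    dists = np.sqrt(np.sum((train_X - query) ** 2, axis=1))
    order = np.argsort(dists, kind="stable")
    neighbors = order[:k]
    votes: dict[str, int] = {}
    for idx in neighbors:
        votes[train_y[idx]] = votes.get(train_y[idx], 0) + 1
    top = max(votes.values())
    tied = {label for label, count in votes.items() if count == top}
    if len(tied) == 1:
        return tied.pop()
    for idx in neighbors:  # nearest neighbor among tied classes decides
        if train_y[idx] in tied:
            return train_y[idx]
    raise AssertionError("unreachable: tied classes must appear in neighbors")


# ---------------------------------------------------------------------------
# SVM hyperparameter search


def _grid_candidates(config: ClassifierConfig) -> np.ndarray:
    """A near-square log2 grid of (C, gamma) with ~tuner_iters points."""
    n_c = max(1, int(np.ceil(np.sqrt(config.tuner_iters))))
    n_g = max(1, int(np.ceil(config.tuner_iters / n_c)))
    cs = np.linspace(*config.cost_log2_range, n_c)
    gs = np.linspace(*config.gamma_log2_range, n_g)
    return np.array([(c, g) for c in cs for g in gs])


def _bayes_search(
    objective,
    config: ClassifierConfig,
    rng: np.random.Generator,
) -> tuple[tuple[float, float], float]:
    """Gaussian-process expected-improvement search over (log2 C, log2 g).

    A compact Bayesian optimizer: seed the surrogate with quasi-random
    evaluations, then repeatedly fit a Matern GP to the observed scores
    and evaluate the candidate with the highest expected improvement from
    a random pool. Deterministic given ``rng``.
    """
    from scipy.stats import norm
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern

    (c_lo, c_hi), (g_lo, g_hi) = config.cost_log2_range, config.gamma_log2_range
    span = np.array([c_hi - c_lo, g_hi - g_lo])
    lo = np.array([c_lo, g_lo])

    n_init = min(config.tuner_iters, 8)
    X = lo + rng.random((n_init, 2)) * span
    scores = [objective(tuple(x)) for x in X]

    for _ in range(config.tuner_iters - n_init):
        gp = GaussianProcessRegressor(
            # Fixed length scale: the surrogate needs to rank candidates,
            # not model the response surface; skipping marginal-likelihood
            # optimization keeps the search fast and deterministic.
            kernel=Matern(length_scale=span / 4.0, nu=2.5),
            optimizer=None,
            alpha=1e-4,
            normalize_y=True,
        )
        gp.fit(X, np.asarray(scores))
        pool = lo + rng.random((256, 2)) * span
        mu, sigma = gp.predict(pool, return_std=True)
        best = max(scores)
        sigma = np.maximum(sigma, 1e-12)
        improve = mu - best - 1e-4
        ei = improve * norm.cdf(improve / sigma) + sigma * norm.pdf(improve / sigma)
        x_next = pool[int(np.argmax(ei))]
        X = np.vstack([X, x_next])
        scores.append(objective(tuple(x_next)))

    # Ties toward smaller C then smaller gamma.
    order = sorted(
        range(len(scores)), key=lambda i: (-scores[i], X[i, 0], X[i, 1])
    )
    best_i = order[0]
    return (float(X[best_i, 0]), float(X[best_i, 1])), float(scores[best_i])


def _tune_svm(
    X: np.ndarray,
    y: np.ndarray,
    config: ClassifierConfig,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Pick (C, gamma) by inner stratified k-fold accuracy on (X, y)."""
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.svm import SVC

    classes, counts = np.unique(y, return_counts=True)
    n_splits = int(min(config.inner_folds, counts.min()))
    if n_splits < 2:
        # Too few per-class examples for inner CV; fall back to mid-range.
        return (
            2.0 ** np.mean(config.cost_log2_range),
            2.0 ** np.mean(config.gamma_log2_range),
        )
    cv = StratifiedKFold(
        n_splits=n_splits,
        shuffle=True,
        random_state=int(rng.integers(2**31 - 1)),
    )
    splits = list(cv.split(X, y))

    def objective(log2_params: tuple[float, float]) -> float:
        c, g = 2.0 ** log2_params[0], 2.0 ** log2_params[1]
        correct = 0
        for train_idx, test_idx in splits:
            clf = SVC(C=c, gamma=g, kernel="rbf")
            clf.fit(X[train_idx], y[train_idx])
            correct += int(np.sum(clf.predict(X[test_idx]) == y[test_idx]))
        return correct / len(y)

    if config.tuner == "grid":
        candidates = _grid_candidates(config)
        scored = [(objective(tuple(x)), x) for x in candidates]
        scored.sort(key=lambda item: (-item[0], item[1][0], item[1][1]))
        best = scored[0][1]
    else:
        best, _ = _bayes_search(objective, config, rng)
    return 2.0 ** best[0], 2.0 ** best[1]


# ---------------------------------------------------------------------------
# LOOCV


def _prepare_matrix(features, config: ClassifierConfig) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=float)
        power_cols = [
            j
            for j, name in enumerate(features.columns)
            if name.endswith(("_activity", "_psd"))
        ]
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        power_cols = list(range(X.shape[1]))
    if config.log_transform_power_features:
        X = X.copy()
        for j in power_cols:
            X[:, j] = np.log10(np.maximum(X[:, j], 1e-30))
    return X


def loocv_evaluate(
    features,
    labels: Sequence[str],
    config: ClassifierConfig | None = None,
    subject_id: str = "",
) -> SubjectEval:
    """Leave-one-out evaluation of one subject's feature table.

    ``features`` is an ``[n_trials x n_features]`` array or DataFrame
    (feature columns only). For each fold, the scaler — and for SVM the
    (C, gamma) search — is fit on the training trials alone, then the
    held-out trial is predicted. Accuracy is the percentage of correct
    folds. ``fold_details`` records per-fold scaler statistics and chosen
    hyperparameters so leakage can be audited.
    """
    config = config or ClassifierConfig()
    X = _prepare_matrix(features, config)
    y = np.asarray(list(labels), dtype=object)
    n = X.shape[0]
    if n < 2:
        raise ValueError("LOOCV needs at least 2 trials")
    if y.shape[0] != n:
        raise ValueError(f"{y.shape[0]} labels for {n} trials")
    if np.unique(y).size < 2:
        raise DegenerateTaskError(
            "all trials share one label; nothing to classify"
        )
    if config.kind == "knn" and config.k > n - 1:
        raise ValueError(f"k={config.k} exceeds training size {n - 1}")

    predictions: list[str] = []
    fold_details: list[dict] = []
    for i in range(n):
        train_mask = np.ones(n, dtype=bool)
        train_mask[i] = False
        X_train, y_train = X[train_mask], y[train_mask]
        if config.standardize:
            mean = X_train.mean(axis=0)
            scale = X_train.std(axis=0)
            scale[scale == 0] = 1.0
        else:
            mean = np.zeros(X.shape[1])
            scale = np.ones(X.shape[1])
        Z_train = (X_train - mean) / scale
        z_query = (X[i] - mean) / scale
        detail: dict = {"scaler_mean": mean.copy(), "scaler_scale": scale.copy()}

        if config.kind == "knn":
            pred = knn_predict(Z_train, y_train, z_query, k=config.k)
        else:
            rng = np.random.default_rng([max(config.tuner_seed, 0), i])
            c, g = _tune_svm(Z_train, y_train, config, rng)
            from sklearn.svm import SVC

            clf = SVC(C=c, gamma=g, kernel="rbf")
            clf.fit(Z_train, y_train)
            pred = str(clf.predict(z_query[np.newaxis, :])[0])
            detail["hyperparameters"] = {"C": c, "gamma": g}
        predictions.append(pred)
        fold_details.append(detail)

    accuracy = 100.0 * float(np.mean(np.asarray(predictions) == y))
    return SubjectEval(
        subject_id=subject_id,
        predictions=predictions,
        labels=list(y),
        accuracy=accuracy,
        fold_details=fold_details,
    )


def aggregate_cohort(per_subject_accuracies: Sequence[float]) -> float:
    """Unweighted mean of per-subject accuracies (%), reported to two
    decimals with conventional half-up rounding."""
    values = list(per_subject_accuracies)
    if not values:
        raise ValueError("cannot aggregate an empty accuracy list")
    mean = float(np.mean(values))
    return float(Decimal(repr(mean)).quantize(Decimal("0.01"), ROUND_HALF_UP))
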