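"""TCRnodseek: an SVM nodule classifier tuned by a genetic algorithm.

The model standardises the selected features, fits a support-vector machine
whose hyperparameters (kernel, C and RBF width) are chosen by a seeded
genetic algorithm maximising mean cross-validated AUC, maps decision scores
to a bounded predicted value through a sigmoid (Platt-style) calibration fit
on the training scores, and fixes the operating point at the Youden cutoff
of the training predicted values.

The estimator follows the scikit-learn contract (``fit`` / ``predict`` /
``predict_proba`` / ``get_params``) and therefore composes with pipelines
and model selection.  The full train → predict path is deterministic under
``random_state``: two fits with identical inputs serialise byte-identically.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigError, ValidationError
from .features import LABEL_COLUMN, TCR_FEATURES, split_features_labels
from .metrics import auc_from_scores, youden_cutoff

POSITIVE_LABEL = "malignant"


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm search settings for the SVM hyperparameters."""

    population_size: int = 30
    generations: int = 40
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    elitism: int = 2
    cv_folds: int = 5
    log10_c_bounds: tuple[float, float] = (-2.0, 3.0)
    log10_gamma_bounds: tuple[float, float] = (-3.0, 1.0)
    kernels: tuple[str, ...] = ("rbf", "linear")
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 1 or self.generations < 1:
            raise ConfigError("population_size and generations must be >= 1")
        if not (1 <= self.elitism <= self.population_size):
            raise ConfigError("need 1 <= elitism <= population_size")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name in ("log10_c_bounds", "log10_gamma_bounds"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigError(f"{name} must be finite and ordered")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        bad = set(self.kernels) - {"rbf", "linear"}
        if not self.kernels or bad:
            raise ConfigError(f"unsupported kernel(s): {sorted(bad)}")


class TCRNodSeekClassifier(ClassifierMixin, BaseEstimator):
    """GA-optimised SVM labelling lung nodules benign vs malignant.

    Parameters mirror :class:`GAConfig` (flattened for the scikit-learn
    parameter API) plus ``features``, the ordered feature subset to use when
    ``X`` is a DataFrame (``None`` uses all columns).

    Fitted attributes
    -----------------
    classes_ : the two class labels, sorted.
    best_params_ : dict with the GA-chosen kernel, C and gamma.
    best_fitness_ : mean CV AUC of the chosen hyperparameters.
    trajectory_ : best fitness per generation (non-decreasing by elitism).
    youden_cutoff_ : operating threshold on the predicted value.
    """

    def __init__(
        self,
        features=None,
        population_size: int = 30,
        generations: int = 40,
        crossover_rate: float = 0.8,
        mutation_rate: float = 0.1,
        elitism: int = 2,
        cv_folds: int = 5,
        log10_c_bounds: tuple[float, float] = (-2.0, 3.0),
        log10_gamma_bounds: tuple[float, float] = (-3.0, 1.0),
        kernels: tuple[str, ...] = ("rbf", "linear"),
        random_state: int = 0,
    ):
        self.features = features
        self.population_size = population_size
        self.generations = generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.elitism = elitism
        self.cv_folds = cv_folds
        self.log10_c_bounds = log10_c_bounds
        self.log10_gamma_bounds = log10_gamma_bounds
        self.kernels = kernels
        self.random_state = random_state

    @classmethod
    def from_ga_config(cls, ga: GAConfig, features=None) -> "TCRNodSeekClassifier":
        ga.validate()
        return cls(
            features=features,
            population_size=ga.population_size,
            generations=ga.generations,
            crossover_rate=ga.crossover_rate,
            mutation_rate=ga.mutation_rate,
            elitism=ga.elitism,
            cv_folds=ga.cv_folds,
            log10_c_bounds=ga.log10_c_bounds,
            log10_gamma_bounds=ga.log10_gamma_bounds,
            kernels=ga.kernels,
            random_state=ga.seed,
        )

    # ------------------------------------------------------------------ fit

    def _matrix(self, X, require_fitted_columns: bool = False) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            cols = (
                list(self.selected_features_)
                if require_fitted_columns
                else (list(self.features) if self.features is not None else list(X.columns))
            )
            if LABEL_COLUMN in cols:
                cols.remove(LABEL_COLUMN)
            missing = [c for c in cols if c not in X.columns]
            if missing:
                raise ValidationError(f"missing feature column(s): {missing}")
            return X[cols].to_numpy(dtype=float), cols
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("X must be a 2-D array or DataFrame")
        if require_fitted_columns and arr.shape[1] != len(self.selected_features_):
            raise ValidationError(
                f"expected {len(self.selected_features_)} feature columns, "
                f"got {arr.shape[1]}"
            )
        return arr, [f"x{i}" for i in range(arr.shape[1])]

    def fit(self, X, y):
        ga = GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            elitism=self.elitism,
            cv_folds=self.cv_folds,
            log10_c_bounds=tuple(self.log10_c_bounds),
            log10_gamma_bounds=tuple(self.log10_gamma_bounds),
            kernels=tuple(self.kernels),
            seed=self.random_state if self.random_state is not None else 0,
        )
        ga.validate()
        mat, cols = self._matrix(X)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValidationError(f"need exactly 2 classes, got {list(classes)}")
        if counts.min() < ga.cv_folds:
            raise ValidationError(
                f"smallest class has {counts.min()} subjects, fewer than "
                f"cv_folds={ga.cv_folds}; reduce the number of folds"
            )
        self.classes_ = classes
        positive = POSITIVE_LABEL if POSITIVE_LABEL in classes else classes[1]
        self.positive_label_ = positive
        y01 = (y == positive).astype(int)
        self.selected_features_ = cols
        self.n_features_in_ = mat.shape[1]

        self.scaler_ = StandardScaler().fit(mat)
        xs = self.scaler_.transform(mat)

        best, trajectory = self._ga_search(xs, y01, ga)
        self.best_params_ = {
            "kernel": ga.kernels[int(best[0])],
            "C": float(10.0 ** best[1]),
            "gamma": float(10.0 ** best[2]),
        }
        self.best_fitness_ = trajectory[-1]
        self.trajectory_ = trajectory

        self.svm_ = self._make_svm(self.best_params_).fit(xs, y01)
        scores = self.svm_.decision_function(xs)
        # unpenalised logistic fit of class on decision score (Platt scaling)
        self.calibrator_ = LogisticRegression(
            C=np.inf, solver="lbfgs", max_iter=1000
        ).fit(scores.reshape(-1, 1), y01)
        values = self.calibrator_.predict_proba(scores.reshape(-1, 1))[:, 1]
        self.youden_cutoff_, self.youden_j_ = youden_cutoff(values, y01, positive=1)
        self.training_values_ = values
        return self

    @staticmethod
    def _make_svm(params: dict) -> SVC:
        return SVC(
            kernel=params["kernel"],
            C=params["C"],
            gamma=params["gamma"] if params["kernel"] == "rbf" else "scale",
        )

    def _ga_search(self, xs, y01, ga: GAConfig):
        """Tournament-selection GA over (kernel, log10 C, log10 gamma)."""
        rng = np.random.default_rng(ga.seed)
        splitter = StratifiedKFold(
            n_splits=ga.cv_folds, shuffle=True, random_state=ga.seed % (2 ** 31)
        )
        folds = list(splitter.split(xs, y01))  # identical folds for every genome
        c_lo, c_hi = ga.log10_c_bounds
        g_lo, g_hi = ga.log10_gamma_bounds
        cache: dict[tuple, float] = {}

        def fitness(genome) -> float:
            key = (int(genome[0]), round(genome[1], 6), round(genome[2], 6))
            if key not in cache:
                params = {
                    "kernel": ga.kernels[int(genome[0])],
                    "C": 10.0 ** genome[1],
                    "gamma": 10.0 ** genome[2],
                }
                aucs = []
                for train_idx, test_idx in folds:
                    svm = self._make_svm(params).fit(xs[train_idx], y01[train_idx])
                    scores = svm.decision_function(xs[test_idx])
                    aucs.append(auc_from_scores(scores, y01[test_idx], positive=1))
                cache[key] = float(np.mean(aucs))
            return cache[key]

        def random_genome():
            return np.array(
                [
                    rng.integers(0, len(ga.kernels)),
                    rng.uniform(c_lo, c_hi),
                    rng.uniform(g_lo, g_hi),
                ]
            )

        pop = [random_genome() for _ in range(ga.population_size)]
        fits = np.array([fitness(g) for g in pop])
        trajectory = [float(fits.max())]

        for _ in range(ga.generations):
            order = np.argsort(-fits, kind="stable")
            elites = [pop[i].copy() for i in order[: ga.elitism]]
            children = []
            while len(children) < ga.population_size - ga.elitism:
                parents = []
                for _ in range(2):  # tournament of 3
                    idx = rng.integers(0, ga.population_size, size=3)
                    parents.append(pop[idx[np.argmax(fits[idx])]])
                child = parents[0].copy()
                if rng.random() < ga.crossover_rate:  # uniform crossover
                    take = rng.random(3) < 0.5
                    child[take] = parents[1][take]
                if rng.random() < ga.mutation_rate:
                    child[0] = rng.integers(0, len(ga.kernels))
                if rng.random() < ga.mutation_rate:
                    child[1] = np.clip(
                        child[1] + rng.normal(0, 0.1 * (c_hi - c_lo)), c_lo, c_hi
                    )
                if rng.random() < ga.mutation_rate:
                    child[2] = np.clip(
                        child[2] + rng.normal(0, 0.1 * (g_hi - g_lo)), g_lo, g_hi
                    )
                children.append(child)
            pop = elites + children
            fits = np.array([fitness(g) for g in pop])
            trajectory.append(float(fits.max()))

        best = pop[int(np.argmax(fits))]
        return best, trajectory

    # -------------------------------------------------------------- predict

    def predict_value(self, X) -> np.ndarray:
        """Calibrated predicted value in [0, 1] (malignancy score)."""
        check_is_fitted(self, "svm_")
        mat, _ = self._matrix(X, require_fitted_columns=True)
        xs = self.scaler_.transform(mat)
        scores = self.svm_.decision_function(xs)
        return self.calibrator_.predict_proba(scores.reshape(-1, 1))[:, 1]

    def decision_function(self, X) -> np.ndarray:
        """Raw (uncalibrated) SVM decision scores."""
        check_is_fitted(self, "svm_")
        mat, _ = self._matrix(X, require_fitted_columns=True)
        return self.svm_.decision_function(self.scaler_.transform(mat))

    def predict_proba(self, X) -> np.ndarray:
        v = self.predict_value(X)
        out = np.column_stack([1 - v, v])
        if self.classes_[0] == self.positive_label_:
            out = out[:, ::-1]
        return out

    def predict(self, X) -> np.ndarray:
        """Class labels at the Youden cutoff (value >= cutoff → malignant)."""
        v = self.predict_value(X)
        negative = next(c for c in self.classes_ if c != self.positive_label_)
        return np.where(v >= self.youden_cutoff_, self.positive_label_, negative)

    # ---------------------------------------------------------- persistence

    def to_json_dict(self) -> dict:
        check_is_fitted(self, "svm_")
        return {
            "schema_version": 1,
            "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.get_params().items()
            },
            "classes": [str(c) for c in self.classes_],
            "positive_label": str(self.positive_label_),
            "selected_features": list(self.selected_features_),
            "standardization": {
                "mean": self.scaler_.mean_.tolist(),
                "scale": self.scaler_.scale_.tolist(),
            },
            "hyperparameters": self.best_params_,
            "svm": {
                "support_vectors": self.svm_.support_vectors_.tolist(),
                "dual_coef": self.svm_.dual_coef_.tolist(),
                "intercept": self.svm_.intercept_.tolist(),
                "gamma": float(self.svm_._gamma),
            },
            "calibration": {
                "coef": float(self.calibrator_.coef_[0, 0]),
                "intercept": float(self.calibrator_.intercept_[0]),
            },
            "youden_cutoff": float(self.youden_cutoff_),
            "youden_j": float(self.youden_j_),
            "training": {
                "seed": self.random_state,
                "ga_trajectory": [float(v) for v in self.trajectory_],
                "best_fitness": float(self.best_fitness_),
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "LoadedTCRNodSeekModel":
        return LoadedTCRNodSeekModel(json.loads(Path(path).read_text()))


class LoadedTCRNodSeekModel:
    """A deserialised TCRnodseek model evaluating the stored SVM directly."""

    def __init__(self, payload: dict):
        if payload.get("schema_version") != 1:
            raise ValidationError("unsupported model schema version")
        self.payload = payload
        self.selected_features_ = payload["selected_features"]
        self.classes_ = np.array(payload["classes"])
        self.positive_label_ = payload["positive_label"]
        self.youden_cutoff_ = payload["youden_cutoff"]
        self._mean = np.array(payload["standardization"]["mean"])
        self._scale = np.array(payload["standardization"]["scale"])
        self._sv = np.array(payload["svm"]["support_vectors"])
        self._dual = np.array(payload["svm"]["dual_coef"])[0]
        self._b = payload["svm"]["intercept"][0]
        self._gamma = payload["svm"]["gamma"]
        self._kernel = payload["hyperparameters"]["kernel"]
        self._cal_a = payload["calibration"]["coef"]
        self._cal_b = payload["calibration"]["intercept"]

    def _scores(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.selected_features_ if c not in X.columns]
            if missing:
                raise ValidationError(f"missing feature column(s): {missing}")
            X = X[self.selected_features_].to_numpy(dtype=float)
        xs = (np.asarray(X, dtype=float) - self._mean) / self._scale
        if self._kernel == "linear":
            k = xs @ self._sv.T
        else:
            d2 = ((xs[:, None, :] - self._sv[None, :, :]) ** 2).sum(axis=2)
            k = np.exp(-self._gamma * d2)
        return k @ self._dual + self._b

    def predict_value(self, X) -> np.ndarray:
        s = self._scores(X)
        return 1.0 / (1.0 + np.exp(-(self._cal_a * s + self._cal_b)))

    def predict(self, X) -> np.ndarray:
        v = self.predict_value(X)
        negative = next(c for c in self.classes_ if c != self.positive_label_)
        return np.where(v >= self.youden_cutoff_, self.positive_label_, negative)


# ------------------------------------------------------- functional wrappers

def ga_optimize(table: pd.DataFrame, selected_features, ga: GAConfig):
    """Run only the hyperparameter search; returns (best params, trajectory)."""
    model = TCRNodSeekClassifier.from_ga_config(ga, features=list(selected_features))
    X, y = split_features_labels(table)
    model.fit(X, y)
    return model.best_params_, model.trajectory_


def train(table: pd.DataFrame, selected_features, ga: GAConfig) -> TCRNodSeekClassifier:
    """Train a TCRnodseek model on a cohort feature table with labels."""
    model = TCRNodSeekClassifier.from_ga_config(ga, features=list(selected_features))
    X, y = split_features_labels(table)
    return model.fit(X, y)


def predict(model, table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject predicted value and label at the Youden cutoff."""
    X = table.drop(columns=[LABEL_COLUMN], errors="ignore")
    values = model.predict_value(X)
    labels = model.predict(X)
    return pd.DataFrame(
        {"predicted_value": values, "predicted_label": labels}, index=table.index
    )


def ablate_tcr_features(
    table: pd.DataFrame,
    selected_features,
    ga: GAConfig,
    tcr_features=TCR_FEATURES,
):
    """Train paired models with and without the TCR-derived features.

    Both models use the same GA seed and therefore identical CV folds.  The
    without-TCR model uses every non-TCR column of the table (not just the
    selected subset) so clinical information is fully available to it.
    """
    with_model = train(table, selected_features, ga)
    non_tcr = [
        c for c in table.columns if c not in tcr_features and c != LABEL_COLUMN
    ]
    if not non_tcr:
        raise ValidationError("no non-TCR features left for the ablated model")
    without_model = train(table, non_tcr, ga)
    return with_model, without_model
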