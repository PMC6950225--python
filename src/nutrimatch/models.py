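"""Zero-inflated nutrient prediction from the shared nutrient panel.

A target-database-exclusive nutrient (lactose, g per 100 g) is predicted
from the shared nutrients.  Because the response is non-negative and has a
large point mass at exactly zero (lactose-free foods), plain regressors are
composed two ways:

* **bounded** — any regressor with its negative predictions clipped to 0
  (:class:`BoundedRegressor`);
* **combined** — a zero/non-zero classifier multiplied element-wise with a
  bounded regressor, so a food classified lactose-free is predicted exactly
  0 (:class:`ZeroInflatedRegressor`, a hurdle-style composition).

Regressor families: LASSO, Ridge, a feed-forward neural network, and
gradient-boosted trees; naive baselines (mean, median, median-of-nonzero,
perfect-classifier-plus-mean) calibrate how much signal the features add.
Features are standardized with training-set statistics only, and training
outliers are removed by isolation-forest anomaly ranking.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import IsolationForest
from sklearn.linear_model import Lasso, LogisticRegression, Ridge
from sklearn.model_selection import GridSearchCV, KFold, RepeatedKFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessState",
    "standardize",
    "remove_outliers",
    "MeanBaseline",
    "MedianBaseline",
    "NonzeroMedianBaseline",
    "PerfectClassifierMeanBaseline",
    "fit_baseline",
    "BoundedRegressor",
    "ZeroInflatedRegressor",
    "PredictorSpec",
    "build_predictor",
    "lasso_alpha_grid",
    "grid_search_cv",
    "feature_importances",
    "PRESETS",
]


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class PreprocessState:
    """Training-derived standardization statistics and excluded outliers."""

    means: np.ndarray
    stds: np.ndarray
    outlier_ids: list[str] = field(default_factory=list)
    contamination: float = 0.013


def standardize(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, PreprocessState]:
    """Standardize to zero mean / unit variance with training statistics.

    Test data are transformed with the training mean and standard deviation
    only — statistics never leak from test rows.  A zero-variance training
    column keeps scale 1 (values are only centered) with a warning.
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("train must be 2-D with at least 2 rows")
    scaler = StandardScaler().fit(train)
    if np.any(scaler.var_ == 0):
        logger.warning(
            "%d zero-variance training column(s); std treated as 1",
            int(np.sum(scaler.var_ == 0)),
        )
    train_s = scaler.transform(train)
    test_s = None
    if test is not None:
        test = np.asarray(test, dtype=float)
        if test.shape[1] != train.shape[1]:
            raise ValueError("train and test must have the same feature count")
        test_s = scaler.transform(test)
    state = PreprocessState(
        means=scaler.mean_.copy(), stds=scaler.scale_.copy()
    )
    return train_s, test_s, state


def remove_outliers(
    train: np.ndarray,
    contamination: float = 0.013,
    seed: int = 0,
    ids: list[str] | None = None,
) -> tuple[np.ndarray, list]:
    """Drop the ``ceil(contamination * n)`` most anomalous training rows.

    Anomaly scores come from an isolation forest (random axis-aligned
    splits; shorter average isolation path = more anomalous).  The removal
    count is fixed by the ceiling rule, so e.g. n = 378 at contamination
    0.013 removes exactly 5 rows.  Deterministic under a fixed seed.

    Returns (kept rows, removed ids) where ids default to row indices.
    """
    if not 0 < contamination < 0.5:
        raise ValueError("contamination must be in (0, 0.5)")
    train = np.asarray(train, dtype=float)
    n = train.shape[0]
    if ids is None:
        ids = list(range(n))
    k = math.ceil(contamination * n)
    if contamination * n < 1:
        logger.warning(
            "contamination %.4g * n=%d < 1; no outliers removed", contamination, n
        )
        return train, []
    forest = IsolationForest(contamination=contamination, random_state=seed)
    forest.fit(train)
    scores = forest.score_samples(train)  # lower = more anomalous
    out_idx = np.argsort(scores, kind="stable")[:k]
    keep = np.ones(n, dtype=bool)
    keep[out_idx] = False
    return train[keep], [ids[i] for i in sorted(out_idx)]


# ---------------------------------------------------------------------------
# baselines


class _ConstantBaseline(RegressorMixin, BaseEstimator):
    def predict(self, X):
        check_is_fitted(self, "constant_")
        return np.full(np.asarray(X).shape[0], self.constant_)


class MeanBaseline(_ConstantBaseline):
    """Predicts the training-set mean everywhere."""

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if y.size == 0:
            raise ValueError("empty targets")
        self.constant_ = float(np.mean(y))
        return self


class MedianBaseline(_ConstantBaseline):
    """Predicts the training-set median everywhere."""

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if y.size == 0:
            raise ValueError("empty targets")
        self.constant_ = float(np.median(y))
        return self


class NonzeroMedianBaseline(_ConstantBaseline):
    """Predicts the median of the strictly positive training targets."""

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        pos = y[y > 0]
        if pos.size == 0:
            raise ValueError("median-of-nonzero baseline needs positive targets")
        self.constant_ = float(np.median(pos))
        return self


class PerfectClassifierMeanBaseline(RegressorMixin, BaseEstimator):
    """Oracle zero/non-zero split plus the training mean.

    Predicts 0 where the *true* value is 0 and the training mean where it
    is non-zero, so ``predict`` needs the true targets — it is a ceiling
    for the combined compositions, not a deployable model.
    """

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if y.size == 0:
            raise ValueError("empty targets")
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X, y_true=None):
        check_is_fitted(self, "mean_")
        if y_true is None:
            raise ValueError(
                "the perfect-classifier baseline needs y_true at predict time"
            )
        y_true = np.asarray(y_true, dtype=float)
        return np.where(y_true == 0, 0.0, self.mean_)


_BASELINES = {
    "mean": MeanBaseline,
    "median": MedianBaseline,
    "median_nonzero": NonzeroMedianBaseline,
    "perfect_classifier_mean": PerfectClassifierMeanBaseline,
}


def fit_baseline(kind: str, train_targets) -> BaseEstimator:
    """Fit one of the four naive baselines on the training targets."""
    if kind not in _BASELINES:
        raise ValueError(f"unknown baseline {kind!r}; choose from {sorted(_BASELINES)}")
    return _BASELINES[kind]().fit(None, train_targets)


# ---------------------------------------------------------------------------
# bounded and combined compositions


class BoundedRegressor(RegressorMixin, BaseEstimator):
    """Meta-regressor clipping negative predictions to 0.

    Lactose per 100 g cannot be negative, but unconstrained regressors emit
    negative values near zero; the bound makes predictions physically
    admissible without changing the fit.  Coefficients of a wrapped linear
    model are passed through (they equal the unbounded model's).
    """

    def __init__(self, regressor=None):
        self.regressor = regressor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in training data")
        reg = self.regressor if self.regressor is not None else Lasso()
        self.regressor_ = clone(reg).fit(X, y)
        return self

    def predict(self, X):
        check_is_fitted(self, "regressor_")
        return np.maximum(0.0, np.asarray(self.regressor_.predict(X), dtype=float))

    def predict_raw(self, X):
        """The wrapped regressor's unclipped predictions."""
        check_is_fitted(self, "regressor_")
        return np.asarray(self.regressor_.predict(X), dtype=float)

    @property
    def coef_(self):
        return self.regressor_.coef_

    @property
    def intercept_(self):
        return self.regressor_.intercept_


class ZeroInflatedRegressor(RegressorMixin, BaseEstimator):
    """Zero/non-zero classifier times a bounded regressor (hurdle model).

    The classifier learns the indicator ``y > 0`` (exact zeros are the zero
    class); the regressor is fit on all training rows.  The final
    prediction is the element-wise product of the binary class and the
    clipped regression output, so predictions are 0 exactly where the
    classifier says zero.
    """

    def __init__(self, classifier=None, regressor=None, threshold: float = 0.5):
        self.classifier = classifier
        self.regressor = regressor
        self.threshold = threshold

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        labels = (y > 0).astype(int)
        if labels.min() == labels.max():
            raise ValueError(
                "targets must contain both zero and non-zero values"
            )
        clf = self.classifier if self.classifier is not None else LogisticRegression(
            max_iter=5000
        )
        reg = self.regressor if self.regressor is not None else BoundedRegressor()
        self.classifier_ = clone(clf).fit(X, labels)
        reg = clone(reg)
        if not isinstance(reg, BoundedRegressor):
            reg = BoundedRegressor(regressor=reg)
        self.regressor_ = reg.fit(X, y)
        return self

    def predict_zero_class(self, X) -> np.ndarray:
        """Binary indicator: 1 = lactose-containing, 0 = lactose-free."""
        check_is_fitted(self, "classifier_")
        if hasattr(self.classifier_, "predict_proba"):
            proba = self.classifier_.predict_proba(X)[:, 1]
            return (proba >= self.threshold).astype(int)
        return np.asarray(self.classifier_.predict(X), dtype=int)

    def predict(self, X):
        check_is_fitted(self, "regressor_")
        return self.predict_zero_class(X) * self.regressor_.predict(X)

    @property
    def coef_(self):
        return self.regressor_.coef_


# ---------------------------------------------------------------------------
# family construction

#: Final hyperparameters as published for the original train/test split;
#: they are data-dependent optima shipped as a preset, not defaults.
PRESETS: dict[str, dict] = {
    "published-final": {
        "lasso": {"alpha": 0.039},
        "bounded_lasso": {"alpha": 0.020},
        "combined_lasso": {"alpha": 0.022, "C": 215443.47},
        "ridge": {"alpha": 59.64},
        "bounded_ridge": {"alpha": 15.20},
        "combined_ridge": {"alpha": 27.83, "C": 215443.47},
        "ffnn": {
            "hidden_layers": 2,
            "nodes_per_layer": 50,
            "learning_rate": 0.0012,
            "alpha": 0.029,
            "epochs": 185,
        },
        "gbt": {
            "n_estimators": 100,
            "max_depth_regressor": 9,
            "max_depth_classifier": 7,
            "colsample_regressor": 0.9,
            "colsample_classifier": 1.0,
        },
    }
}


@dataclass
class PredictorSpec:
    """Declarative model composition: family + bounded/combined switches."""

    family: str  # {"lasso", "ridge", "ffnn", "gbt"} or a baseline kind
    bounded: bool = False
    combined: bool = False
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.combined:
            self.bounded = True  # the regressor branch is always bounded


def _make_regressor(family: str, hp: dict, seed: int):
    if family == "lasso":
        return Lasso(alpha=hp.get("alpha", 1.0), max_iter=50_000)
    if family == "ridge":
        return Ridge(alpha=hp.get("alpha", 1.0))
    if family == "ffnn":
        layers = int(hp.get("hidden_layers", 2))
        nodes = int(hp.get("nodes_per_layer", 50))
        return MLPRegressor(
            hidden_layer_sizes=(nodes,) * layers,
            learning_rate_init=hp.get("learning_rate", 0.0012),
            alpha=hp.get("alpha", 0.029),
            max_iter=int(hp.get("epochs", 185)),
            random_state=seed,
        )
    if family == "gbt":
        from xgboost import XGBRegressor

        return XGBRegressor(
            n_estimators=int(hp.get("n_estimators", 100)),
            max_depth=int(hp.get("max_depth_regressor", 9)),
            colsample_bytree=hp.get("colsample_regressor", 0.9),
            random_state=seed,
            verbosity=0,
        )
    raise ValueError(f"unknown regression family {family!r}")


def _make_classifier(family: str, hp: dict, seed: int):
    if family == "gbt":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=int(hp.get("n_estimators", 100)),
            max_depth=int(hp.get("max_depth_classifier", 7)),
            colsample_bytree=hp.get("colsample_classifier", 1.0),
            random_state=seed,
            verbosity=0,
        )
    return LogisticRegression(C=hp.get("C", 1.0), max_iter=5000, random_state=seed)


def build_predictor(spec: PredictorSpec, seed: int = 0) -> BaseEstimator:
    """Build the estimator a :class:`PredictorSpec` describes (unfitted)."""
    if spec.family in _BASELINES:
        return _BASELINES[spec.family]()
    reg = _make_regressor(spec.family, spec.hyperparams, seed)
    if spec.combined:
        return ZeroInflatedRegressor(
            classifier=_make_classifier(spec.family, spec.hyperparams, seed),
            regressor=BoundedRegressor(regressor=reg),
            threshold=spec.hyperparams.get("threshold", 0.5),
        )
    if spec.bounded:
        return BoundedRegressor(regressor=reg)
    return reg


def lasso_alpha_grid(
    num: int = 50, low: float = 1e-3, high: float = 1.0
) -> np.ndarray:
    """The default LASSO penalty grid: log-spaced between 1e-3 and 1."""
    return np.logspace(np.log10(low), np.log10(high), num)


# ---------------------------------------------------------------------------
# cross-validated grid search


def grid_search_cv(
    estimator: BaseEstimator,
    param_grid: dict,
    X,
    y,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    scoring: str = "r2",
) -> tuple[dict, pd.DataFrame]:
    """Seeded k-fold grid search; returns (best params, full CV table).

    Mean CV score (default R²) per grid point; grid points whose folds fail
    (e.g. a single-class classifier fold) are flagged invalid and never
    selected.  Score ties are broken toward the smallest parameter values
    in the grid's key order.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not param_grid:
        raise ValueError("param_grid must be non-empty")
    if repeats > 1:
        cv = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    else:
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search = GridSearchCV(
            estimator,
            param_grid,
            scoring=scoring,
            cv=cv,
            error_score=np.nan,
            refit=False,
        ).fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    table = pd.DataFrame(
        {
            **{k: search.cv_results_[f"param_{k}"] for k in param_grid},
            "mean_cv_score": search.cv_results_["mean_test_score"],
            "std_cv_score": search.cv_results_["std_test_score"],
        }
    )
    table["valid"] = ~table["mean_cv_score"].isna()
    if not table["valid"].any():
        raise ValueError("every grid point failed cross-validation")
    valid = table[table["valid"]]
    best_score = valid["mean_cv_score"].max()
    ties = valid[valid["mean_cv_score"] >= best_score - 1e-15]
    ties = ties.sort_values(list(param_grid), kind="stable")
    best = {k: ties.iloc[0][k] for k in param_grid}
    return best, table


# ---------------------------------------------------------------------------
# feature importances


def feature_importances(model, feature_names=None, method_out: dict | None = None):
    """Per-feature importances aligned to ``feature_names``.

    * Linear families (incl. their bounded/combined wrappers): signed
      coefficients; exact zeros stay exactly 0.
    * Feed-forward network: signed sum of first-layer weights per input
      (``first_layer_weight_sum``).
    * Gradient-boosted trees: non-negative split frequency per feature
      (``split_frequency``); features never split on report 0.

    Returns a pandas Series (sortable by absolute magnitude).  Raises for
    families without defined importances.  ``method_out``, if supplied, is
    filled with a ``{"method": ...}`` label for the export.
    """
    inner = model
    if isinstance(inner, ZeroInflatedRegressor):
        inner = inner.regressor_
    if isinstance(inner, BoundedRegressor):
        inner = inner.regressor_

    method = None
    if isinstance(inner, MLPRegressor):
        values = inner.coefs_[0].sum(axis=1)
        method = "first_layer_weight_sum"
    elif hasattr(inner, "get_booster"):
        booster = inner.get_booster()
        scores = booster.get_score(importance_type="weight")
        n = inner.n_features_in_
        values = np.zeros(n)
        for key, v in scores.items():
            values[int(key.lstrip("f"))] = v
        method = "split_frequency"
    elif hasattr(inner, "coef_"):
        values = np.asarray(inner.coef_, dtype=float).ravel()
        method = "coefficients"
    else:
        raise ValueError(
            f"feature importances are not defined for {type(inner).__name__}"
        )
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(len(values))]
    if len(feature_names) != len(values):
        raise ValueError("feature_names length does not match importance count")
    if method_out is not None:
        method_out["method"] = method
    return pd.Series(values, index=list(feature_names), name=method)
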