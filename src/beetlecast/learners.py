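"""The nine probabilistic infestation classifiers behind one train/predict contract.

Discriminative learners (SVM, GLM, GBM, KNN, NN) work on raw/standardized
features; the Bayesian-network learners (NB, CL, IAMB) work on a 5-level
equal-width discretization fitted on the training rows; the mixed model
(MM) is a logistic stacker over the other eight, fitted on out-of-fold
probabilities produced by year folds so the stacking step cannot leak the
target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from beetlecast.bayesnet import ChowLiuTree, DiscreteNaiveBayes, IambModel
from beetlecast.features import Discretizer, FeatureMatrix

LEARNER_NAMES = ["SVM", "GLM", "GBM", "NB", "CL", "IAMB", "KNN", "NN", "MM"]
BASE_LEARNERS = [n for n in LEARNER_NAMES if n != "MM"]


class SingleClassError(ValueError):
    """Training data contains only one target class."""


@dataclass
class LearnerSpec:
    """Name plus hyperparameters of one learner.

    Defaults follow the reference analysis: GBM with 10,000 depth-1 trees
    and shrinkage 0.1; KNN with k = 15 Euclidean neighbors; NN with one
    hidden layer of ceil(n_features / 2) sigmoid units; linear SVM with a
    Platt-style sigmoid mapping decision values to probabilities.
    """

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in LEARNER_NAMES:
            raise ValueError(f"unknown learner {self.name!r}; choose from {LEARNER_NAMES}")

    def get(self, key: str, default):
        return self.params.get(key, default)


def default_specs(**overrides) -> list[LearnerSpec]:
    """Specs for the full nine-learner roster, with optional per-learner params.

    ``overrides`` maps learner name to a params dict, e.g.
    ``default_specs(GBM={"n_estimators": 200})``.
    """
    return [LearnerSpec(name, dict(overrides.get(name, {}))) for name in LEARNER_NAMES]


# ---------------------------------------------------------------------------
# Trained model wrappers
# ---------------------------------------------------------------------------

class TrainedModel:
    """A fitted learner exposing probability-of-infestation predictions."""

    version = 1

    def __init__(self, name: str, feature_cols: list[str], params: dict):
        self.name = name
        self.feature_cols = list(feature_cols)
        self.params = dict(params)

    def _check_schema(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.feature_cols if c not in X.columns]
        if missing:
            raise ValueError(f"prediction rows lack feature columns: {missing}")
        return X[self.feature_cols]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        p = self._predict(self._check_schema(X))
        return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)

    def _predict(self, X: pd.DataFrame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _SklearnModel(TrainedModel):
    def __init__(self, name, feature_cols, params, estimator, scaler=None):
        super().__init__(name, feature_cols, params)
        self.estimator = estimator
        self.scaler = scaler

    def _predict(self, X):
        arr = X.to_numpy(dtype=float)
        if self.scaler is not None:
            arr = self.scaler.transform(arr)
        return self.estimator.predict_proba(arr)[:, 1]


class _SvmModel(TrainedModel):
    """Linear SVM with a Platt sigmoid fitted on training decision values."""

    def __init__(self, name, feature_cols, params, svm, platt, scaler):
        super().__init__(name, feature_cols, params)
        self.svm = svm
        self.platt = platt
        self.scaler = scaler

    def decision_values(self, X: pd.DataFrame) -> np.ndarray:
        arr = self.scaler.transform(self._check_schema(X).to_numpy(dtype=float))
        return self.svm.decision_function(arr)

    def _predict(self, X):
        arr = self.scaler.transform(X.to_numpy(dtype=float))
        d = self.svm.decision_function(arr)[:, None]
        return self.platt.predict_proba(d)[:, 1]


class _KnnModel(TrainedModel):
    """k-nearest-neighbor vote with deterministic tie-breaks.

    Prediction is the infested fraction among the k Euclidean-nearest
    training rows; distance ties at the k-th neighbor are broken by
    training-row order (stable sort).
    """

    def __init__(self, name, feature_cols, params, X_train, y_train, k):
        super().__init__(name, feature_cols, params)
        self.X_train = np.asarray(X_train, dtype=float)
        self.y_train = np.asarray(y_train, dtype=float)
        self.k = int(min(k, len(self.y_train)))

    def _predict(self, X):
        arr = X.to_numpy(dtype=float)
        out = np.empty(len(arr))
        block = max(1, int(2e7) // max(len(self.X_train), 1))
        for start in range(0, len(arr), block):
            d = cdist(arr[start:start + block], self.X_train)
            order = np.argsort(d, axis=1, kind="stable")[:, : self.k]
            out[start:start + block] = self.y_train[order].mean(axis=1)
        return out


class _DiscreteModel(TrainedModel):
    """Wraps a discrete Bayesian-network model with its fitted bin edges."""

    def __init__(self, name, feature_cols, params, discretizer, model):
        super().__init__(name, feature_cols, params)
        self.discretizer = discretizer
        self.model = model

    def _predict(self, X):
        return self.model.predict_proba(self.discretizer.transform(X))

    def predict_partial(self, X: pd.DataFrame) -> np.ndarray:
        """Predict tolerating missing (NaN) covariate values."""
        cols = [c for c in self.feature_cols if c in X.columns]
        return self.model.predict_proba(self.discretizer.transform(X[cols]))


class _MixedModel(TrainedModel):
    """Logistic-regression stack over the base learners' probabilities."""

    def __init__(self, name, feature_cols, params, base_models, kept, stacker):
        super().__init__(name, feature_cols, params)
        self.base_models = base_models  # dict name -> TrainedModel
        self.kept = list(kept)          # base columns used by the stacker
        self.stacker = stacker          # LogisticRegression or None (prior only)
        self.prior = params.get("prior", 0.5)

    def base_probabilities(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {name: self.base_models[name].predict(X) for name in self.base_models}
        )

    def _predict(self, X):
        probs = self.base_probabilities(X)
        if self.stacker is None or not self.kept:
            return np.full(len(X), self.prior)
        return self.stacker.predict_proba(probs[self.kept].to_numpy())[:, 1]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _xy(fm: FeatureMatrix, rows):
    X = fm.features(rows)
    y = fm.target(rows).astype(int)
    if len(X) == 0:
        raise ValueError("empty training data")
    return X, y


def _require_two_classes(y: np.ndarray, name: str) -> None:
    if len(np.unique(y)) < 2:
        raise SingleClassError(
            f"{name} requires both target classes in the training data"
        )


def _fit_discrete(name, spec, fm, rows, model_factory):
    X, y = _xy(fm, rows)
    disc = Discretizer(n_levels=spec.get("n_levels", 5)).fit(X)
    Xd = disc.transform(X)
    level_sets = {c: disc.level_values(c) for c in X.columns}
    model = model_factory(Xd, y, level_sets)
    return _DiscreteModel(name, fm.feature_cols, spec.params, disc, model)


def train(
    spec: LearnerSpec,
    fm: FeatureMatrix,
    seed: int | None = 0,
    rows=None,
    folds=None,
) -> TrainedModel:
    """Fit one learner on (a subset of) a feature matrix.

    ``rows`` restricts training to a row index subset (default: all rows).
    ``folds`` (year folds of the training rows) is only consumed by the
    mixed model, whose stacker is fitted on out-of-fold base probabilities.
    Deterministic given the seed.
    """
    name = spec.name
    if name == "MM":
        return fit_mixed_model(
            [LearnerSpec(n, spec.params.get(n, {})) for n in BASE_LEARNERS],
            fm,
            seed=seed,
            rows=rows,
            folds=folds,
            stacking=spec.get("stacking", "out-of-fold"),
        )

    X, y = _xy(fm, rows)

    if name == "GLM":
        _require_two_classes(y, name)
        est = LogisticRegression(
            penalty=None, max_iter=spec.get("max_iter", 2000), solver="lbfgs"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X.to_numpy(dtype=float), y)
        return _SklearnModel(name, fm.feature_cols, spec.params, est)

    if name == "GBM":
        _require_two_classes(y, name)
        est = GradientBoostingClassifier(
            n_estimators=spec.get("n_estimators", 10_000),
            max_depth=spec.get("max_depth", 1),
            learning_rate=spec.get("learning_rate", 0.1),
            random_state=seed,
        )
        est.fit(X.to_numpy(dtype=float), y)
        return _SklearnModel(name, fm.feature_cols, spec.params, est)

    if name == "SVM":
        _require_two_classes(y, name)
        scaler = StandardScaler().fit(X.to_numpy(dtype=float))
        arr = scaler.transform(X.to_numpy(dtype=float))
        svm = LinearSVC(
            C=spec.get("C", 1.0),
            max_iter=spec.get("max_iter", 5000),
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            svm.fit(arr, y)
            platt = LogisticRegression(max_iter=1000)
            platt.fit(svm.decision_function(arr)[:, None], y)
        return _SvmModel(name, fm.feature_cols, spec.params, svm, platt, scaler)

    if name == "NN":
        _require_two_classes(y, name)
        hidden = spec.get("hidden_units", None) or math.ceil(len(fm.feature_cols) / 2)
        scaler = StandardScaler().fit(X.to_numpy(dtype=float))
        est = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            activation="logistic",
            max_iter=spec.get("max_iter", 300),
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(scaler.transform(X.to_numpy(dtype=float)), y)
        return _SklearnModel(name, fm.feature_cols, spec.params, est, scaler=scaler)

    if name == "KNN":
        return _KnnModel(
            name, fm.feature_cols, spec.params,
            X.to_numpy(dtype=float), y, k=spec.get("k", 15),
        )

    if name == "NB":
        alpha = spec.get("alpha", 1.0)
        return _fit_discrete(
            name, spec, fm, rows,
            lambda Xd, yy, lv: DiscreteNaiveBayes(alpha=alpha).fit(Xd, yy, lv),
        )

    if name == "CL":
        alpha = spec.get("alpha", 1.0)
        return _fit_discrete(
            name, spec, fm, rows,
            lambda Xd, yy, lv: ChowLiuTree(alpha=alpha).fit(Xd, yy, lv),
        )

    if name == "IAMB":
        sig = spec.get("alpha", 0.05)
        return _fit_discrete(
            name, spec, fm, rows,
            lambda Xd, yy, lv: IambModel(alpha=sig).fit(Xd, yy, lv),
        )

    raise ValueError(f"unknown learner {name!r}")


def predict(model: TrainedModel, fm: FeatureMatrix, rows=None) -> np.ndarray:
    """Probability of infestation for (a subset of) feature-matrix rows."""
    return model.predict(fm.features(rows))


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model to a versioned container on disk."""
    import joblib

    joblib.dump(
        {
            "container_version": TrainedModel.version,
            "learner": model.name,
            "hyperparameters": model.params,
            "feature_cols": model.feature_cols,
            "model": model,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    """Load a model saved by :func:`save_model` (deterministic round-trip)."""
    import joblib

    payload = joblib.load(path)
    if payload.get("container_version") != TrainedModel.version:
        raise ValueError(
            f"unsupported model container version {payload.get('container_version')}"
        )
    return payload["model"]


# ---------------------------------------------------------------------------
# Mixed model (stacked generalization)
# ---------------------------------------------------------------------------

def _year_folds(fm: FeatureMatrix, rows) -> list[tuple[np.ndarray, np.ndarray]]:
    rows = np.asarray(rows)
    ty = fm.df.loc[rows, "target_year"].to_numpy()
    folds = []
    for year in np.unique(ty):
        m = ty == year
        folds.append((rows[m], rows[~m]))
    return folds


def out_of_fold_probabilities(
    base_specs: list[LearnerSpec],
    fm: FeatureMatrix,
    rows,
    seed: int | None = 0,
    folds=None,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Out-of-fold base probabilities over the training rows, by year fold.

    Returns (probability frame indexed like ``rows``, target, failed names).
    Base learners that fail on some fold (e.g., a single-class fold for a
    discriminative learner) are dropped entirely with a warning.
    """
    rows = np.asarray(rows if rows is not None else fm.df.index.to_numpy())
    if folds is None:
        folds = [(hold, rest) for (hold, rest) in _year_folds(fm, rows)]
    else:
        folds = [(hold, rest) for (_, hold, rest) in folds] if len(folds) and len(folds[0]) == 3 else folds
    if len(folds) < 2:
        folds = [(rows, rows)]  # degenerate: resubstitution fallback

    probs = pd.DataFrame(index=rows, dtype=float)
    failed: list[str] = []
    for spec in base_specs:
        col = np.full(len(rows), np.nan)
        pos = {r: i for i, r in enumerate(rows)}
        try:
            for hold, rest in folds:
                model = train(spec, fm, seed=seed, rows=rest)
                p = predict(model, fm, hold)
                col[[pos[r] for r in hold]] = p
        except (SingleClassError, ValueError) as exc:
            warnings.warn(f"base learner {spec.name} dropped from stack: {exc}")
            failed.append(spec.name)
            continue
        probs[spec.name] = col
    y = fm.target(rows).astype(int)
    return probs, y, failed


def fit_mixed_model(
    base_specs: list[LearnerSpec],
    fm: FeatureMatrix,
    seed: int | None = 0,
    rows=None,
    folds=None,
    stacking: str = "out-of-fold",
    oof_probs: pd.DataFrame | None = None,
) -> _MixedModel:
    """Fit the stacked mixed model.

    The stacking coefficients are a logistic regression of the target on
    the eight base probabilities.  By default those probabilities are
    produced out-of-fold over the year folds of the training rows, which
    keeps the stacker from rewarding base models that memorize their
    training targets; ``stacking="resubstitution"`` uses in-sample
    probabilities instead (for fidelity experiments).  Base models are then
    refitted on all training rows for prediction.  Constant probability
    columns carry no ranking signal and are excluded from the stacker; if
    none remain, the model predicts the training base rate.
    """
    rows = np.asarray(rows if rows is not None else fm.df.index.to_numpy())
    y = fm.target(rows).astype(int)

    base_models: dict[str, TrainedModel] = {}
    failed: list[str] = []
    for spec in base_specs:
        try:
            base_models[spec.name] = train(spec, fm, seed=seed, rows=rows)
        except (SingleClassError, ValueError) as exc:
            warnings.warn(f"base learner {spec.name} dropped from stack: {exc}")
            failed.append(spec.name)

    if stacking == "resubstitution":
        probs = pd.DataFrame(
            {name: m.predict(fm.features(rows)) for name, m in base_models.items()},
            index=rows,
        )
    elif oof_probs is not None:
        probs = oof_probs.loc[rows, [s.name for s in base_specs if s.name in oof_probs]]
    else:
        specs_ok = [s for s in base_specs if s.name in base_models]
        probs, _, oof_failed = out_of_fold_probabilities(
            specs_ok, fm, rows, seed=seed, folds=folds
        )
        failed.extend(oof_failed)

    probs = probs[[c for c in probs.columns if c not in failed]]
    probs = probs.dropna(axis=1)
    kept = [c for c in probs.columns if probs[c].nunique() > 1]
    params = {"stacking": stacking, "prior": float(y.mean()), "dropped": failed}

    stacker = None
    if kept and len(np.unique(y)) > 1:
        stacker = LogisticRegression(max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stacker.fit(probs[kept].to_numpy(), y)
    return _MixedModel("MM", fm.feature_cols, params, base_models, kept, stacker)
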