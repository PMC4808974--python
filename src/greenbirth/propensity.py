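"""Super-learner propensity scores for the high-greenness contrast.

The probability of living in greenness tertiles 2-3 given baseline
covariates is estimated, within each community type, by a stacking
ensemble: base learners produce V-fold cross-validated predictions, a
convex weight vector over learners is chosen to minimize the
cross-validated binomial negative log-likelihood, and the weighted
combination of full-sample refits yields the final score. By construction
the ensemble's cross-validated risk is no worse than the best single
learner's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import clone
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.compose import ColumnTransformer

__all__ = [
    "PropensityFit",
    "make_folds",
    "cv_predictions",
    "solve_weights",
    "fit_propensity",
    "default_library",
    "binomial_nll",
]

SCORE_EPS = 1e-4  # final scores clipped to [eps, 1-eps]
_PRED_EPS = 1e-6


def binomial_nll(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binomial negative log-likelihood (the CV risk)."""
    p = np.clip(np.asarray(p, float), _PRED_EPS, 1 - _PRED_EPS)
    y = np.asarray(y, float)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def make_folds(n: int, V: int, labels: np.ndarray, seed: int) -> np.ndarray:
    """Exposure-stratified fold assignment; sizes differ by <= 1 per stratum."""
    if V < 2:
        raise ValueError("V must be >= 2")
    if n < 2 * V:
        raise ValueError("need n >= 2V")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < V:
            raise ValueError(f"stratum {lab!r} has fewer than V={V} members")
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % V
    return folds


def _spline_logistic() -> Pipeline:
    """L2 logistic on a spline basis of the continuous columns (GAM surrogate)."""
    def build(X: np.ndarray):
        X = np.asarray(X, float)
        nuniq = np.array([len(np.unique(X[:, j])) for j in range(X.shape[1])])
        cont = np.flatnonzero(nuniq > 4)
        disc = np.flatnonzero(nuniq <= 4)
        return ColumnTransformer([
            ("spline", SplineTransformer(n_knots=4, degree=3), cont),
            ("pass", "passthrough", disc),
        ])

    class SplineLogit:
        def __init__(self):
            self._model = None

        def get_params(self, deep=True):  # sklearn clone support
            return {}

        def set_params(self, **kw):
            return self

        def fit(self, X, y):
            ct = build(X)
            self._model = Pipeline([
                ("expand", ct),
                ("scale", StandardScaler()),
                ("logit", LogisticRegression(C=1.0, max_iter=2000)),
            ])
            self._model.fit(np.asarray(X, float), y)
            return self

        def predict_proba(self, X):
            return self._model.predict_proba(np.asarray(X, float))

    return SplineLogit()


def default_library(seed: int = 0) -> list[tuple[str, object]]:
    """Default base learners: marginal mean, L2 logistic, spline logistic,
    shallow gradient-boosted trees."""
    return [
        ("mean", DummyClassifier(strategy="prior")),
        ("logistic", Pipeline([("scale", StandardScaler()),
                               ("logit", LogisticRegression(C=1.0, max_iter=2000))])),
        ("spline_logistic", _spline_logistic()),
        ("gbt", GradientBoostingClassifier(max_depth=2, n_estimators=100,
                                           learning_rate=0.1,
                                           random_state=int(seed) % 2**31)),
    ]


def fast_library() -> list[tuple[str, object]]:
    """Small library for replicate studies: marginal mean + L2 logistic."""
    return [
        ("mean", DummyClassifier(strategy="prior")),
        ("logistic", Pipeline([("scale", StandardScaler()),
                               ("logit", LogisticRegression(C=1.0, max_iter=2000))])),
    ]


def _clone(est):
    try:
        return clone(est)
    except TypeError:
        return est.__class__()


def cv_predictions(X: np.ndarray, y: np.ndarray, folds: np.ndarray,
                   library: Sequence[tuple[str, object]],
                   ) -> tuple[np.ndarray, list[str], list[str]]:
    """Cross-validated prediction matrix (n x n_learners).

    Entry (i, l) is learner l's predicted probability for subject i, trained
    on all folds except i's. Learners that fail on any fold are dropped with
    a warning; returns (matrix, kept learner names, dropped names).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    cols, kept, dropped = [], [], []
    for name, est in library:
        pred = np.full(n, np.nan)
        try:
            for v in np.unique(folds):
                tr = folds != v
                model = _clone(est).fit(X[tr], y[tr])
                pred[~tr] = model.predict_proba(X[~tr])[:, 1]
        except Exception as exc:  # noqa: BLE001 - any learner failure drops it
            warnings.warn(f"learner {name!r} dropped: {exc}", stacklevel=2)
            dropped.append(name)
            continue
        cols.append(pred)
        kept.append(name)
    if not cols:
        raise RuntimeError("every learner failed")
    return np.column_stack(cols), kept, dropped


def solve_weights(Z: np.ndarray, y: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Convex learner weights minimizing the CV binomial NLL on the simplex.

    Ties between learners with identical prediction columns are resolved by
    splitting their total weight uniformly.
    """
    Z = np.clip(np.asarray(Z, float), _PRED_EPS, 1 - _PRED_EPS)
    y = np.asarray(y, float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("prediction matrix contains non-finite entries")
    L = Z.shape[1]
    if L == 1:
        return np.array([1.0])

    def nll(w):
        p = np.clip(Z @ w, _PRED_EPS, 1 - _PRED_EPS)
        return -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))

    def grad(w):
        p = np.clip(Z @ w, _PRED_EPS, 1 - _PRED_EPS)
        return -(Z.T @ (y / p - (1 - y) / (1 - p))) / len(y)

    res = minimize(nll, np.full(L, 1.0 / L), jac=grad, method="SLSQP",
                   bounds=[(0.0, 1.0)] * L,
                   constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                                 "jac": lambda w: np.ones(L)}],
                   options={"ftol": tol, "maxiter": 500})
    if not res.success:
        raise RuntimeError(f"weight optimization failed: {res.message}")
    w = np.clip(res.x, 0.0, None)
    w /= w.sum()

    # the simplex vertices are feasible, so no single learner may beat the
    # ensemble; polish from the best vertex if the solver left slack
    vertex_nll = np.array([nll(np.eye(L)[j]) for j in range(L)])
    best = int(np.argmin(vertex_nll))
    if nll(w) > vertex_nll[best]:
        res2 = minimize(nll, np.eye(L)[best], jac=grad, method="SLSQP",
                        bounds=[(0.0, 1.0)] * L,
                        constraints=[{"type": "eq",
                                      "fun": lambda w: w.sum() - 1.0,
                                      "jac": lambda w: np.ones(L)}],
                        options={"ftol": tol, "maxiter": 500})
        cand = np.clip(res2.x, 0.0, None)
        cand /= cand.sum()
        w = cand if nll(cand) <= vertex_nll[best] else np.eye(L)[best]

    # uniform tie rule over duplicate columns
    groups: list[list[int]] = []
    for j in range(L):
        for g in groups:
            if np.allclose(Z[:, j], Z[:, g[0]], atol=1e-12):
                g.append(j)
                break
        else:
            groups.append([j])
    for g in groups:
        if len(g) > 1:
            w[g] = w[g].sum() / len(g)
    return w


@dataclass
class PropensityFit:
    """Result of the stacked propensity estimation for one sample."""

    folds: np.ndarray
    cv_matrix: np.ndarray
    learner_names: list[str]
    dropped_learners: list[str]
    weights: np.ndarray
    learner_risks: dict[str, float]
    ensemble_risk: float
    scores: np.ndarray
    seed: int
    V: int
    covariate_names: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "learners": self.learner_names,
            "dropped": self.dropped_learners,
            "weights": [float(w) for w in self.weights],
            "learner_risks": {k: float(v) for k, v in self.learner_risks.items()},
            "ensemble_risk": float(self.ensemble_risk),
            "V": self.V,
            "seed": self.seed,
            "covariates": self.covariate_names,
        }


def fit_propensity(X: np.ndarray | pd.DataFrame, y: np.ndarray,
                   library: Sequence[tuple[str, object]] | None = None,
                   V: int = 10, seed: int = 0) -> PropensityFit:
    """Stacked-ensemble propensity scores for one community-type sample."""
    names: list[str] = []
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if library is None:
        library = default_library(seed)

    folds = make_folds(len(y), V, y, seed)
    Z, kept, dropped = cv_predictions(X, y, folds, library)
    w = solve_weights(Z, y)

    risks = {name: binomial_nll(Z[:, j], y) for j, name in enumerate(kept)}
    ens_risk = binomial_nll(Z @ w, y)

    # refit on the full sample and combine
    full_preds = []
    lib_by_name = dict(library)
    for name in kept:
        model = _clone(lib_by_name[name]).fit(X, y)
        full_preds.append(model.predict_proba(X)[:, 1])
    scores = np.clip(np.column_stack(full_preds) @ w, SCORE_EPS, 1 - SCORE_EPS)

    return PropensityFit(folds, Z, kept, dropped, w, risks, ens_risk,
                         scores, seed, V, names)
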