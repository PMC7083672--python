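"""The ten single-model algorithms.

Registry: ANN, CTA, FDA, GAM, GBM, GLM, MAXENT, MARS, RF, SRE.  All produce
per-cell suitabilities in [0, 1] so they are commensurate in the weighted
ensemble.  The surface range envelope (SRE, the BIOCLIM climate envelope)
is implemented from scratch; the presence-background maximum-entropy model
for continuous predictors is fit as its regularized-logistic equivalence;
the remaining learners are standard scikit-learn estimators behind a
uniform wrapper.  MARS and FDA share a hinge (piecewise-linear) basis
expansion; GAM uses per-variable B-spline bases.

Class weighting follows the equal-total convention: each presence has
weight 1 and each pseudo-absence has weight n_presence / n_absence, so the
two classes contribute equal total weight.  Learners without sample-weight
support (ANN, FDA) are fitted unweighted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .grids import Grid, GridStack, OccurrenceSet, extract_values
from .background import PseudoAbsenceSet

log = logging.getLogger(__name__)

ALGORITHM_IDS = ("ANN", "CTA", "FDA", "GAM", "GBM", "GLM", "MAXENT", "MARS",
                 "RF", "SRE")

DEFAULT_SRE_TAIL = 0.025


@dataclass
class TrainingSet:
    """Labeled presence/pseudo-absence table with equal-total case weights."""

    X: pd.DataFrame
    y: np.ndarray
    weights: np.ndarray
    variables: list[str]

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("case weights must be nonnegative")
        if self.X.isna().any().any():
            raise ValueError("training table contains NoData values")

    def subset(self, idx) -> "TrainingSet":
        return TrainingSet(
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y[idx], weights=self.weights[idx],
            variables=list(self.variables),
        )


def equal_total_weights(y: np.ndarray) -> np.ndarray:
    """Presences weight 1; absences n_presence/n_absence (equal class totals)."""
    y = np.asarray(y, dtype=int)
    n_p = int((y == 1).sum())
    n_a = int((y == 0).sum())
    if n_p == 0 or n_a == 0:
        raise ValueError("both classes must be nonempty")
    w = np.ones(len(y), dtype=float)
    w[y == 0] = n_p / n_a
    return w


def build_training_set(
    occ: OccurrenceSet,
    pa_set: PseudoAbsenceSet,
    stack: GridStack,
    variables: list[str],
) -> TrainingSet:
    """Assemble the labeled table for one pseudo-absence replicate.

    Points falling on NoData cells for any selected variable are dropped
    (logged); weights follow the equal-total convention.
    """
    pres = extract_values(stack, occ.lon, occ.lat, variables)
    absn = extract_values(stack, pa_set.lon, pa_set.lat, variables)
    n_bad = int(pres["on_nodata"].sum() + absn["on_nodata"].sum())
    if n_bad:
        log.info("dropping %d training points on NoData cells", n_bad)
    pres = pres[~pres["on_nodata"]]
    absn = absn[~absn["on_nodata"]]
    X = pd.concat([pres[variables], absn[variables]], ignore_index=True)
    y = np.concatenate([np.ones(len(pres), dtype=int),
                        np.zeros(len(absn), dtype=int)])
    return TrainingSet(X=X, y=y, weights=equal_total_weights(y),
                       variables=list(variables))


# ---------------------------------------------------------------------------
# feature bases

class HingeBasis(BaseEstimator, TransformerMixin):
    """Piecewise-linear basis: x plus hinge pairs at training quantiles.

    For each variable and each knot k in the fitted quantiles, emits
    max(x - k, 0) and max(k - x, 0); this is the adaptive-regression-spline
    style basis used by the MARS and FDA learners.
    """

    def __init__(self, quantiles=(0.2, 0.4, 0.6, 0.8)):
        self.quantiles = quantiles

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.knots_ = np.quantile(X, self.quantiles, axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        feats = [X]
        for q in range(self.knots_.shape[0]):
            k = self.knots_[q]
            feats.append(np.maximum(X - k, 0.0))
            feats.append(np.maximum(k - X, 0.0))
        return np.hstack(feats)


# ---------------------------------------------------------------------------
# surface range envelope (BIOCLIM)

class SREModel:
    """Rectilinear presence envelope on per-variable quantile intervals.

    Stores [q_tail, q_(1-tail)] of the presence values per variable;
    predicts 1 inside the box (every variable within its interval), else 0.
    """

    def __init__(self, tail_quantile: float = DEFAULT_SRE_TAIL):
        if not 0 <= tail_quantile < 0.5:
            raise ValueError("tail_quantile must be in [0, 0.5)")
        self.tail_quantile = tail_quantile

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        pres = X[y == 1]
        if len(pres) < 5:
            raise ValueError("SRE needs at least 5 presences")
        t = self.tail_quantile
        self.lo_ = np.quantile(pres, t, axis=0)
        self.hi_ = np.quantile(pres, 1.0 - t, axis=0)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        inside = np.all((X >= self.lo_) & (X <= self.hi_), axis=1)
        p1 = inside.astype(float)
        return np.column_stack([1.0 - p1, p1])


# ---------------------------------------------------------------------------
# registry

def _make_estimator(algorithm_id: str, seed: int, hyper: dict):
    h = dict(hyper or {})
    if algorithm_id == "GLM":
        # quadratic-surface logistic regression, effectively unpenalized
        return Pipeline([
            ("scale", StandardScaler()),
            ("poly", PolynomialFeatures(degree=2, include_bias=False)),
            ("clf", LogisticRegression(C=h.get("C", 1000.0), max_iter=5000)),
        ])
    if algorithm_id == "MAXENT":
        # presence-background maximum entropy == regularized logistic
        # regression on linear + quadratic features
        return Pipeline([
            ("scale", StandardScaler()),
            ("poly", PolynomialFeatures(degree=2, include_bias=False)),
            ("clf", LogisticRegression(C=h.get("C", 1.0), max_iter=5000)),
        ])
    if algorithm_id == "GAM":
        return Pipeline([
            ("spline", SplineTransformer(
                n_knots=h.get("n_knots", 6), degree=3, extrapolation="constant")),
            ("clf", LogisticRegression(C=h.get("C", 10.0), max_iter=5000)),
        ])
    if algorithm_id == "MARS":
        return Pipeline([
            ("hinge", HingeBasis()),
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(C=h.get("C", 10.0), max_iter=5000)),
        ])
    if algorithm_id == "FDA":
        return Pipeline([
            ("hinge", HingeBasis()),
            ("clf", LinearDiscriminantAnalysis()),
        ])
    if algorithm_id == "CTA":
        return DecisionTreeClassifier(
            min_samples_leaf=h.get("min_samples_leaf", 10), random_state=seed)
    if algorithm_id == "RF":
        return RandomForestClassifier(
            n_estimators=h.get("n_estimators", 100),
            min_samples_leaf=h.get("min_samples_leaf", 2),
            random_state=seed, n_jobs=1)
    if algorithm_id == "GBM":
        return GradientBoostingClassifier(
            n_estimators=h.get("n_estimators", 100), random_state=seed)
    if algorithm_id == "ANN":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", MLPClassifier(
                hidden_layer_sizes=h.get("hidden_layer_sizes", (8,)),
                alpha=1e-3, max_iter=h.get("max_iter", 800),
                random_state=seed)),
        ])
    if algorithm_id == "SRE":
        return SREModel(tail_quantile=h.get("tail_quantile", DEFAULT_SRE_TAIL))
    raise KeyError(f"unknown algorithm id {algorithm_id!r}")


#: estimators whose fit() accepts sample_weight (directly or via pipeline)
_WEIGHTED = {"GLM", "MAXENT", "GAM", "MARS", "CTA", "RF", "GBM", "SRE"}


@dataclass(frozen=True)
class AlgorithmSpec:
    algorithm_id: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.algorithm_id not in ALGORITHM_IDS:
            raise KeyError(f"unknown algorithm id {self.algorithm_id!r}")


@dataclass
class FittedModel:
    """A fitted learner plus the metadata identifying its run."""

    algorithm_id: str
    estimator: object
    variables: list[str]
    seed: int
    failed: bool = False
    failure_reason: str = ""

    def predict01(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Suitability in [0, 1] for rows of variable values."""
        if isinstance(X, pd.DataFrame):
            X = X[self.variables].to_numpy(dtype=float)
        p = self.estimator.predict_proba(np.asarray(X, dtype=float))[:, 1]
        return np.clip(p, 0.0, 1.0)


def fit_sre(train: TrainingSet, tail_quantile: float = DEFAULT_SRE_TAIL) -> FittedModel:
    """Fit the surface range envelope on the training presences."""
    model = SREModel(tail_quantile=tail_quantile)
    model.fit(train.X[train.variables].to_numpy(dtype=float), train.y)
    return FittedModel("SRE", model, list(train.variables), seed=0)


def fit_model(spec: AlgorithmSpec, train: TrainingSet, seed: int) -> FittedModel:
    """Fit one algorithm; failures are flagged, not raised.

    Case weights are passed to every learner that supports them; a fixed
    seed makes the fit reproducible.
    """
    est = _make_estimator(spec.algorithm_id, seed, spec.hyperparameters)
    X = train.X[train.variables].to_numpy(dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence noise
            if spec.algorithm_id in _WEIGHTED:
                if isinstance(est, Pipeline):
                    est.fit(X, train.y, clf__sample_weight=train.weights)
                else:
                    est.fit(X, train.y, sample_weight=train.weights)
            else:
                est.fit(X, train.y)
    except Exception as exc:  # non-convergence / degenerate input
        log.warning("fit failed for %s: %s", spec.algorithm_id, exc)
        return FittedModel(spec.algorithm_id, None, list(train.variables),
                           seed=seed, failed=True, failure_reason=str(exc))
    return FittedModel(spec.algorithm_id, est, list(train.variables), seed=seed)


def predict_grid(model: FittedModel, stack: GridStack) -> Grid:
    """Predict suitability over every valid cell of the stack.

    NoData in any model variable propagates; output is clipped to [0, 1].
    """
    missing = [v for v in model.variables if v not in stack]
    if missing:
        raise KeyError(f"stack lacks model variables: {missing}")
    mask = stack.combined_mask(model.variables)
    table = stack.table(model.variables, mask=mask)
    p = model.predict01(table[model.variables])
    ref = stack[model.variables[0]]
    out = np.full(stack.shape, ref.nodata, dtype=float)
    rows, cols = np.nonzero(mask)
    out[rows, cols] = p
    return ref.like(out)


def predict_table(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """Predict suitability for a precomputed per-cell variable table."""
    return model.predict01(table)
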