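"""Static machine-learning comparators for dynamic prognosis prediction.

Three conventional classifiers - Gaussian naive Bayes (GNB), random forest
(RF) and a support-vector classifier (SVC) - are trained on first-slice
covariates against fixed-horizon survivorship labels (dead within 6, 12,
24, 36 or 48 months of diagnosis; patients censored before a horizon carry
no label at that horizon). The fitted models can then score the covariate
vector of ANY later slice, which is how a baseline-trained static model is
pressed into dynamic prediction.

RF and SVC hyperparameters are picked from small fixed grids on an internal
seeded 70/30 split; GNB has no tuning. SVC features are standardized and
its risks come from the internally cross-validated Platt calibration, so
all three kinds emit a probability of the dead-by-horizon class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import ConfigurationError, ScoringError
from .timeslice import LandmarkSurvival, SliceTable

#: The eleven baseline features, fixed order.
STATIC_FEATURES = [
    "age", "diameter_mm", "n_lesions", "vascular_invasion",
    "massive_ascites", "mild_moderate_ascites", "afp", "alb", "tbil",
    "pt", "child_pugh_score",
]

HORIZONS = (6, 12, 24, 36, 48)

RF_GRID = [{"n_estimators": n, "max_depth": d}
           for n in (100, 500) for d in (3, 5, None)]
SVC_GRID = [{"C": c} for c in (0.1, 1.0, 10.0)]


def make_labels(ls: LandmarkSurvival, horizon_months: float) -> pd.Series:
    """Dead-by-horizon labels; censored-before-horizon patients are excluded.

    1 = death observed within ``horizon_months`` of the landmark,
    0 = follow-up (event or censoring) extends beyond the horizon.
    """
    t, e = ls.time_from_landmark, ls.event
    known = ((e == 1) & (t <= horizon_months)) | (t >= horizon_months)
    labels = ((e == 1) & (t <= horizon_months)).astype(int)
    return pd.Series(labels[known], index=np.asarray(ls.patient_ids)[known])


class _ConstantModel:
    """Degenerate stand-in when a horizon has a single label class."""

    def __init__(self, prob_dead: float):
        self.prob_dead = float(prob_dead)

    def predict_proba(self, X):
        p = np.full((len(X), 2), [1 - self.prob_dead, self.prob_dead])
        return p


def _build_estimator(kind: str, params: Mapping, seed: int):
    if kind == "GNB":
        return GaussianNB()
    if kind == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    if kind == "SVC":
        # probabilities via internal cross-validated Platt calibration
        return Pipeline([
            ("scale", StandardScaler()),
            ("svc", CalibratedClassifierCV(
                SVC(kernel="rbf", random_state=seed, **params),
                ensemble=False)),
        ])
    raise ConfigurationError(f"unknown static model kind {kind!r}")


def _ranking_scores(kind: str, params: Mapping, seed: int,
                    X_tr, y_tr, X_te) -> np.ndarray:
    """Held-out risk ordering used for hyperparameter selection."""
    if kind == "SVC":
        est = Pipeline([("scale", StandardScaler()),
                        ("svc", SVC(kernel="rbf", random_state=seed,
                                    **params))])
        est.fit(X_tr, y_tr)
        return est.decision_function(X_te)
    est = _build_estimator(kind, params, seed)
    est.fit(X_tr, y_tr)
    return est.predict_proba(X_te)[:, 1]


@dataclass
class StaticModelBundle:
    """Per-horizon fitted classifiers of one kind, plus training metadata."""

    kind: str
    models: dict[float, object] = field(default_factory=dict)
    chosen_params: dict[float, dict] = field(default_factory=dict)
    degenerate: dict[float, bool] = field(default_factory=dict)
    seed: int = 0
    feature_names: tuple[str, ...] = tuple(STATIC_FEATURES)

    def predict_risk(self, features: pd.DataFrame, horizon_months: float) -> pd.Series:
        """Probability of death by the horizon for each feature vector.

        ``features`` may come from any slice; columns must cover the
        training features.
        """
        if horizon_months not in self.models:
            raise ConfigurationError(
                f"{self.kind}: no fitted model for horizon {horizon_months}")
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise ScoringError(f"missing feature column(s): {missing}")
        X = features[list(self.feature_names)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ScoringError("feature matrix contains missing values")
        proba = self.models[horizon_months].predict_proba(X)[:, 1]
        return pd.Series(proba, index=features.index)


def _tune(kind: str, X: np.ndarray, y: np.ndarray, seed: int) -> dict:
    """Pick grid params by held-out AUC on an internal seeded 70/30 split.

    AUC matches the downstream use of these models as risk rankers.
    """
    grid = RF_GRID if kind == "RF" else SVC_GRID
    if len(grid) == 1 or len(np.unique(y)) < 2:
        return dict(grid[0])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.3, random_state=seed, stratify=y)
    if len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2:
        return dict(grid[0])
    best_params, best_auc = None, -np.inf
    for params in grid:
        scores = _ranking_scores(kind, params, seed, X_tr, y_tr, X_te)
        auc = float(roc_auc_score(y_te, scores))
        if auc > best_auc + 1e-12:
            best_params, best_auc = dict(params), auc
    return best_params


def fit_static(
    kind: str,
    features: pd.DataFrame,
    ls: LandmarkSurvival,
    horizons: Sequence[float] = HORIZONS,
    seed: int = 0,
) -> StaticModelBundle:
    """Fit one classifier kind per horizon on first-slice features.

    ``features`` rows are indexed by patient_id and must cover the eleven
    baseline features; labels come from the slice's landmark survival.
    Horizons whose labels collapse to one class get a degenerate constant
    model. Fully seeded: a fixed seed reproduces hyperparameters and
    predictions.
    """
    bundle = StaticModelBundle(kind=kind, seed=seed)
    missing = [c for c in STATIC_FEATURES if c not in features.columns]
    if missing:
        raise ScoringError(f"missing feature column(s): {missing}")
    for horizon in horizons:
        labels = make_labels(ls, horizon)
        labels = labels[labels.index.isin(features.index)]
        X = features.loc[labels.index, STATIC_FEATURES].to_numpy(dtype=float)
        y = labels.to_numpy()
        if len(np.unique(y)) < 2 or not np.ptp(X, axis=0).any():
            # one label class, or no feature varies: nothing to learn
            bundle.models[horizon] = _ConstantModel(y.mean() if len(y) else 0.5)
            bundle.degenerate[horizon] = True
            bundle.chosen_params[horizon] = {}
            continue
        params = {} if kind == "GNB" else _tune(kind, X, y, seed)
        est = _build_estimator(kind, params, seed)
        est.fit(X, y)
        bundle.models[horizon] = est
        bundle.chosen_params[horizon] = params
        bundle.degenerate[horizon] = False
    return bundle


def features_at_slice(table: SliceTable, slice_index: int,
                      ids: Sequence[str] | None = None,
                      feature_names: Sequence[str] = STATIC_FEATURES) -> pd.DataFrame:
    """Extract the static feature matrix from any slice of a slice table."""
    missing = [c for c in feature_names if c not in table.variables]
    if missing:
        raise ScoringError(f"slice table lacks feature column(s): {missing}")
    frame = table.slice_values(slice_index, ids)
    return frame[list(feature_names)]
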