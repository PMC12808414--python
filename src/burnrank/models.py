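"""Tabular baseline models and risk dichotomization.

The aggregate-feature route uses standard scikit-learn estimators behind a
uniform fit/predict surface: logistic regression, linear and quadratic
discriminant analysis and random forests for classification; lasso, ridge,
elastic net and random forests for regression.  Hyperparameters are
searched over small config-defined grids on inner subject-wise folds.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.impute import SimpleImputer
from sklearn.linear_model import ElasticNet, Lasso, LogisticRegression, Ridge
from sklearn.model_selection import GridSearchCV, GroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .config import SMBM_CUTOFFS

CLASSIFIERS = ("logreg", "lda", "qda", "rf")
REGRESSORS = ("lasso", "ridge", "elasticnet", "rf")

DEFAULT_GRIDS: Dict[str, Dict[str, list]] = {
    "logreg": {"model__C": [0.01, 0.1, 1.0, 10.0]},
    "lda": {},
    "qda": {"model__reg_param": [0.0, 0.1, 0.5]},
    "rf_class": {"model__max_depth": [3, 6, None], "model__n_estimators": [100]},
    "lasso": {"model__alpha": [0.001, 0.01, 0.1, 1.0]},
    "ridge": {"model__alpha": [0.1, 1.0, 10.0, 100.0]},
    "elasticnet": {
        "model__alpha": [0.001, 0.01, 0.1, 1.0],
        "model__l1_ratio": [0.2, 0.5, 0.8],
    },
    "rf_reg": {"model__max_depth": [3, 6, None], "model__n_estimators": [100]},
}


def dichotomize(scores, component: str) -> np.ndarray:
    """Binary high-risk labels from subscale scores.

    High risk at or above the instrument cut-off (PF 3.5, CW 2.83, EE 2.75);
    the boundary itself counts as high risk.
    """
    component = component.lower()
    if component not in SMBM_CUTOFFS:
        raise ValueError(f"unknown component {component!r}; expected pf/cw/ee")
    scores = np.asarray(scores, dtype=float)
    return (scores >= SMBM_CUTOFFS[component]).astype(int)


def _base_estimator(name: str, task: str, seed: int):
    if task == "classify":
        return {
            "logreg": LogisticRegression(max_iter=2000),
            "lda": LinearDiscriminantAnalysis(),
            "qda": QuadraticDiscriminantAnalysis(),
            "rf": RandomForestClassifier(random_state=seed),
        }[name]
    return {
        "lasso": Lasso(max_iter=10000),
        "ridge": Ridge(),
        "elasticnet": ElasticNet(max_iter=10000),
        "rf": RandomForestRegressor(random_state=seed),
    }[name]


def fit_tabular_baselines(
    X: np.ndarray,
    y: np.ndarray,
    task: str,
    groups: Optional[np.ndarray] = None,
    n_inner_folds: int = 3,
    seed: int = 0,
    grids: Optional[Dict[str, Dict[str, list]]] = None,
    models: Optional[tuple] = None,
) -> Dict[str, object]:
    """Fit the named estimator family with inner-fold hyperparameter search.

    ``groups`` (participant ids) make the inner search subject-wise; with
    no groups or degenerate targets the default hyperparameters are used.
    Returns a dict name -> fitted estimator exposing predict (and
    predict_proba for classifiers).
    """
    if task not in ("classify", "regress"):
        raise ValueError(f"unknown task {task!r}")
    names = models or (CLASSIFIERS if task == "classify" else REGRESSORS)
    grids = grids or DEFAULT_GRIDS
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    fitted: Dict[str, object] = {}
    for name in names:
        pipe = Pipeline(
            [
                ("impute", SimpleImputer(strategy="median")),
                ("scale", StandardScaler()),
                ("model", _base_estimator(name, task, seed)),
            ]
        )
        grid_key = f"{name}_class" if (name == "rf" and task == "classify") else name
        grid_key = f"{name}_reg" if (name == "rf" and task == "regress") else grid_key
        grid = grids.get(grid_key, {})
        searchable = (
            grid
            and groups is not None
            and len(np.unique(groups)) >= n_inner_folds
            and (task == "regress" or len(np.unique(y)) > 1)
        )
        if searchable:
            cv = GroupKFold(n_splits=n_inner_folds)
            search = GridSearchCV(
                pipe,
                grid,
                cv=cv.split(X, y, groups),
                scoring="roc_auc" if task == "classify" else "neg_mean_absolute_error",
                n_jobs=1,
                error_score=np.nan,
            )
            try:
                search.fit(X, y)
                fitted[name] = search.best_estimator_
                continue
            except ValueError:
                pass  # e.g. single-class inner folds; fall back to defaults
        pipe.fit(X, y)
        fitted[name] = pipe
    return fitted
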