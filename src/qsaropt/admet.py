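"""Phase-3 ADMET property classification.

For each of the five binary endpoints (Caco-2 permeability, CYP3A4
metabolism, hERG cardiotoxicity, HOB oral bioavailability, MN
mutagenicity) the stage:

1. selects 25 descriptors by recursive feature elimination (RFE) with a
   seeded random forest — refit, drop the single least important feature
   by impurity importance, repeat;
2. trains eleven classifier families on the training split over those 25
   descriptors;
3. evaluates each on the test split and keeps the best by F1 (ties:
   higher AUC, then family name order).

Decision threshold is 0.5 on the predicted positive-class score; a score
exactly at the threshold maps to label 1.  No class reweighting is
applied; prevalence is logged instead so imbalance effects stay visible.
A family that fails to fit is recorded and skipped, never fatal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (AdaBoostClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .activity import SplitSpec, split_dataset
from .metrics import ClassificationEval, evaluate_classifier

CLASSIFIER_FAMILIES = (
    "logistic", "naive_bayes", "lda", "decision_tree", "random_forest",
    "adaboost", "gradient_boosting", "svc", "mlp", "xgboost", "lightgbm",
)

RFE_FOREST_PARAMS = {"n_estimators": 100}


def make_classifier(family: str, seed: int):
    """Instantiate one of the eleven classifier families, seeded."""
    if family == "logistic":
        return LogisticRegression(max_iter=2000)
    if family == "naive_bayes":
        return GaussianNB()
    if family == "lda":
        return LinearDiscriminantAnalysis()
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if family == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if family == "svc":
        return SVC(probability=True, random_state=seed)
    if family == "mlp":
        return MLPClassifier(max_iter=800, random_state=seed)
    if family == "xgboost":
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)
    if family == "lightgbm":
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1)
    raise ValueError(f"unknown classifier family {family!r}; "
                     f"expected one of {CLASSIFIER_FAMILIES}")


def positive_scores(model, X: np.ndarray) -> np.ndarray:
    """Positive-class score in [0, 1] for any of the families."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="X does not have valid feature names")
        return model.predict_proba(np.asarray(X, dtype=float))[:, 1]


def rfe_select(X: pd.DataFrame, labels: np.ndarray, n_keep: int, seed: int) -> list[str]:
    """Recursive feature elimination to ``n_keep`` descriptors.

    One feature is dropped per iteration (smallest mean impurity
    decrease under a seeded random forest).  Survivors are returned in
    original column order.  Survivor sets are nested across ``n_keep``
    for a fixed seed, since the elimination path is deterministic.
    """
    if n_keep <= 0:
        raise ValueError(f"n_keep must be positive, got {n_keep}")
    if n_keep > X.shape[1]:
        raise ValueError(f"n_keep = {n_keep} exceeds {X.shape[1]} columns")
    if n_keep == X.shape[1]:
        return list(X.columns)
    base = RandomForestClassifier(random_state=seed, n_jobs=1, **RFE_FOREST_PARAMS)
    rfe = RFE(estimator=base, n_features_to_select=n_keep, step=1)
    rfe.fit(X.to_numpy(dtype=float), np.asarray(labels, dtype=int))
    return [c for c, kept in zip(X.columns, rfe.support_) if kept]


@dataclass
class AdmetSurrogate:
    """Fitted classifier for one ADMET endpoint over its 25 descriptors."""

    property_name: str
    feature_list: list[str]
    best_family: str
    model: object
    threshold: float = 0.5

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return positive_scores(self.model, np.atleast_2d(np.asarray(X, dtype=float)))

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_score(X) >= self.threshold).astype(int)


@dataclass
class AdmetTrainResult:
    surrogate: AdmetSurrogate
    family_evals: dict[str, ClassificationEval]
    failed_families: dict[str, str] = field(default_factory=dict)
    prevalence: float = float("nan")
    split_sizes: tuple[int, int, int] = (0, 0, 0)


def train_admet_property(X: pd.DataFrame, labels: np.ndarray, property_name: str,
                         families=CLASSIFIER_FAMILIES, split: SplitSpec | None = None,
                         seed: int = 0, n_keep: int = 25) -> AdmetTrainResult:
    """Select features and the best classifier family for one endpoint.

    ``X`` is the normalized post-constant-removal descriptor table.  RFE
    runs on the training split only; families are compared on the test
    split.
    """
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError(f"{property_name}: labels must be binary")
    labels = labels.astype(int)
    if len(families) == 0:
        raise ValueError("no classifier families given")
    split = split or SplitSpec()
    tr, te, va = split_dataset(X.shape[0], split)
    n_keep = min(n_keep, X.shape[1])
    features = rfe_select(X.iloc[tr], labels[tr], n_keep, seed)
    Xf = X[features].to_numpy(dtype=float)

    evals: dict[str, ClassificationEval] = {}
    fitted: dict[str, object] = {}
    failed: dict[str, str] = {}
    for fam in families:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = make_classifier(fam, seed)
                model.fit(Xf[tr], labels[tr])
                scores = positive_scores(model, Xf[te])
        except Exception as exc:  # convergence/degenerate-fit failures are non-fatal
            failed[fam] = f"{type(exc).__name__}: {exc}"
            continue
        fitted[fam] = model
        evals[fam] = evaluate_classifier(labels[te], scores)
    if not fitted:
        raise RuntimeError(f"{property_name}: every classifier family failed: {failed}")

    def sort_key(fam: str):
        ev = evals[fam]
        auc = ev.auc if ev.auc is not None else -1.0
        return (-ev.f1, -auc, fam)

    best = min(fitted, key=sort_key)
    surrogate = AdmetSurrogate(property_name=property_name, feature_list=features,
                               best_family=best, model=fitted[best])
    return AdmetTrainResult(surrogate=surrogate, family_evals=evals,
                            failed_families=failed, prevalence=float(labels.mean()),
                            split_sizes=(tr.size, te.size, va.size))


def predict_admet(surrogates: dict[str, AdmetSurrogate], X_test: pd.DataFrame) -> pd.DataFrame:
    """Binary label table (one column per property) for new compounds.

    ``X_test`` must be in the same normalized descriptor space the
    surrogates were trained on and contain every required column.
    """
    out = {}
    for prop, sur in surrogates.items():
        missing = [c for c in sur.feature_list if c not in X_test.columns]
        if missing:
            raise KeyError(f"{prop}: missing descriptor column(s) {missing}")
        out[prop] = sur.predict_label(X_test[sur.feature_list].to_numpy(dtype=float))
    return pd.DataFrame(out, index=X_test.index.copy())
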