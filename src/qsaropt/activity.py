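"""Phase-2 QSAR activity regression.

Trains the ten standard regression families on the selected descriptor
panel, scores them on a held-out test split (8:1:1 train/test/validation),
fuses the top three by simple average, 5:3:2 weighted average, or
stacking, and converts predictions between pIC50 and IC50.

Conventions
-----------
* pIC50 = -log10(IC50 in molar) = 9 - log10(IC50 in nM); the activity
  target is in nM throughout.
* Weighted fusion assigns the weights (0.5, 0.3, 0.2) to the base models
  in descending single-model test R^2 order.
* Stacking trains an intercept-free ordinary-least-squares meta-model on
  k-fold out-of-fold base predictions over the training split, then
  applies it to the base models' test predictions.
* Model ranking uses R^2 (MAPE is excluded: pIC50 values near zero make
  relative error unstable).
* The validation split is never touched by training or fusion-weight
  selection; it is reserved for comparing fusion strategies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from lightgbm import LGBMRegressor
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .metrics import RegressionEval, evaluate_regression

REGRESSION_FAMILIES = (
    "linear", "ridge", "lasso", "elastic_net", "random_forest",
    "lightgbm", "xgboost", "gbdt", "svr", "decision_tree",
)

FUSION_STRATEGIES = ("simple_average", "weighted_average", "stacking")


@dataclass(frozen=True)
class SplitSpec:
    """8:1:1 train/test/validation split with a seeded shuffle."""

    train_frac: float = 0.8
    test_frac: float = 0.1
    val_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_frac + self.test_frac + self.val_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if min(self.train_frac, self.test_frac, self.val_frac) <= 0:
            raise ValueError("all split fractions must be positive")


@dataclass(frozen=True)
class FusionSpec:
    """Which fusion strategy to apply to the top-three base models."""

    strategy: str = "stacking"
    weights: tuple[float, ...] = (0.5, 0.3, 0.2)
    meta_folds: int = 5

    def __post_init__(self) -> None:
        if self.strategy not in FUSION_STRATEGIES:
            raise ValueError(f"unknown fusion strategy {self.strategy!r}")
        if self.strategy == "weighted_average":
            w = np.asarray(self.weights, dtype=float)
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
                raise ValueError("weights must be nonnegative and sum to 1")


def split_dataset(n: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (train, test, validation) index arrays.

    Test and validation sizes are the fractions rounded to the nearest
    integer; the remainder goes to train.  Requires n >= 10.
    """
    if n < 10:
        raise ValueError(f"need at least 10 samples to split 8:1:1, got {n}")
    n_test = int(n * spec.test_frac + 0.5)
    n_val = int(n * spec.val_frac + 0.5)
    n_train = n - n_test - n_val
    if min(n_train, n_test, n_val) < 1:
        raise ValueError("degenerate split: every partition must be non-empty")
    perm = np.random.default_rng(spec.seed).permutation(n)
    return perm[:n_train], perm[n_train:n_train + n_test], perm[n_train + n_test:]


def make_regressor(family: str, seed: int):
    """Instantiate one of the ten regression families with a fixed seed.

    Hyperparameters are library defaults; only seeds and thread counts
    are pinned so fits are reproducible on any machine.
    """
    if family == "linear":
        return LinearRegression()
    if family == "ridge":
        return Ridge(random_state=seed)
    if family == "lasso":
        return Lasso(random_state=seed)
    if family == "elastic_net":
        return ElasticNet(random_state=seed)
    if family == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1)
    if family == "lightgbm":
        return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1)
    if family == "xgboost":
        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0)
    if family == "gbdt":
        return GradientBoostingRegressor(random_state=seed)
    if family == "svr":
        return SVR()
    if family == "decision_tree":
        return DecisionTreeRegressor(random_state=seed)
    raise ValueError(f"unknown regression family {family!r}; "
                     f"expected one of {REGRESSION_FAMILIES}")


def train_family(family: str, X_train: np.ndarray, y_train: np.ndarray, seed: int):
    """Fit one family; the returned handle supports ``predict``."""
    model = make_regressor(family, seed)
    model.fit(np.asarray(X_train, dtype=float), np.asarray(y_train, dtype=float))
    return model


def predict_with(model, X: np.ndarray) -> np.ndarray:
    """Predict on a plain array, muting the cosmetic feature-name warning
    LightGBM's sklearn wrapper raises for unnamed inputs."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="X does not have valid feature names")
        return np.asarray(model.predict(np.asarray(X, dtype=float)))


def simple_average(base_preds: np.ndarray) -> np.ndarray:
    return np.mean(np.asarray(base_preds, dtype=float), axis=0)


def weighted_average(base_preds: np.ndarray, weights) -> np.ndarray:
    base_preds = np.asarray(base_preds, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != base_preds.shape[0]:
        raise ValueError(f"weight vector length {w.shape[0]} does not match "
                         f"{base_preds.shape[0]} base predictions")
    return np.tensordot(w, base_preds, axes=1)


def fit_stacking_meta(oof_preds: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Intercept-free OLS coefficients on out-of-fold base predictions."""
    A = np.asarray(oof_preds, dtype=float).T
    coef, *_ = np.linalg.lstsq(A, np.asarray(y, dtype=float), rcond=None)
    return coef


def fuse_predictions(base_preds: np.ndarray, spec: FusionSpec,
                     oof_preds: np.ndarray | None = None,
                     oof_y: np.ndarray | None = None) -> np.ndarray:
    """Fuse base-model predictions on a target set.

    ``base_preds`` is (n_models, n_samples), ordered by descending base
    R^2 (the weighted strategy relies on this ordering).  Stacking needs
    out-of-fold predictions of the same models on the training split.
    """
    base_preds = np.asarray(base_preds, dtype=float)
    if spec.strategy == "simple_average":
        return simple_average(base_preds)
    if spec.strategy == "weighted_average":
        return weighted_average(base_preds, spec.weights)
    if oof_preds is None or oof_y is None:
        raise ValueError("stacking requires out-of-fold base predictions and targets")
    coef = fit_stacking_meta(oof_preds, oof_y)
    return coef @ base_preds


def oof_base_predictions(families: list[str], X: np.ndarray, y: np.ndarray,
                         seed: int, n_folds: int = 5) -> np.ndarray:
    """K-fold out-of-fold predictions of each family on its training data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    oof = np.zeros((len(families), X.shape[0]))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr_idx, te_idx in kf.split(X):
        for i, fam in enumerate(families):
            model = train_family(fam, X[tr_idx], y[tr_idx], seed)
            oof[i, te_idx] = predict_with(model, X[te_idx])
    return oof


def pic50_to_ic50(pic50: float) -> float:
    """IC50 in nM from pIC50 (= 9 - log10 IC50_nM)."""
    if not math.isfinite(pic50):
        raise ValueError(f"pIC50 must be finite, got {pic50}")
    return 10.0 ** (9.0 - pic50)


def ic50_to_pic50(ic50_nM: float) -> float:
    """pIC50 from IC50 in nM; IC50 must be positive."""
    if not (ic50_nM > 0):
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return 9.0 - math.log10(ic50_nM)


@dataclass
class ActivitySurrogate:
    """Trained activity predictor over a fixed descriptor panel.

    ``predict`` takes a (n, len(feature_list)) array in normalized
    descriptor space, column order matching ``feature_list``.
    """

    feature_list: list[str]
    base_families: list[str]
    base_models: list
    fusion: FusionSpec
    meta_coef: np.ndarray | None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        base = np.vstack([predict_with(m, X) for m in self.base_models])
        if self.fusion.strategy == "simple_average":
            return simple_average(base)
        if self.fusion.strategy == "weighted_average":
            return weighted_average(base, self.fusion.weights)
        return self.meta_coef @ base


@dataclass
class ActivityModelResult:
    surrogate: ActivitySurrogate
    family_evals: dict[str, RegressionEval]          # on the test split
    fusion_evals_val: dict[str, RegressionEval]      # on the validation split
    fusion_eval_test: RegressionEval                 # chosen fusion, test split
    split_sizes: tuple[int, int, int]


def train_activity_model(X: np.ndarray, y: np.ndarray, feature_list: list[str],
                         split: SplitSpec, fusion: FusionSpec, seed: int,
                         families: tuple[str, ...] = REGRESSION_FAMILIES,
                         n_top: int = 3) -> ActivityModelResult:
    """Train all families, fuse the top ``n_top`` by test R^2, evaluate.

    All three fusion strategies are scored on the validation split for
    the run report; the returned surrogate uses the strategy named in
    ``fusion``.  Base models are fit on the train split only, so the
    test- and validation-split evaluations stay honest.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    tr, te, va = split_dataset(X.shape[0], split)
    fitted: dict[str, object] = {}
    evals: dict[str, RegressionEval] = {}
    for fam in families:
        model = train_family(fam, X[tr], y[tr], seed)
        fitted[fam] = model
        evals[fam] = evaluate_regression(y[te], predict_with(model, X[te]))
    ranked = sorted(families, key=lambda f: (-evals[f].r2, f))
    top = ranked[:n_top]
    base_models = [fitted[f] for f in top]
    base_te = np.vstack([predict_with(m, X[te]) for m in base_models])
    base_va = np.vstack([predict_with(m, X[va]) for m in base_models])
    oof = oof_base_predictions(top, X[tr], y[tr], seed, n_folds=fusion.meta_folds)
    meta_coef = fit_stacking_meta(oof, y[tr])

    fusion_evals_val = {}
    for strat in FUSION_STRATEGIES:
        spec = FusionSpec(strategy=strat, weights=fusion.weights,
                          meta_folds=fusion.meta_folds)
        fused_va = fuse_predictions(base_va, spec, oof_preds=oof, oof_y=y[tr])
        fusion_evals_val[strat] = evaluate_regression(y[va], fused_va)

    fused_te = fuse_predictions(base_te, fusion, oof_preds=oof, oof_y=y[tr])
    fusion_eval_test = evaluate_regression(y[te], fused_te)

    surrogate = ActivitySurrogate(
        feature_list=list(feature_list), base_families=top,
        base_models=base_models, fusion=fusion,
        meta_coef=meta_coef if fusion.strategy == "stacking" else None,
    )
    return ActivityModelResult(
        surrogate=surrogate, family_evals=evals,
        fusion_evals_val=fusion_evals_val, fusion_eval_test=fusion_eval_test,
        split_sizes=(tr.size, te.size, va.size),
    )
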