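"""Phase-1 descriptor screen.

Four nested stages reduce the descriptor table to the small panel that
feeds the QSAR activity model:

1. constant-column removal (the raw table carries descriptors whose
   observations are all identical, typically all zero);
2. min-max normalization, x' = (x - x_min) / (x_max - x_min);
3. grey relational analysis (GRA) against the pIC50 reference sequence,
   keeping the top-k descriptors by relational degree;
4. a greedy Spearman redundancy filter at |rho| <= cutoff, scanning in
   GRA order so the member of a correlated pair with the stronger
   activity association is kept;
5. Shapley-attribution ranking of the survivors under a seeded random
   forest, keeping the top-k by mean |attribution|.

GRA scores similarity of curve shapes: with reference sequence y(k) and
candidate x_i(k), the relational coefficient at point k is
``xi_i(k) = (a + alpha*b) / (|y(k) - x_i(k)| + alpha*b)`` where a and b
are the global min and max of |y(k) - x_i(k)| over all candidates and
points and alpha (default 0.5) is the resolution coefficient; the
relational degree r_i is the mean of xi_i over points.  The reference is
min-max normalized with the same formula as the descriptors so the
absolute differences are commensurate.

Ties anywhere are broken by descending score then ascending name, so
reports are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestRegressor

from ._treeshap import shap_values

#: Hyperparameters of the forest behind the Shapley ranking stage.  Kept
#: moderate (200 trees, depth 10, sqrt feature subsampling) — the ranking
#: stabilizes well before the forest does, and attributions are computed
#: on a bounded row subsample.
SHAP_FOREST_PARAMS = {"n_estimators": 200, "max_depth": 10, "max_features": "sqrt"}
SHAP_MAX_SAMPLES = 100


@dataclass
class NormalizationParams:
    """Per-descriptor min/max retained for later de-normalization."""

    x_min: pd.Series
    x_max: pd.Series

    def denormalize(self, names: list[str], values: np.ndarray) -> np.ndarray:
        lo = self.x_min[names].to_numpy(dtype=float)
        hi = self.x_max[names].to_numpy(dtype=float)
        return lo + np.asarray(values, dtype=float) * (hi - lo)


@dataclass
class GraResult:
    """Grey relational degrees plus the global difference extremes a, b."""

    degrees: pd.Series
    a: float
    b: float


@dataclass
class SelectionReport:
    """What each screening stage removed and kept, with scores."""

    removed_zero_variance: list[str]
    gra_top: list[str]
    gra_degrees: dict[str, float]
    retained_after_spearman: list[str]
    shap_top: list[str]
    shap_scores: dict[str, float]
    thresholds: dict = field(default_factory=dict)

    def validate_nesting(self) -> None:
        if not set(self.shap_top) <= set(self.retained_after_spearman):
            raise AssertionError("shap_top not nested in retained_after_spearman")
        if not set(self.retained_after_spearman) <= set(self.gra_top):
            raise AssertionError("retained_after_spearman not nested in gra_top")

    def to_frame(self) -> pd.DataFrame:
        """Per-descriptor stage-reached summary (selection audit trail)."""
        rows = []
        spearman = set(self.retained_after_spearman)
        shap_set = set(self.shap_top)
        for name in self.gra_top:
            stage = "gra"
            if name in spearman:
                stage = "spearman"
            if name in shap_set:
                stage = "shap"
            rows.append({
                "descriptor": name, "stage_reached": stage,
                "gra_degree": self.gra_degrees.get(name),
                "mean_abs_shap": self.shap_scores.get(name),
            })
        for name in self.removed_zero_variance:
            rows.append({"descriptor": name, "stage_reached": "removed_constant",
                         "gra_degree": None, "mean_abs_shap": None})
        return pd.DataFrame(rows)

    def as_dict(self) -> dict:
        return {
            "removed_zero_variance": self.removed_zero_variance,
            "gra_top": self.gra_top,
            "gra_degrees": self.gra_degrees,
            "retained_after_spearman": self.retained_after_spearman,
            "shap_top": self.shap_top,
            "shap_scores": self.shap_scores,
            "thresholds": self.thresholds,
        }


def drop_zero_variance(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove columns whose values are all identical.

    The removal rule is exact equality of every value (all-zero columns
    are the common case), not a variance epsilon.  Column order is
    preserved.  Raises if nothing survives.
    """
    values = table.to_numpy()
    constant = (values == values[0:1, :]).all(axis=0)
    removed = [c for c, is_const in zip(table.columns, constant) if is_const]
    kept = table.loc[:, ~constant]
    if kept.shape[1] == 0:
        raise ValueError("all descriptor columns are constant; nothing to select from")
    return kept, removed


def minmax_normalize(table: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationParams]:
    """Scale every column to [0, 1] via (x - x_min) / (x_max - x_min)."""
    x_min = table.min(axis=0)
    x_max = table.max(axis=0)
    constant = x_max <= x_min
    if constant.any():
        bad = list(table.columns[constant])
        raise ValueError(f"constant column(s) cannot be normalized: {bad}; "
                         "run drop_zero_variance first")
    norm = (table - x_min) / (x_max - x_min)
    return norm, NormalizationParams(x_min=x_min.astype(float), x_max=x_max.astype(float))


def normalize_reference(y: np.ndarray) -> np.ndarray:
    """Min-max normalize the GRA reference sequence (same formula)."""
    y = np.asarray(y, dtype=float)
    lo, hi = y.min(), y.max()
    if hi <= lo:
        raise ValueError("reference sequence is constant")
    return (y - lo) / (hi - lo)


def grey_relational_degree(X: pd.DataFrame, y: np.ndarray, alpha: float = 0.5) -> GraResult:
    """Grey relational degree of every descriptor column against y.

    ``X`` must be normalized to [0, 1] and ``y`` must be the normalized
    reference with one value per row of ``X``.  If every descriptor is
    identical to the reference (b = 0) all degrees are 1, with a warning.
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    y = np.asarray(y, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("reference length does not match table rows")
    diffs = np.abs(X.to_numpy(dtype=float) - y[:, None])
    a = float(diffs.min())
    b = float(diffs.max())
    if b == 0.0:
        warnings.warn("all descriptor sequences identical to the reference; "
                      "grey relational degrees degenerate to 1", stacklevel=2)
        degrees = pd.Series(1.0, index=X.columns)
        return GraResult(degrees=degrees, a=a, b=b)
    xi = (a + alpha * b) / (diffs + alpha * b)
    degrees = pd.Series(xi.mean(axis=0), index=X.columns)
    return GraResult(degrees=degrees, a=a, b=b)


def select_top_k_gra(result: GraResult, k: int) -> list[str]:
    """Names of the k largest relational degrees, descending.

    Ties broken by ascending name; k larger than the table returns the
    full ranking.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    order = sorted(result.degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in order[:k]]


def spearman_filter(X: pd.DataFrame, priority: list[str], cutoff: float) -> list[str]:
    """Greedy redundancy filter on Spearman rank correlation.

    Scans candidates in ``priority`` order; a candidate is retained iff
    its |rho| against every already-retained descriptor is <= cutoff.
    rho is the Pearson product-moment correlation of average-tie ranks.
    """
    if not (0 < cutoff < 1):
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    missing = [c for c in priority if c not in X.columns]
    if missing:
        raise KeyError(f"priority names not in table: {missing}")
    ranks = np.column_stack([rankdata(X[c].to_numpy(), method="average") for c in priority])
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.atleast_2d(rho)
    retained_idx: list[int] = []
    for i in range(len(priority)):
        if all(abs(rho[i, j]) <= cutoff for j in retained_idx):
            retained_idx.append(i)
    return [priority[i] for i in retained_idx]


def shap_top_k(X: pd.DataFrame, y: np.ndarray, k: int, seed: int,
               forest_params: dict | None = None,
               max_samples: int = SHAP_MAX_SAMPLES) -> tuple[list[str], pd.Series]:
    """Rank descriptors by mean |Shapley attribution| under a random forest.

    Fits a seeded ``RandomForestRegressor`` on all rows, computes exact
    path-dependent tree-Shapley attributions on a seeded subsample of at
    most ``max_samples`` rows, and returns the top-k descriptor names
    (descending mean absolute attribution, ties by name) together with
    the full score series.
    """
    if k < 1 or k > X.shape[1]:
        raise ValueError(f"k must be in [1, {X.shape[1]}], got {k}")
    params = dict(SHAP_FOREST_PARAMS if forest_params is None else forest_params)
    model = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    model.fit(X.to_numpy(dtype=float), np.asarray(y, dtype=float))
    n = X.shape[0]
    if n > max_samples:
        idx = np.random.default_rng(seed).choice(n, size=max_samples, replace=False)
        sample = X.to_numpy(dtype=float)[np.sort(idx)]
    else:
        sample = X.to_numpy(dtype=float)
    phi, _ = shap_values(model, sample)
    scores = pd.Series(np.abs(phi).mean(axis=0), index=X.columns)
    order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [name for name, _ in order[:k]]
    return top, scores


def run_selection(descriptors: pd.DataFrame, pic50: np.ndarray, *,
                  gra_k: int = 200, spearman_cut: float = 0.85, shap_k: int = 20,
                  alpha: float = 0.5, seed: int = 0,
                  ) -> tuple[SelectionReport, pd.DataFrame, NormalizationParams]:
    """Run the full phase-1 screen; returns (report, normalized table, params).

    The returned table is the normalized post-constant-removal table (all
    columns), from which callers take the selected panels by name.
    """
    live, removed = drop_zero_variance(descriptors)
    norm, params = minmax_normalize(live)
    y_ref = normalize_reference(np.asarray(pic50, dtype=float))
    gra = grey_relational_degree(norm, y_ref, alpha=alpha)
    gra_top = select_top_k_gra(gra, min(gra_k, norm.shape[1]))
    retained = spearman_filter(norm, gra_top, spearman_cut)
    k = min(shap_k, len(retained))
    shap_top, shap_scores = shap_top_k(norm[retained], pic50, k, seed)
    report = SelectionReport(
        removed_zero_variance=removed,
        gra_top=gra_top,
        gra_degrees={n: float(gra.degrees[n]) for n in gra_top},
        retained_after_spearman=retained,
        shap_top=shap_top,
        shap_scores={n: float(s) for n, s in shap_scores.items()},
        thresholds={"gra_k": gra_k, "spearman_cut": spearman_cut, "shap_k": shap_k,
                    "alpha": alpha, "seed": seed,
                    "shap_forest": dict(SHAP_FOREST_PARAMS)},
    )
    report.validate_nesting()
    return report, norm, params
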