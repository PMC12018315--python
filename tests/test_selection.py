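"""Phase-1 screen: constant removal, normalization, GRA, Spearman, Shapley."""

import numpy as np
import pandas as pd
import pytest

from qsaropt.selection import (GraResult, drop_zero_variance, grey_relational_degree,
                               minmax_normalize, normalize_reference, run_selection,
                               select_top_k_gra, shap_top_k, spearman_filter)


def gra_literal(X: pd.DataFrame, y: np.ndarray, alpha: float) -> pd.Series:
    """Test-only literal transcription of the relational coefficient/degree
    formulas, looping over descriptors i and points k."""
    cols = list(X.columns)
    n = len(y)
    diffs = {c: [abs(y[k] - X[c].iloc[k]) for k in range(n)] for c in cols}
    flat = [d for c in cols for d in diffs[c]]
    a, b = min(flat), max(flat)
    degrees = {}
    for c in cols:
        xi = [(a + alpha * b) / (diffs[c][k] + alpha * b) for k in range(n)]
        degrees[c] = sum(xi) / n
    return pd.Series(degrees)


class TestDropZeroVariance:
    def test_default_synthetic_counts(self, small_dataset):
        kept, removed = drop_zero_variance(small_dataset.descriptors)
        assert len(removed) == small_dataset.config.n_zero_cols
        assert kept.shape[1] == 120 - 37

    def test_no_constant_columns_is_identity(self):
        df = pd.DataFrame({"a": [1, 2, 3], "b": [0.5, 0.1, 0.9]})
        kept, removed = drop_zero_variance(df)
        assert removed == [] and kept.equals(df)

    def test_all_sevens_column_removed(self):
        df = pd.DataFrame({"a": [1, 2, 3], "b": [7, 7, 7], "c": [0, 1, 0]})
        kept, removed = drop_zero_variance(df)
        assert removed == ["b"] and list(kept.columns) == ["a", "c"]

    def test_all_constant_raises(self):
        with pytest.raises(ValueError):
            drop_zero_variance(pd.DataFrame({"a": [0, 0], "b": [3, 3]}))


class TestMinmaxNormalize:
    @pytest.mark.parametrize("col, expected", [
        ([2, 4, 6], [0.0, 0.5, 1.0]),
        ([0.0, 0.25, 1.0], [0.0, 0.25, 1.0]),
        ([-1.0, 0.0, 3.0], [0.0, 0.25, 1.0]),
    ])
    def test_hand_cases(self, col, expected):
        norm, params = minmax_normalize(pd.DataFrame({"x": col}))
        assert np.allclose(norm["x"], expected)

    def test_bounds_and_denormalization(self, small_dataset):
        kept, _ = drop_zero_variance(small_dataset.descriptors)
        norm, params = minmax_normalize(kept)
        assert float(norm.min().min()) >= 0.0 and float(norm.max().max()) <= 1.0
        name = kept.columns[3]
        back = params.denormalize([name], norm[name].to_numpy())
        assert np.allclose(back, kept[name], atol=1e-9)

    def test_constant_column_error_names_column(self):
        with pytest.raises(ValueError, match="bad"):
            minmax_normalize(pd.DataFrame({"ok": [1, 2], "bad": [5, 5]}))


class TestGreyRelational:
    def test_hand_example(self):
        X = pd.DataFrame({"x1": [0.0, 0.5, 1.0], "x2": [1.0, 0.5, 0.0]})
        y = np.array([0.0, 0.5, 1.0])
        res = grey_relational_degree(X, y, alpha=0.5)
        assert res.a == 0.0 and res.b == 1.0
        assert res.degrees["x1"] == pytest.approx(1.0)
        assert res.degrees["x2"] == pytest.approx(5.0 / 9.0, abs=1e-12)

    def test_self_match_has_unit_degree(self, rng):
        y = rng.uniform(size=8)
        X = pd.DataFrame({"same": y, "other": rng.uniform(size=8)})
        res = grey_relational_degree(X, y)
        assert res.degrees["same"] == pytest.approx(1.0)
        assert res.degrees["other"] < 1.0

    def test_coefficient_lower_bound_when_a_zero(self, rng):
        # with a = 0 and alpha = 0.5 each coefficient is >= 1/3, so degrees are too
        y = rng.uniform(size=10)
        X = pd.DataFrame({f"c{i}": rng.uniform(size=10) for i in range(4)})
        X["exact"] = y  # forces a = 0
        res = grey_relational_degree(X, y, alpha=0.5)
        assert (res.degrees >= 1.0 / 3.0 - 1e-12).all()
        assert (res.degrees <= 1.0).all()

    def test_matches_literal_transcription_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 7))
            p = int(rng.integers(1, 6))
            X = pd.DataFrame(rng.uniform(size=(n, p)),
                             columns=[f"d{j}" for j in range(p)])
            y = rng.uniform(size=n)
            alpha = float(rng.uniform(0.1, 1.0))
            fast = grey_relational_degree(X, y, alpha=alpha).degrees
            slow = gra_literal(X, y, alpha)
            assert np.allclose(fast[slow.index], slow, atol=1e-12)

    def test_degenerate_reference_warns_and_returns_ones(self):
        y = np.array([0.1, 0.9])
        X = pd.DataFrame({"a": y, "b": y})
        with pytest.warns(UserWarning):
            res = grey_relational_degree(X, y)
        assert (res.degrees == 1.0).all()


class TestTopK:
    def test_rank_and_ties(self):
        res = GraResult(degrees=pd.Series({"A": 0.9, "B": 0.7, "C": 0.8}), a=0, b=1)
        assert select_top_k_gra(res, 2) == ["A", "C"]
        assert select_top_k_gra(res, 10) == ["A", "C", "B"]
        tied = GraResult(degrees=pd.Series({"B": 0.5, "A": 0.5}), a=0, b=1)
        assert select_top_k_gra(tied, 1) == ["A"]


class TestSpearmanFilter:
    def test_monotone_transform_pair_keeps_higher_priority(self, rng):
        x = rng.uniform(size=40)
        X = pd.DataFrame({"f1": x, "f2": np.exp(3 * x)})
        assert spearman_filter(X, ["f1", "f2"], 0.85) == ["f1"]
        assert spearman_filter(X, ["f2", "f1"], 0.85) == ["f2"]

    def test_independent_columns_all_retained(self, rng):
        from scipy.stats import spearmanr
        X = pd.DataFrame(rng.uniform(size=(200, 3)), columns=["a", "b", "c"])
        rho = spearmanr(X.to_numpy()).statistic
        assert np.abs(rho[np.triu_indices(3, 1)]).max() < 0.3  # fixture sanity
        assert spearman_filter(X, ["a", "b", "c"], 0.3) == ["a", "b", "c"]

    def test_greedy_trace(self, rng):
        # f2 rank-correlates with f1 above the cutoff, f3 with neither
        from scipy.stats import spearmanr
        n = 200
        x = rng.uniform(size=n)
        ranks = np.argsort(np.argsort(x))
        jit = np.argsort(np.argsort(ranks + rng.uniform(0, 0.25 * n, n)))
        X = pd.DataFrame({"f1": x, "f2": np.sort(x)[jit], "f3": rng.uniform(size=n)})
        rho = spearmanr(X.to_numpy()).statistic
        assert abs(rho[0, 1]) > 0.85 and abs(rho[0, 2]) < 0.3 and abs(rho[1, 2]) < 0.3
        assert spearman_filter(X, ["f1", "f2", "f3"], 0.85) == ["f1", "f3"]

    def test_output_pairwise_correlation_bounded(self, small_dataset):
        from scipy.stats import spearmanr
        kept, _ = drop_zero_variance(small_dataset.descriptors)
        norm, _ = minmax_normalize(kept)
        y = normalize_reference(small_dataset.activity["pIC50"].to_numpy())
        top = select_top_k_gra(grey_relational_degree(norm, y), 60)
        retained = spearman_filter(norm, top, 0.85)
        rho = spearmanr(norm[retained].to_numpy()).statistic
        np.fill_diagonal(rho, 0.0)
        assert np.abs(rho).max() <= 0.85 + 1e-12


class TestShapTopK:
    def test_signal_outranks_noise_across_seeds(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame({
                "signal": rng.uniform(size=150),
                "noise1": rng.uniform(size=150),
                "noise2": rng.uniform(size=150),
            })
            y = 2.0 * X["signal"].to_numpy() + rng.normal(0, 0.2, 150)
            top, scores = shap_top_k(X, y, k=3, seed=seed)
            wins += top[0] == "signal"
        assert wins >= 19  # >= 95% of 20 repeats

    def test_full_ranking_when_k_equals_columns(self, rng):
        X = pd.DataFrame(rng.uniform(size=(80, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() + rng.normal(0, 0.1, 80)
        top, scores = shap_top_k(X, y, k=4, seed=0)
        assert sorted(top) == list("abcd")
        assert len(scores) == 4

    def test_k_out_of_range(self, rng):
        X = pd.DataFrame(rng.uniform(size=(30, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            shap_top_k(X, np.zeros(30), k=3, seed=0)


class TestRunSelection:
    def test_nesting_and_report(self, small_dataset):
        report, norm, params = run_selection(
            small_dataset.descriptors, small_dataset.activity["pIC50"].to_numpy(),
            gra_k=60, shap_k=20, seed=7)
        assert set(report.shap_top) <= set(report.retained_after_spearman)
        assert set(report.retained_after_spearman) <= set(report.gra_top)
        assert len(report.shap_top) == 20
        frame = report.to_frame()
        assert set(frame["stage_reached"]) <= {"gra", "spearman", "shap", "removed_constant"}
        assert (frame["stage_reached"] == "shap").sum() == 20
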