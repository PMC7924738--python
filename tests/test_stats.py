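import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from twbio.datasets import TW_IDS, load_characterization, load_elements
from twbio.stats import (
    aicc,
    benjamini_hochberg,
    fit_time_models,
    metric_screen,
    pca,
    spearman,
)


def brute_force_permutation_p(x, y):
    """Independent oracle: enumerate permutations, score each with scipy."""
    obs = abs(sps.spearmanr(x, y).statistic)
    y = np.asarray(y, float)
    hits = 0
    total = 0
    for perm in itertools.permutations(range(len(y))):
        r = sps.spearmanr(x, y[list(perm)]).statistic
        if abs(r) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestSpearman:
    def test_monotone_increasing(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).rho == pytest.approx(-1.0)

    def test_midrank_ties_hand_value(self):
        res = spearman([1, 2, 2, 3], [1, 2, 3, 4])
        assert res.rho == pytest.approx(0.9487, abs=1e-4)

    def test_perfect_rank_exact_p_at_n7(self):
        # only the identity and the full reversal reach |rho| = 1
        res = spearman(np.arange(7), np.arange(7) ** 3)
        assert res.p_value == pytest.approx(2 / 5040)
        assert res.method == "exact-permutation"

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        res = spearman(x, y)
        assert res.p_value == pytest.approx(brute_force_permutation_p(x, y))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        base = spearman(x, y)
        warped = spearman(np.exp(x), y**3)
        assert warped.rho == pytest.approx(base.rho)
        assert warped.p_value == pytest.approx(base.p_value)

    def test_na_pairs_dropped(self):
        res = spearman([1, 2, np.nan, 4, 5], [2, 4, 6, 8, np.nan])
        assert res.n == 3

    def test_zero_variance_flagged(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(res.rho)
        assert "zero variance" in res.method


class TestPCA:
    def test_duplicated_variable_pc1_explains_all(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=10)
        table = pd.DataFrame({"a": v, "b": 2 * v + 1})
        res = pca(table)
        assert res.variance_explained[0] == pytest.approx(100.0)

    def test_variance_conservation_and_orthonormality(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.normal(size=(9, 5)),
                             columns=list("abcde"))
        res = pca(table)
        assert res.variance_explained.sum() == pytest.approx(100.0)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame({"a": rng.normal(size=6),
                              "b": rng.normal(size=6),
                              "c": np.ones(6)})
        with pytest.warns(UserWarning, match="constant"):
            res = pca(table)
        assert "c" not in res.loadings.index

    def test_characterization_fixture_majority_in_two_components(self):
        ch = load_characterization().loc[list(TW_IDS)]
        el = load_elements().loc[list(TW_IDS)]
        table = pd.concat(
            [ch[["cod", "scod", "turbidity", "colour_index", "tss",
                 "tn_n", "nh4_n", "po4_p"]],
             el[["Mg", "Ca", "Na", "Si", "Fe", "Zn", "Cr", "Ni"]]],
            axis=1,
        )
        res = pca(table)
        assert res.variance_explained[:2].sum() > 50.0


class TestAicc:
    def test_formula_hand_value(self):
        # n=10, sse=2.5, k=3: 10*ln(0.25) + 6 + 24/6
        assert aicc(2.5, 10, 3) == pytest.approx(10 * math.log(0.25) + 6 + 4)

    def test_overfit_rejected(self):
        with pytest.raises(ValueError, match="residual"):
            aicc(1.0, 5, 4)


def simulate_trend_data(seed, interaction_strength, noise_sd=2.0):
    """Seven cultures, five sampling times, second-order time trend with
    an optional covariate-by-time interaction."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(7):
        x = rng.uniform(0.0, 1.0)
        y_tw = rng.uniform(50.0, 100.0)
        for t in (0.0, 3.75, 7.5, 11.25, 15.0):
            tc = (t - 7.5) / 5.0
            y = (y_tw + 10 * tc + 3 * tc**2
                 + interaction_strength * (8 * tc + 4 * tc**2) * x
                 + rng.normal(0.0, noise_sd))
            rows.append({"y": y, "time": t, "sample": f"S{i}", "y_tw": y_tw,
                         "x": x})
    return pd.DataFrame(rows)


class TestFitTimeModels:
    def test_strong_interaction_selects_covariate_model(self):
        table = fit_time_models(simulate_trend_data(0, 1.0))
        assert table.loc["TW x", "relevant"]
        assert table.loc["Time", "delta_aicc"] > 4

    def test_pure_time_data_keeps_time_model(self):
        table = fit_time_models(simulate_trend_data(1, 0.0))
        assert table.loc["Time", "delta_aicc"] <= 4

    def test_covariate_rescaling_leaves_verdicts(self):
        data = simulate_trend_data(2, 1.0)
        t1 = fit_time_models(data)
        data2 = data.assign(x=5.0 * data["x"] - 3.0)
        t2 = fit_time_models(data2)
        assert np.allclose(t1["aicc"].astype(float), t2["aicc"].astype(float))
        assert (t1["relevant"] == t2["relevant"]).all()

    def test_equivalent_parameterizations_same_sse(self):
        # shifting time rescales the centered basis but spans the same
        # column space: SSE and AICc are invariant
        data = simulate_trend_data(3, 0.5)
        t1 = fit_time_models(data)
        t2 = fit_time_models(data.assign(time=data["time"] + 100.0))
        assert np.allclose(t1["sse"].astype(float), t2["sse"].astype(float))
        assert np.allclose(t1["aicc"].astype(float), t2["aicc"].astype(float))

    def test_delta_of_best_is_zero(self):
        table = fit_time_models(simulate_trend_data(4, 1.0))
        assert table["delta_aicc"].min() == pytest.approx(0.0)


class TestMetricScreen:
    def test_cardinality(self):
        rng = np.random.default_rng(0)
        idx = [f"TW{i}" for i in range(1, 8)]
        metrics = pd.DataFrame(rng.normal(size=(7, 4)), index=idx,
                               columns=list("ABCD"))
        chars = pd.DataFrame(rng.normal(size=(7, 14)), index=idx,
                             columns=[f"c{i}" for i in range(14)])
        out = metric_screen(metrics, chars)
        assert len(out) == 56
        assert (out["n"] <= 7).all()

    def test_duplicated_metric_perfect_rho(self):
        rng = np.random.default_rng(1)
        idx = list("abcdefg")
        v = rng.normal(size=7)
        out = metric_screen(pd.DataFrame({"m": v}, index=idx),
                            pd.DataFrame({"m_copy": v}, index=idx))
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_sparse_pair_skipped(self):
        idx = list("abcdefg")
        m = pd.DataFrame({"m": [1, 2, np.nan, np.nan, np.nan, np.nan, np.nan]},
                         index=idx)
        c = pd.DataFrame({"c": np.arange(7.0)}, index=idx)
        out = metric_screen(m, c)
        assert out.loc[0, "method"].startswith("skipped")

    def test_bh_adjustment_available_but_optional(self):
        q = benjamini_hochberg([0.01, 0.02, 0.5])
        assert q[0] <= q[2]
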