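import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from icrsim.stats import (anova_tukey, backward_regression,
                          contribution_decomposition, spearman_matrix)


def design_fixture(n=60, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "horizontal": rng.uniform(0.2, 0.6, n),
        "vertical": rng.uniform(0.15, 0.6, n),
        "diameter": rng.choice([5.0, 5.5, 6.0], n),
    })
    df["delta_k_mean"] = -12.0 * df["vertical"] + noise * rng.standard_normal(n)
    df["delta_axial_length"] = rng.standard_normal(n)
    df["delta_cct"] = -20.0 * df["vertical"] + 0.5 * rng.standard_normal(n)
    df["max_contact_pressure"] = 300 * df["vertical"] + 50 * rng.standard_normal(n)
    return df


class TestSpearman:
    def test_perfect_monotone(self):
        df = design_fixture()
        df["delta_k_mean"] = df["vertical"]
        out = spearman_matrix(df)
        row = out[(out.outcome == "delta_k_mean") & (out.predictor == "vertical")]
        assert row["rho"].iloc[0] == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_map(self):
        df = design_fixture()
        df["delta_k_mean"] = np.exp(-df["vertical"])
        out = spearman_matrix(df)
        row = out[(out.outcome == "delta_k_mean") & (out.predictor == "vertical")]
        assert row["rho"].iloc[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self):
        """Brute-force oracle: average-rank transform followed by Pearson."""
        df = design_fixture(n=20, seed=3)
        out = spearman_matrix(df)
        for _, row in out.iterrows():
            x = sps.rankdata(df[row["predictor"]])
            y = sps.rankdata(df[row["outcome"]])
            rho_ref = np.corrcoef(x, y)[0, 1]
            assert row["rho"] == pytest.approx(rho_ref, abs=1e-12)

    def test_requires_ten_rows(self):
        with pytest.raises(ValueError):
            spearman_matrix(design_fixture(n=9))


class TestAnovaTukey:
    def test_f_statistic_matches_hand_computation(self):
        df = pd.DataFrame({
            "cat": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
            "y": [1.0, 2, 3, 2, 5, 6, 5, 6, 9, 8, 9, 10],
        })
        res = anova_tukey(df, "cat", "y")
        groups = [g["y"].to_numpy() for _, g in df.groupby("cat")]
        gm = np.concatenate(groups).mean()
        ssb = sum(len(g) * (g.mean() - gm) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F_ref = (ssb / 2) / (ssw / 9)
        assert res["F"].iloc[0] == pytest.approx(F_ref, rel=1e-12)

    def test_two_groups_tukey_equals_pooled_t(self):
        """With two groups the studentized-range p-value collapses to the
        two-sample pooled-t p-value (q = t sqrt(2))."""
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"cat": ["a"] * 8 + ["b"] * 8,
                           "y": np.r_[rng.normal(0, 1, 8), rng.normal(1, 1, 8)]})
        res = anova_tukey(df, "cat", "y")
        t, p_ref = sps.ttest_ind(df[df.cat == "a"].y, df[df.cat == "b"].y)
        assert res["tukey_p"].iloc[0] == pytest.approx(p_ref, abs=1e-7)

    def test_degenerate_zero_variance_flagged(self):
        df = pd.DataFrame({"cat": ["a"] * 3 + ["b"] * 3, "y": [1.0] * 6})
        res = anova_tukey(df, "cat", "y")
        assert res["degenerate"].iloc[0]

    def test_empty_cell_rejected(self):
        df = pd.DataFrame({"cat": ["a", "a", "b"], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="cell"):
            anova_tukey(df, "cat", "y")

    def test_within_stratification(self):
        df = design_fixture(n=90, seed=7)
        df["category"] = np.repeat(["h", "r", "s"], 30)
        res = anova_tukey(df, "diameter", "delta_k_mean", within="category")
        assert set(res["stratum"]) == {"h", "r", "s"}


class TestBackwardRegression:
    def test_planted_single_predictor(self):
        df = design_fixture(seed=11)
        rng = np.random.default_rng(1)
        df["y"] = 2.0 * df["vertical"] + 1e-8 * rng.standard_normal(len(df))
        res = backward_regression(df, "y")
        assert res.kept == ["vertical"]
        assert res.params["vertical"] == pytest.approx(2.0, rel=1e-5)

    def test_orthogonal_predictors_unit_vif(self):
        n = 32
        df = pd.DataFrame({
            "horizontal": np.tile([0.0, 1.0], n // 2),
            "vertical": np.repeat([0.0, 1.0], n // 2),
        })
        df["diameter"] = np.tile([0.0, 1.0, 1.0, 0.0], n // 4)
        df["y"] = np.arange(n, dtype=float)
        res = backward_regression(df, "y")
        for v in res.vif.values():
            assert v == pytest.approx(1.0, abs=1e-9)

    def test_vif_matches_auxiliary_regressions(self):
        import statsmodels.api as sm
        df = design_fixture(seed=21)
        df["horizontal"] = 0.5 * df["vertical"] + 0.1 * np.random.default_rng(2).standard_normal(len(df))
        res = backward_regression(df, "delta_k_mean")
        for j in ("horizontal", "vertical", "diameter"):
            others = [p for p in ("horizontal", "vertical", "diameter") if p != j]
            r2 = sm.OLS(df[j], sm.add_constant(df[others])).fit().rsquared
            assert res.vif[j] == pytest.approx(1.0 / (1.0 - r2), rel=1e-9)

    def test_collinear_predictor_excluded(self):
        df = design_fixture(seed=31)
        df["horizontal"] = df["vertical"] * 2.0 + 1e-9
        res = backward_regression(df, "delta_k_mean")
        assert res.excluded_by_vif


class TestContributionDecomposition:
    def test_planted_single_factor(self):
        df = design_fixture(seed=41, noise=1e-6)
        rep = contribution_decomposition(df, "delta_k_mean")
        assert rep.shares["vertical"] > 0.98
        assert rep.shares["design"] < 0.02

    def test_pure_noise_goes_to_design(self):
        df = design_fixture(seed=43)
        rep = contribution_decomposition(df, "delta_axial_length")
        assert rep.shares["design"] > 0.9

    def test_shares_sum_to_one_nonnegative(self):
        df = design_fixture(seed=47, noise=3.0)
        for outcome in ("delta_k_mean", "max_contact_pressure"):
            rep = contribution_decomposition(df, outcome)
            assert sum(rep.shares.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(v >= 0 for v in rep.shares.values())

    def test_matches_explicit_ordering_enumeration(self):
        """Independent oracle: enumerate all 6 predictor orderings and
        average the clipped adjusted-R^2 gains by hand."""
        import statsmodels.api as sm

        df = design_fixture(seed=53, noise=2.0)
        outcome = "delta_k_mean"
        preds = ["horizontal", "vertical", "diameter"]

        def r2adj(subset):
            if not subset:
                return 0.0
            X = sm.add_constant(df[list(subset)])
            return sm.OLS(df[outcome], X).fit().rsquared_adj

        gains = {p: [] for p in preds}
        for order in itertools.permutations(preds):
            best = 0.0
            for k, p in enumerate(order):
                now = r2adj(order[:k + 1])
                gains[p].append(max(0.0, now - best))
                best = max(best, now)
        raw = {p: np.mean(v) for p, v in gains.items()}
        full = max(0.0, r2adj(preds))
        scale = full / sum(raw.values())
        expected = {p: v * scale for p, v in raw.items()}
        expected["design"] = 1.0 - full
        total = sum(expected.values())
        expected = {k: v / total for k, v in expected.items()}

        rep = contribution_decomposition(df, outcome)
        for k, v in expected.items():
            assert rep.shares[k] == pytest.approx(v, abs=1e-10)
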