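"""PGLS regression, slope-heterogeneity ANCOVA and residual group tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from turbicomp import comparative
from turbicomp.evomodels import simulate_bm
from turbicomp.phylo import phylo_covariance, pure_birth_tree
from conftest import star_tree


class TestPGLSCore:
    def test_star_tree_equals_ols(self):
        tree = star_tree(20)
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = 1.2 + 2.0 * x + rng.normal(size=20) * 0.4
        fit = comparative.pgls_fit(y, x, tree, model="BM")
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert np.abs(fit.coef - ols.params).max() < 1e-8
        assert np.abs(fit.se - ols.bse).max() < 1e-8
        assert abs(fit.r2 - ols.rsquared) < 1e-8

    def test_exact_linear_data_any_tree(self):
        tree = pure_birth_tree(12, seed=1)
        x = np.linspace(-1, 1, 12)
        fit = comparative.pgls_fit(2.0 * x, x, tree, model="BM")
        assert fit.coef[1] == pytest.approx(2.0)
        assert np.abs(fit.residuals).max() < 1e-10

    def test_identity_model_is_ols(self):
        tree = pure_birth_tree(15, seed=2)
        rng = np.random.default_rng(3)
        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        fit = comparative.pgls_fit(y, x, tree, model="none")
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert np.abs(fit.coef - ols.params).max() < 1e-8
        assert np.abs(fit.se - ols.bse).max() < 1e-8

    def test_weighted_residual_orthogonality(self):
        tree = pure_birth_tree(24, seed=5)
        rng = np.random.default_rng(5)
        x = simulate_bm(tree, 1.0, 0.0, rng)[0]
        y = 0.5 * x + simulate_bm(tree, 0.5, 0.0, rng)[0]
        fit = comparative.pgls_fit(y, x, tree, model="BM")
        V = phylo_covariance(tree, "BM")
        X = np.column_stack([np.ones(24), x])
        g = X.T @ np.linalg.solve(V, fit.residuals.to_numpy())
        assert np.abs(g).max() < 1e-8

    def test_residuals_sum_to_zero_under_identity(self):
        tree = star_tree(10)
        rng = np.random.default_rng(8)
        y = rng.normal(size=10)
        fit = comparative.pgls_fit(y, rng.normal(size=10), tree, model="none")
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-10)

    def test_auto_selects_best_aic(self):
        tree = pure_birth_tree(32, seed=9)
        rng = np.random.default_rng(9)
        x = simulate_bm(tree, 1.0, 0.0, rng)[0]
        y = 1.5 * x + simulate_bm(tree, 1.0, 0.0, rng)[0]
        fit = comparative.pgls_fit(y, x, tree, model="auto")
        assert fit.candidates is not None and len(fit.candidates) == 4
        assert fit.aic == pytest.approx(fit.candidates["aic"].min())
        assert (fit.loglik >= fit.candidates["loglik"] - 1e-6).any()

    def test_species_mismatch_reported(self):
        tree = pure_birth_tree(8, seed=1)
        y = pd.Series(np.arange(7.0), index=tree.tip_labels[:-1])
        with pytest.raises(ValueError, match=tree.tip_labels[-1]):
            comparative.pgls_fit(y, y, tree)

    def test_bm_simulation_slope_recovery(self):
        tree = pure_birth_tree(64, seed=12)
        rng = np.random.default_rng(12)
        x = simulate_bm(tree, 1.0, 0.0, rng)[0]
        slopes = []
        for _ in range(40):
            y = 1.5 * x + simulate_bm(tree, 1.0, 0.0, rng)[0]
            slopes.append(comparative.pgls_fit(y, x, tree, model="BM").coef[1])
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 1.5) < 2 * se + 1e-9


class TestAncovaSlopes:
    @staticmethod
    def grouped_data(seed, slopes=(1.0, 1.0, 1.0), n_per=12, noise=0.1):
        rng = np.random.default_rng(seed)
        tree = pure_birth_tree(n_per * len(slopes), seed=seed)
        labels = np.array(
            [f"g{i}" for i in range(len(slopes)) for _ in range(n_per)]
        )
        labels = labels[rng.permutation(len(labels))]
        x = rng.normal(size=len(labels))
        slope_of = {f"g{i}": s for i, s in enumerate(slopes)}
        y = np.array([slope_of[g] for g in labels]) * x + rng.normal(
            size=len(labels)
        ) * noise
        return tree, y, x, pd.Series(labels, index=tree.tip_labels)

    def test_distinct_slopes_detected(self):
        tree, y, x, g = self.grouped_data(3, slopes=(1.0, 2.0), n_per=30, noise=0.1)
        res = comparative.ancova_slopes(y, x, g, tree, model="none")
        assert res.f_p < 0.01
        assert res.pairwise["p"].iloc[0] < 0.01
        assert res.slopes.loc["g0", "slope"] == pytest.approx(1.0, abs=0.15)
        assert res.slopes.loc["g1", "slope"] == pytest.approx(2.0, abs=0.15)

    def test_single_group_errors(self):
        tree, y, x, g = self.grouped_data(4, slopes=(1.0,), n_per=10)
        with pytest.raises(ValueError, match="two groups"):
            comparative.ancova_slopes(y, x, g, tree)

    def test_small_group_errors(self):
        tree, y, x, g = self.grouped_data(5, slopes=(1.0, 1.0), n_per=6)
        g.iloc[:] = "g0"
        g.iloc[0] = "g1"
        with pytest.raises(ValueError, match="fewer than 3"):
            comparative.ancova_slopes(y, x, g, tree)

    def test_type_one_error_rate_near_nominal(self):
        rejections = 0
        reps = 60
        for r in range(reps):
            tree, y, x, g = self.grouped_data(100 + r, slopes=(1.0, 1.0), n_per=15)
            res = comparative.ancova_slopes(y, x, g, tree, model="none")
            rejections += res.f_p < 0.05
        assert rejections / reps < 0.15  # ~5% nominal, binomial noise allowed


class TestResidualTests:
    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        res = rng.normal(size=24)
        groups = np.array(["a"] * 12 + ["b"] * 12)
        f, p = comparative.anova_on_residuals(res, groups)
        t, pt = stats.ttest_ind(res[:12], res[12:])
        assert f == pytest.approx(t ** 2)
        assert p == pytest.approx(pt)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(4)
        res = rng.normal(size=45)
        groups = np.array(["a"] * 15 + ["b"] * 15 + ["c"] * 15)
        res[groups == "c"] += 3.0  # 3-SD shift
        f, p = comparative.anova_on_residuals(res, groups)
        assert p < 1e-3
        tk = comparative.tukey_hsd(res, groups)
        involving_c = tk[(tk.group_a == "c") | (tk.group_b == "c")]
        other = tk[(tk.group_a != "c") & (tk.group_b != "c")]
        assert (involving_c["p"] < 1e-3).all()
        assert (other["p"] > 0.05).all()

    def test_degenerate_variance_errors(self):
        with pytest.raises(ValueError, match="zero within-group variance"):
            comparative.anova_on_residuals(
                np.array([1.0, 1.0, 2.0, 2.0]), np.array(["a", "a", "b", "b"])
            )

    def test_tukey_two_groups_matches_t_test(self):
        rng = np.random.default_rng(6)
        res = rng.normal(size=30)
        groups = np.array(["a"] * 15 + ["b"] * 15)
        tk = comparative.tukey_hsd(res, groups)
        _, pt = stats.ttest_ind(res[:15], res[15:])
        assert tk["p"].iloc[0] == pytest.approx(pt, abs=1e-6)


class TestPhyloAncovaModels:
    @staticmethod
    def setup_data(seed, effect=0.0):
        tree = pure_birth_tree(45, seed=seed)
        rng = np.random.default_rng(seed)
        diets = pd.Series(
            np.array(["omni"] * 20 + ["carni"] * 15 + ["vermi"] * 10)[
                rng.permutation(45)
            ],
            index=tree.tip_labels,
        )
        x = simulate_bm(tree, 1.0, 0.0, rng)[0]
        y = x + simulate_bm(tree, 0.2, 0.0, rng)[0]
        y[np.asarray(diets) == "vermi"] += effect
        groupings = {
            "H0": pd.Series("all", index=tree.tip_labels),
            "Carni": diets.map(lambda d: "omni" if d == "omni" else "carni+"),
            "Vermi": diets,
        }
        return tree, y, x, groupings

    def test_identical_groupings_lrt_is_null(self):
        tree, y, x, groupings = self.setup_data(3)
        tab = comparative.phylo_ancova_models(
            y, x, tree, {"A": groupings["Vermi"], "B": groupings["Vermi"]}
        )
        assert tab.loc["B", "lrt_chi2"] == pytest.approx(0.0, abs=1e-8)
        assert tab.loc["B", "lrt_p"] == 1.0

    def test_non_nested_groupings_rejected(self):
        tree, y, x, groupings = self.setup_data(4)
        crossed = groupings["Vermi"].copy()
        # make "Carni" no longer a coarsening of this relabelled version
        bad_carni = groupings["Carni"].copy()
        verm = crossed[crossed == "vermi"].index
        bad_carni[verm[0]] = "omni"
        with pytest.raises(ValueError, match="coarsening"):
            comparative.phylo_ancova_models(
                y, x, tree, {"Carni": bad_carni, "Vermi": crossed}
            )

    def test_null_prefers_simplest_model(self):
        wins = 0
        reps = 40
        for r in range(reps):
            tree, y, x, groupings = self.setup_data(200 + r, effect=0.0)
            tab = comparative.phylo_ancova_models(y, x, tree, groupings)
            wins += tab["aic"].idxmin() == "H0"
        assert wins / reps >= 0.6

    def test_strong_vermivore_effect_prefers_full_model(self):
        wins = 0
        reps = 30
        for r in range(reps):
            tree, y, x, groupings = self.setup_data(400 + r, effect=3 * np.sqrt(0.2))
            tab = comparative.phylo_ancova_models(y, x, tree, groupings)
            wins += tab["aic"].idxmin() == "Vermi"
        assert wins / reps >= 0.8
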