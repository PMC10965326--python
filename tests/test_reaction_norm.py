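import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import synstress as ss
from synstress.reaction_norm import fit_dapc, select_treatment_axis


def two_group_expr(n_per=10, shift=5.0, n_genes=20, n_shifted=10, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, (n_genes, 2 * n_per))
    x[:n_shifted, n_per:] += shift
    cols = [f"s{i}" for i in range(2 * n_per)]
    expr = pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    groups = pd.Series(["ctrl"] * n_per + ["treat"] * n_per, index=cols)
    return expr, groups


class TestDapc:
    def test_planted_shift_separates_groups_completely(self):
        expr, groups = two_group_expr()
        model = fit_dapc(expr, groups, n_pcs=5)
        s = model.scores["LD1"]
        assert max(s[groups == "ctrl"]) < min(s[groups == "treat"]) or \
            min(s[groups == "ctrl"]) > max(s[groups == "treat"])

    def test_random_groups_classify_near_chance(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(0, 1, (30, 40)),
                            columns=[f"s{i}" for i in range(40)])
        groups = pd.Series(rng.permutation(["A"] * 20 + ["B"] * 20),
                           index=expr.columns)
        # hold-out accuracy of the fitted discriminant should be near 0.5
        train = expr.columns[:30]
        test = expr.columns[30:]
        model = fit_dapc(expr[train], groups[train], n_pcs=5)
        pcs = model.pca.transform(expr[test].values.T
                                  - expr[train].values.T.mean(axis=0))
        pred = model.lda.predict(pcs[:, :model.n_pcs])
        acc = (pred == groups[test].values).mean()
        assert 0.1 <= acc <= 0.9

    def test_two_variable_toy_matches_closed_form_lda(self):
        rng = np.random.default_rng(2)
        n = 200
        a = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], n)
        b = rng.multivariate_normal([2, 1], [[1, 0.5], [0.5, 1]], n)
        x = np.vstack([a, b])
        expr = pd.DataFrame(x.T, index=["g1", "g2"],
                            columns=[f"s{i}" for i in range(2 * n)])
        groups = pd.Series(["A"] * n + ["B"] * n, index=expr.columns)
        model = fit_dapc(expr, groups, n_pcs=2)
        # closed form: direction Sw^-1 (m2 - m1)
        sw = (np.cov(a.T) * (n - 1) + np.cov(b.T) * (n - 1)) / (2 * n - 2)
        w = np.linalg.solve(sw, b.mean(0) - a.mean(0))
        proj = (x - x.mean(0)) @ w
        r = np.corrcoef(model.scores["LD1"], proj)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_scores_invariant_to_global_constant_shift(self):
        expr, groups = two_group_expr(seed=3)
        m1 = fit_dapc(expr, groups, n_pcs=5)
        m2 = fit_dapc(expr + 7.5, groups, n_pcs=5)
        assert np.allclose(m1.scores.values, m2.scores.values, atol=1e-8)

    def test_singleton_group_warns_but_fits(self):
        expr, groups = two_group_expr()
        groups.iloc[0] = "lonely"
        with pytest.warns(UserWarning, match="single sample"):
            model = fit_dapc(expr, groups, n_pcs=3)
        assert model.scores.shape[0] == expr.shape[1]


class TestAxisSelection:
    def test_treatment_dominant_selects_first_axis(self):
        expr, groups = two_group_expr(shift=8.0, seed=4)
        model = fit_dapc(expr, groups, n_pcs=5)
        ind = (groups == "treat").astype(int)
        axis, orient = select_treatment_axis(model, ind)
        assert axis == 0
        s = orient * model.scores.iloc[:, axis]
        assert s[ind == 1].mean() > s[ind == 0].mean()

    def test_genotype_dominant_puts_treatment_on_later_axis(self):
        # genotype effect is much stronger than treatment: the treatment
        # contrast lands on a later discriminant axis
        rng = np.random.default_rng(5)
        genos, n_per = ["G1", "G2", "G3"], 8
        rows, cols, geno_lab, treat_lab = [], [], [], []
        geno_shift = {"G1": 0.0, "G2": 12.0, "G3": -12.0}
        for g in genos:
            for t in ("control", "heat"):
                for r in range(n_per):
                    cols.append(f"{g}_{t}_{r}")
                    geno_lab.append(g)
                    treat_lab.append(t)
        x = rng.normal(0, 1, (30, len(cols)))
        for j, (g, t) in enumerate(zip(geno_lab, treat_lab)):
            x[:10, j] += geno_shift[g]
            if t == "heat":
                x[10:14, j] += 2.0
        expr = pd.DataFrame(x, columns=cols)
        groups = pd.Series([f"{g}.{t}" for g, t in zip(geno_lab, treat_lab)],
                           index=cols)
        model = fit_dapc(expr, groups, n_pcs=10)
        ind = pd.Series([int(t == "heat") for t in treat_lab], index=cols)
        axis, _ = select_treatment_axis(model, ind)
        assert axis > 0

    def test_sign_flip_invariance(self):
        expr, groups = two_group_expr(seed=6)
        model = fit_dapc(expr, groups, n_pcs=5)
        ind = (groups == "treat").astype(int)
        axis, orient = select_treatment_axis(model, ind)
        flipped = model
        flipped.scores = -model.scores
        axis2, orient2 = select_treatment_axis(flipped, ind)
        assert axis2 == axis
        s1 = orient * (-flipped.scores).iloc[:, axis]      # original oriented
        s2 = orient2 * flipped.scores.iloc[:, axis2]
        assert np.allclose(s1.values, s2.values)


class TestBaselinePlasticity:
    def _scores_model(self, scores, groups):
        model = fit_dapc(*two_group_expr(seed=7), n_pcs=2)
        return model

    def test_median_baseline_and_signed_plasticity_arithmetic(self):
        expr, _ = two_group_expr(n_per=3, seed=8)
        cols = expr.columns
        meta = pd.DataFrame({"genotype": ["G1"] * 6,
                             "treatment": ["control"] * 3 + ["heat"] * 3},
                            index=cols)
        model = fit_dapc(expr, pd.Series(["c"] * 3 + ["t"] * 3, index=cols),
                         n_pcs=2)
        model.scores = pd.DataFrame({"LD1": [-1.0, 0.0, 1.0, 2.5, 3.0, 3.5]},
                                    index=cols)
        rn = ss.baseline_and_plasticity(model, 0, 1, meta)
        assert rn.baseline["G1"] == pytest.approx(0.0)
        assert rn.plasticity[cols[3]] == pytest.approx(2.5)
        assert set(rn.plasticity.index) == set(cols[3:])

    def test_mean_mode_identity(self):
        expr, _ = two_group_expr(n_per=4, seed=9)
        cols = expr.columns
        meta = pd.DataFrame({"genotype": ["G1"] * 8,
                             "treatment": ["control"] * 4 + ["heat"] * 4},
                            index=cols)
        model = fit_dapc(expr, pd.Series(["c"] * 4 + ["t"] * 4, index=cols),
                         n_pcs=2)
        rn = ss.baseline_and_plasticity(model, 0, 1, meta, baseline_stat="mean")
        treated_mean = model.scores.iloc[4:, 0].mean()
        assert rn.baseline["G1"] + rn.plasticity.mean() == pytest.approx(treated_mean)

    def test_genotype_without_control_excluded_with_warning(self):
        expr, _ = two_group_expr(n_per=4, seed=10)
        cols = expr.columns
        meta = pd.DataFrame({"genotype": ["G1"] * 4 + ["G2"] * 4,
                             "treatment": ["control"] * 2 + ["heat"] * 2
                             + ["heat"] * 4},
                            index=cols)
        model = fit_dapc(expr, pd.Series(["c"] * 4 + ["t"] * 4, index=cols),
                         n_pcs=2)
        with pytest.warns(UserWarning, match="no control"):
            rn = ss.baseline_and_plasticity(model, 0, 1, meta)
        assert "G2" not in rn.baseline.index
        assert not set(meta.index[meta["genotype"] == "G2"]) & \
            set(rn.plasticity.index)


class TestRetentionAndRegression:
    def test_retention_arithmetic(self):
        meta = pd.DataFrame({"genotype": ["G1", "G1", "G1"],
                             "treatment": ["control", "control", "heat"]},
                            index=list("abc"))
        traits = pd.DataFrame({"symbiont_density_per_cm2": [6e5, 8e5, 5e5]},
                              index=list("abc"))
        ret = ss.symbiont_retention(traits, meta, "heat")
        assert ret["c"] == pytest.approx(5e5 - 7e5)

    def test_control_equal_densities_give_zero_retention(self):
        meta = pd.DataFrame({"genotype": ["G1"] * 3,
                             "treatment": ["control", "control", "heat"]},
                            index=list("abc"))
        traits = pd.DataFrame({"symbiont_density_per_cm2": [4e5, 4e5, 4e5]},
                              index=list("abc"))
        assert ss.symbiont_retention(traits, meta, "heat")["c"] == 0.0

    def test_exactly_linear_regression(self):
        x = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        y = 2 * x - 1
        res = ss.regress_performance(x, y)
        assert res.slope == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.pvalue < 1e-10
        assert res.adj_r2 <= res.r2 + 1e-12

    def test_null_slope_p_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            x = pd.Series(rng.normal(0, 1, 20))
            y = pd.Series(rng.normal(0, 1, 20))
            ps.append(ss.regress_performance(x, y).pvalue)
        assert 0.4 < np.mean(ps) < 0.6

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            ss.regress_performance(pd.Series([1.0, 1.0, 1.0]),
                                   pd.Series([1.0, 2.0, 3.0]))


class TestEndToEndRecovery:
    def test_planted_genotype_parameters_recovered(self, small_sim):
        _, counts, meta, traits, truth = small_sim
        prep = ss.preprocess(counts, meta)
        genes = [g for g in truth.gene_modules.index[truth.gene_modules == "M1"]
                 if g in prep.expr.index]
        rn = ss.ReactionNorm(prep.expr, prep.meta, traits, "combined",
                             genes=genes).fit()
        rho_b = spearmanr(rn.norm.baseline,
                          truth.baseline.reindex(rn.norm.baseline.index)).statistic
        assert rho_b >= 0.8
        mp = rn.norm.genotype_mean_plasticity(prep.meta)
        rho_p = spearmanr(mp, truth.plasticity.reindex(mp.index)).statistic
        assert rho_p >= 0.8
        assert rn.baseline_regression.slope > 0       # planted slope_baseline > 0
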