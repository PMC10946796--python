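import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import adjusted_rand_score

from lipidims import multivariate as mv
from lipidims.phantom import simulate_feature_matrix
from conftest import make_feature_matrix


class TestParetoScale:
    def test_column_example(self):
        X = np.array([[0.0], [0.0], [4.0], [4.0]])
        Xs, rec = mv.pareto_scale(X)
        np.testing.assert_allclose(
            Xs[:, 0], [-1.4142, -1.4142, 1.4142, 1.4142], atol=1e-4)
        assert not rec.zero_variance[0]

    def test_constant_column_flagged(self):
        X = np.array([[3.0, 1.0], [3.0, 2.0], [3.0, 3.0]])
        Xs, rec = mv.pareto_scale(X)
        assert rec.zero_variance[0]
        np.testing.assert_allclose(Xs[:, 0], 0)

    def test_scaled_sd_is_sqrt_of_original(self, rng):
        X = rng.uniform(0, 10, (20, 4))
        Xs, _ = mv.pareto_scale(X)
        np.testing.assert_allclose(
            Xs.std(axis=0, ddof=0), np.sqrt(X.std(axis=0, ddof=0)), atol=1e-10)


class TestPca:
    def test_collinear_data_one_component(self, rng):
        t = rng.normal(size=10)
        X = np.outer(t, [1.0, 2.0, -1.0]) + 5
        fm = make_feature_matrix(X - X.min() + 1)
        model = mv.fit_pca(fm, n_components=2)
        assert model.explained_variance_pct[0] == pytest.approx(100.0)

    def test_scores_equal_projection(self, rng):
        X = rng.uniform(0, 10, (8, 5))
        fm = make_feature_matrix(X)
        model = mv.fit_pca(fm, n_components=3)
        Xs, _ = mv.pareto_scale(X)
        proj = (Xs - Xs.mean(axis=0)) @ model.loadings.to_numpy()
        np.testing.assert_allclose(model.scores.to_numpy(), proj, atol=1e-8)

    def test_agrees_with_svd_oracle(self, rng):
        X = rng.uniform(0, 10, (6, 5))
        fm = make_feature_matrix(X)
        model = mv.fit_pca(fm, n_components=3)
        Xs, _ = mv.pareto_scale(X)
        Xc = Xs - Xs.mean(axis=0)
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        for k in range(3):
            dot = abs(model.loadings.to_numpy()[:, k] @ vt[k])
            assert dot == pytest.approx(1.0, abs=1e-8)
        var = s**2 / (len(X))
        np.testing.assert_allclose(
            model.explained_variance_pct[:3],
            100 * var[:3] / X.shape[1] / Xs.var(axis=0).mean() * 1, atol=1e-6)

    def test_explained_variance_non_increasing_and_bounded(self, rng):
        fm = make_feature_matrix(rng.uniform(0, 10, (10, 6)))
        model = mv.fit_pca(fm, n_components=4)
        ev = model.explained_variance_pct
        assert (np.diff(ev) <= 1e-12).all()
        assert ev.sum() <= 100 + 1e-9

    def test_too_many_components_rejected(self, rng):
        fm = make_feature_matrix(rng.uniform(0, 10, (4, 5)))
        with pytest.raises(ValueError):
            mv.fit_pca(fm, n_components=4)


def _two_group_fm(rng, n_per=4, n_ions=6, delta=None):
    X = rng.uniform(5, 10, (2 * n_per, n_ions))
    if delta is not None:
        X[n_per:] += delta
    groups = ["A"] * n_per + ["B"] * n_per
    return make_feature_matrix(X), np.array(groups)


class TestOplsda:
    def test_single_informative_ion(self, rng):
        n = 6
        X = np.tile(rng.uniform(5, 6, (1, 5)), (2 * n, 1))  # constant ions
        X = np.column_stack([X, np.r_[np.full(n, 5.0), np.full(n, 9.0)]])
        fm = make_feature_matrix(X)
        groups = np.array(["A"] * n + ["B"] * n)
        model = mv.fit_oplsda(fm, groups, group_pos="B", n_orth=0,
                              compute_q2=False)
        corr = model.splot["splot_corr"].to_numpy()
        assert abs(corr[-1]) == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(corr[:-1], 0.0, atol=1e-12)

    def test_north_zero_matches_nipals_pls(self, rng):
        """With no orthogonal components the predictive scores equal
        one-component NIPALS PLS scores up to sign."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            fm, groups = _two_group_fm(r, n_per=4, n_ions=6, delta=r.uniform(0, 1, 6))
            model = mv.fit_oplsda(fm, groups, group_pos="B", n_orth=0,
                                  compute_q2=False)
            Xs, _ = mv.pareto_scale(fm.values.to_numpy())
            y = np.where(groups == "B", 1.0, -1.0)
            pls = PLSRegression(n_components=1, scale=False)
            pls.fit(Xs, y - y.mean())
            t_ref = pls.x_scores_[:, 0]
            sign = np.sign(t_ref @ model.t_pred)
            np.testing.assert_allclose(model.t_pred, sign * t_ref, atol=1e-8)

    def test_orthogonal_scores_perpendicular(self, rng):
        fm, groups = _two_group_fm(rng, n_per=5, n_ions=8,
                                   delta=rng.uniform(0, 1, 8))
        model = mv.fit_oplsda(fm, groups, n_orth=2, compute_q2=False)
        for k in range(model.t_orth.shape[1]):
            assert abs(model.t_orth[:, k] @ model.t_pred) < 1e-10

    def test_splot_sign_coherence(self, rng):
        fm, groups = _two_group_fm(rng, n_per=6, n_ions=10,
                                   delta=rng.uniform(-1, 1, 10))
        model = mv.fit_oplsda(fm, groups, n_orth=1, compute_q2=False)
        s = model.splot
        nonzero = s["splot_corr"].abs() > 1e-12
        assert (np.sign(s.loc[nonzero, "splot_cov"])
                == np.sign(s.loc[nonzero, "splot_corr"])).all()
        assert (s["splot_corr"].abs() <= 1 + 1e-12).all()

    def test_positive_group_has_positive_mean_score(self, rng):
        fm, groups = _two_group_fm(rng, delta=rng.uniform(0, 2, 6))
        model = mv.fit_oplsda(fm, groups, group_pos="A", compute_q2=False)
        assert model.t_pred[groups == "A"].mean() > 0

    def test_explains_no_less_y_variance_than_pls(self, rng):
        """OPLS with 1 predictive + k orthogonal components captures at
        least the Y-variance of (k+1)-component PLS1."""
        for k in (1, 2):
            fm, groups = _two_group_fm(rng, n_per=6, n_ions=8,
                                       delta=rng.uniform(0, 1, 8))
            model = mv.fit_oplsda(fm, groups, n_orth=k, compute_q2=False)
            Xs, _ = mv.pareto_scale(fm.values.to_numpy())
            y = np.where(groups == groups[-1], 1.0, -1.0)
            yc = y - y.mean()
            pls = PLSRegression(n_components=k + 1, scale=False)
            pls.fit(Xs, yc)
            resid = yc - pls.predict(Xs).ravel()
            r2_pls = 1 - (resid**2).sum() / (yc**2).sum()
            assert model.r2y >= r2_pls - 1e-8

    def test_constant_groups_rejected(self, rng):
        fm, _ = _two_group_fm(rng)
        with pytest.raises(ValueError):
            mv.fit_oplsda(fm, np.array(["A"] * 8), compute_q2=False)

    def test_n_orth_at_rank_rejected(self, rng):
        fm, groups = _two_group_fm(rng, n_per=2, n_ions=3)
        with pytest.raises(ValueError):
            mv.fit_oplsda(fm, groups, n_orth=10, compute_q2=False)


def _model_with_covs(covs):
    splot = pd.DataFrame({
        "splot_cov": covs,
        "splot_corr": np.sign(covs) * 0.5,
    }, index=pd.Index([f"ion{i}" for i in range(len(covs))], name="bin_id"))
    return mv.OplsModel(
        contrast="A_vs_B", group_pos="A", group_neg="B",
        t_pred=np.zeros(2), t_orth=np.empty((2, 0)),
        w_pred=np.zeros(len(covs)), p_pred=np.zeros(len(covs)),
        splot=splot, r2y=1.0, q2=1.0, scaling=None,
        bin_ids=list(splot.index))


class TestPanels:
    def test_threshold_above_max_gives_empty_panel(self):
        model = _model_with_covs(np.array([0.01, -0.02]))
        with pytest.warns(UserWarning):
            panel = mv.select_panel(model, "cov", 0.5)
        assert len(panel) == 0

    def test_signed_selection(self):
        model = _model_with_covs(np.array([0.05, -0.06, 0.01]))
        panel = mv.select_panel(model, "cov", 0.04)
        table = panel.table.set_index("bin_id")
        assert set(table.index) == {"ion0", "ion1"}
        assert table.loc["ion0", "direction"] == "A"
        assert table.loc["ion1", "direction"] == "B"

    def test_monotone_in_threshold(self, rng):
        model = _model_with_covs(rng.normal(0, 0.1, 30))
        sizes = [len(mv.select_panel(model, "cov", t))
                 for t in (0.01, 0.05, 0.1, 0.2)]
        assert sizes == sorted(sizes, reverse=True)

    def test_explicit_exclusion_logged(self):
        model = _model_with_covs(np.array([0.05, -0.06]))
        panel = mv.select_panel(model, "cov", 0.04, exclude=["ion0"])
        assert panel.bin_ids == {"ion1"}
        assert panel.excluded[0]["bin_id"] == "ion0"

    def test_merge_disjoint(self):
        a = mv.select_panel(_model_with_covs(np.array([0.1, 0.1, 0.1])), "cov", 0.04)
        b = mv.select_panel(
            _model_with_covs(np.array([0.0, 0.0, 0.0, 0.1, 0.1, 0.1, 0.1])),
            "cov", 0.04)
        merged = mv.merge_panels([a, b])
        assert len(merged) == 7

    def test_merge_idempotent(self):
        a = mv.select_panel(_model_with_covs(np.array([0.1, -0.2])), "cov", 0.04)
        merged = mv.merge_panels([a, a])
        assert len(merged) == len(a)

    def test_merge_overlap_counts(self, rng):
        """Two panels of 96 and 80 ions sharing 69 -> union of 107."""
        ions = [f"i{k}" for k in range(200)]
        a_ids = ions[:96]
        b_ids = ions[27:107]  # 96-27 = 69 shared with a
        covs_a = np.array([0.1 if i in set(a_ids) else 0.0 for i in ions])
        covs_b = np.array([0.1 if i in set(b_ids) else 0.0 for i in ions])
        pa = _model_with_covs(covs_a)
        pa.splot.index = pd.Index(ions, name="bin_id")
        pb = _model_with_covs(covs_b)
        pb.splot.index = pd.Index(ions, name="bin_id")
        pb.contrast = "C_vs_D"
        panel_a = mv.select_panel(pa, "cov", 0.04)
        panel_b = mv.select_panel(pb, "cov", 0.04)
        merged = mv.merge_panels([panel_a, panel_b])
        assert (len(panel_a), len(panel_b)) == (96, 80)
        assert len(merged) == 107
        assert merged.overlap[("A_vs_B", "C_vs_D")] == 69


class TestHierarchicalClustering:
    def test_identical_rows_merge_at_zero(self, rng):
        base = rng.uniform(0, 10, 6)
        X = np.vstack([base, base, base + rng.uniform(1, 2, 6)])
        fm = make_feature_matrix(X)
        res = mv.hierarchical_cluster(fm, metric="euclidean")
        assert res.row_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_column_permutation_preserves_row_topology(self, rng):
        X = rng.uniform(0, 10, (6, 8))
        fm = make_feature_matrix(X)
        perm = rng.permutation(8)
        fm_p = make_feature_matrix(X[:, perm])
        a = mv.hierarchical_cluster(fm)
        b = mv.hierarchical_cluster(fm_p)
        np.testing.assert_allclose(a.row_linkage, b.row_linkage, atol=1e-12)

    def test_four_tissue_recovery(self):
        """Row clustering cut at k=4 recovers the four tissue classes."""
        fm, _ = simulate_feature_matrix(
            n_ions=60, n_rois_per_group=3, zones=("z",), seed=5)
        # overwrite with 4 clearly separated tissue profiles
        rng = np.random.default_rng(5)
        tissues = np.repeat(["gp", "ac", "cb", "m"], 4)
        profiles = {t: rng.uniform(8, 12, 60) for t in np.unique(tissues)}
        X = np.vstack([profiles[t] + rng.normal(0, 0.3, 60) for t in tissues])
        fm = make_feature_matrix(X, tissues=list(tissues), scale="log2")
        res = mv.hierarchical_cluster(fm)
        labels = res.cut_rows(4)
        assert adjusted_rand_score(tissues, labels) >= 0.9

    def test_too_few_rows_rejected(self, rng):
        fm = make_feature_matrix(rng.uniform(0, 1, (1, 5)))
        with pytest.raises(ValueError):
            mv.hierarchical_cluster(fm)
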