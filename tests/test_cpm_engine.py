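"""CPM core: normalization, partial Spearman screen, strengths, CV."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import trustcpm as tc
from trustcpm import cpm_engine as ce


def brute_partial_spearman(x, y, C):
    """Independent oracle: explicit ranks, lstsq residuals, Pearson, t p-value."""
    n = len(x)
    Z = np.column_stack([np.ones(n)] + [stats.rankdata(C[:, j])
                                        for j in range(C.shape[1])])
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    res_x = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    res_y = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    rho = np.corrcoef(res_x, res_y)[0, 1]
    df = n - 2 - C.shape[1]
    t = rho * np.sqrt(df / (1 - rho**2))
    return rho, 2 * stats.t.sf(abs(t), df)


class TestNormalize:
    def test_symmetric_train_maps_test_midpoint_to_zero(self):
        ztr, zte, (mean, sd) = tc.normalize_fit_apply([0.0, 10.0], [5.0])
        assert mean == 5.0
        assert zte[0] == 0.0
        assert ztr[0] == -ztr[1]

    def test_matches_loop_oracle(self, rng):
        train = rng.standard_normal(30)
        test = rng.standard_normal(10)
        ztr, zte, (mean, sd) = tc.normalize_fit_apply(train, test)
        m, s = train.mean(), train.std(ddof=1)
        for v, z in zip(np.r_[train, test], np.r_[ztr, zte]):
            assert z == pytest.approx((v - m) / s, abs=1e-12)

    def test_constant_train_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            tc.normalize_fit_apply([3.0, 3.0, 3.0], [1.0])


class TestPartialSpearman:
    def test_identity_without_covariates(self, rng):
        x = rng.standard_normal(15)
        rho, p = tc.partial_spearman(x, x)
        assert rho == pytest.approx(1.0)

    def test_collinear_covariate_gives_degenerate_zero(self):
        x = np.arange(12.0)
        rho, p = tc.partial_spearman(x, x, covariates=x)
        assert (rho, p) == (0.0, 1.0)

    def test_matches_brute_force_oracle(self, rng):
        x = rng.standard_normal(20)
        y = 0.5 * x + rng.standard_normal(20)
        C = rng.standard_normal((20, 3))
        rho, p = tc.partial_spearman(x, y, C)
        rho0, p0 = brute_partial_spearman(x, y, C)
        assert rho == pytest.approx(rho0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_agrees_with_pingouin(self, rng):
        x = rng.standard_normal(40)
        y = 0.4 * x + rng.standard_normal(40)
        z = rng.standard_normal(40)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ours = tc.partial_spearman(x, y, z)
        ref = pg.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        assert ours[0] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="at least"):
            tc.partial_spearman(np.arange(5.0), np.arange(5.0),
                                np.ones((5, 2)) * np.arange(5.0)[:, None])

    def test_rank_deficient_covariates_rejected(self, rng):
        x = rng.standard_normal(20)
        z = rng.standard_normal(20)
        with pytest.raises(ValueError, match="rank-deficient"):
            tc.partial_spearman(x, x, np.column_stack([z, z]))


class TestSelectEdges:
    def test_behavior_equal_to_edge_is_selected(self, rng):
        E = rng.standard_normal((30, 12))
        sel = tc.select_edges(E, E[:, 7], alpha=0.01)
        assert 7 in sel.positive
        assert sel.negative.size == 0 or 7 not in sel.negative

    def test_vanishing_alpha_empties_both_sets(self, rng):
        E = rng.standard_normal((30, 50))
        y = rng.standard_normal(30)
        sel = tc.select_edges(E, y, alpha=1e-12)
        assert sel.positive.size == 0 and sel.negative.size == 0

    def test_planted_recovery_matches_independent_recount(self):
        ds = tc.generate_dataset(tc.SyntheticParams(seed=42))
        y = ds.behavior["trust"].to_numpy()
        C = ds.behavior[["age", "sex", "education", "fd"]].to_numpy()
        sel = tc.select_edges(ds.edges, y, C, alpha=0.01)
        hits = np.intersect1d(sel.positive, ds.signal_edges)
        sensitivity = hits.size / ds.signal_edges.size
        assert sensitivity >= 0.8
        # recount each planted edge with the brute-force scalar routine
        for k in ds.signal_edges:
            rho0, p0 = brute_partial_spearman(ds.edges[:, k], y, C)
            assert sel.rho[k] == pytest.approx(rho0, abs=1e-10)
            assert (k in sel.positive) == (p0 < 0.01 and rho0 > 0)

    def test_disjoint_sets(self, rng):
        E = rng.standard_normal((40, 200))
        y = rng.standard_normal(40)
        sel = tc.select_edges(E, y, alpha=0.2)
        assert np.intersect1d(sel.positive, sel.negative).size == 0


class TestStrengthAndModel:
    def test_strength_arithmetic(self):
        v = np.array([0.2, 0.5, -0.3, -0.1])
        assert tc.network_strength(v, np.array([0, 3])) == pytest.approx(0.1)
        assert tc.network_strength(v, np.array([], dtype=int)) == 0.0

    def test_strength_loop_oracle_and_linearity(self, rng):
        v = rng.standard_normal(50)
        sel = rng.choice(50, size=17, replace=False)
        assert tc.network_strength(v, sel) == pytest.approx(
            sum(v[k] for k in sel), abs=1e-12)
        assert tc.network_strength(3.5 * v, sel) == pytest.approx(
            3.5 * tc.network_strength(v, sel), abs=1e-10)

    def test_exact_line_recovered(self):
        s = np.array([0.0, 1.0, 2.0, 3.0])
        assert tc.fit_strength_model(s, 2 * s + 1) == pytest.approx((1.0, 2.0))

    def test_zero_behavior_gives_zero_model(self):
        s = np.array([1.0, 2.0, 3.0])
        assert tc.fit_strength_model(s, np.zeros(3)) == (0.0, 0.0)

    def test_matches_normal_equations(self, rng):
        s = rng.standard_normal(20)
        y = rng.standard_normal(20)
        a, b = tc.fit_strength_model(s, y)
        X = np.column_stack([np.ones(20), s])
        ref = np.linalg.solve(X.T @ X, X.T @ y)
        assert (a, b) == pytest.approx(tuple(ref), abs=1e-10)

    def test_constant_strengths_fall_back_to_mean(self):
        y = np.array([1.0, 2.0, 3.0])
        a, b = tc.fit_strength_model(np.ones(3), y)
        assert (a, b) == (pytest.approx(2.0), 0.0)


class TestSubsetRanks:
    @given(st.integers(0, 10_000), st.integers(1, 4))
    @settings(max_examples=25, deadline=None)
    def test_drop_update_equals_direct_ranking(self, seed, n_drop):
        rng = np.random.default_rng(seed)
        E = rng.integers(0, 5, size=(14, 25)).astype(float)  # heavy ties
        ws = ce._EdgeWorkspace(E)
        dropped = rng.choice(14, size=n_drop, replace=False)
        train = np.setdiff1d(np.arange(14), dropped)
        R = ce._subset_ranks(ws.E, ws.R_full, train, dropped, ws.tied_cols)
        ref = np.column_stack([stats.rankdata(E[train, k]) for k in range(25)])
        assert np.allclose(R, ref)


class TestLoocv:
    def test_perfect_signal_toy(self, toy_atlas):
        rng = np.random.default_rng(0)
        n, m = 12, tc.n_edges(toy_atlas.n_nodes)
        E = rng.standard_normal((n, m))
        y = E[:, 10].copy()  # behavior exactly equals one edge
        bt = pd.DataFrame({"subject_id": [str(i) for i in range(n)], "trust": y})
        # a strict screen leaves only the perfectly correlated edge
        cfg = tc.CpmConfig(covariates=(), selection_alpha=1e-4)
        res = tc.run_loocv(E, bt, cfg)
        assert res.assessment()["positive"].r == pytest.approx(1.0)
        assert all(10 in f.positive_edges for f in res.folds)

    def test_subject_order_invariance(self, toy_dataset):
        cfg = tc.CpmConfig()
        conns = toy_dataset.connectomes()
        res1 = tc.run_loocv(conns, toy_dataset.behavior, cfg)
        shuffled = toy_dataset.behavior.sample(frac=1, random_state=9)
        res2 = tc.run_loocv(conns, shuffled, cfg)
        assert res1.subject_ids == res2.subject_ids
        assert np.allclose(res1.predicted_pos, res2.predicted_pos)

    def test_no_leakage_from_held_out_subject(self, toy_dataset):
        cfg = tc.CpmConfig()
        res1 = tc.run_loocv(toy_dataset.edges, toy_dataset.behavior, cfg)
        i = 4
        tampered = toy_dataset.behavior.copy()
        tampered.loc[i, "trust"] = 10 - tampered.loc[i, "trust"]
        res2 = tc.run_loocv(toy_dataset.edges, tampered, cfg)
        f1, f2 = res1.folds[i], res2.folds[i]
        assert np.array_equal(f1.positive_edges, f2.positive_edges)
        assert np.array_equal(f1.negative_edges, f2.negative_edges)
        assert f1.behavior_normalizer == f2.behavior_normalizer
        assert f1.positive_model == f2.positive_model

    def test_id_mismatch_rejected(self, toy_dataset):
        bt = toy_dataset.behavior.copy()
        bt.loc[0, "subject_id"] = "nobody"
        with pytest.raises(ValueError, match="subject ids"):
            tc.run_loocv(toy_dataset.connectomes(), bt, tc.CpmConfig())

    def test_too_few_subjects_rejected(self, rng):
        E = rng.standard_normal((5, 10))
        bt = pd.DataFrame({"trust": rng.integers(0, 10, 5)})
        with pytest.raises(ValueError, match="at least 10"):
            tc.run_loocv(E, bt, tc.CpmConfig(covariates=()))

    def test_fold_sets_always_disjoint(self, toy_dataset):
        res = tc.run_loocv(toy_dataset.edges, toy_dataset.behavior, tc.CpmConfig())
        for f in res.folds:
            assert np.intersect1d(f.positive_edges, f.negative_edges).size == 0


class TestKfold:
    def test_k_equal_n_reduces_to_loocv(self, toy_dataset):
        n = len(toy_dataset.behavior)
        cfg = tc.CpmConfig(k=n, repeats=1, seed=3)
        kres = tc.run_kfold(toy_dataset.edges, toy_dataset.behavior, cfg)
        lres = tc.run_loocv(toy_dataset.edges, toy_dataset.behavior, cfg)
        assert np.array_equal(kres.results[0].predicted_pos, lres.predicted_pos)
        assert np.array_equal(kres.results[0].predicted_neg, lres.predicted_neg)

    def test_perfect_signal_mean_r_near_one(self, toy_atlas):
        rng = np.random.default_rng(1)
        n, m = 20, tc.n_edges(toy_atlas.n_nodes)
        E = rng.standard_normal((n, m))
        y = E[:, 3] + 0.01 * rng.standard_normal(n)
        bt = pd.DataFrame({"trust": y})
        cfg = tc.CpmConfig(covariates=(), k=5, repeats=5, seed=0,
                           selection_alpha=1e-4)
        kres = tc.run_kfold(E, bt, cfg)
        assert kres.summary()["r_pos_mean"] > 0.95

    def test_k_larger_than_n_rejected(self, toy_dataset):
        cfg = tc.CpmConfig(k=500, repeats=1)
        with pytest.raises(ValueError, match="exceeds"):
            tc.run_kfold(toy_dataset.edges, toy_dataset.behavior, cfg)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"selection_alpha": 0.0}, {"selection_alpha": 1.5}, {"k": 1},
        {"repeats": 0}, {"cv_scheme": "bootstrap"},
        {"small_sample_p_rule": "midp"},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            tc.CpmConfig(**kwargs)
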