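import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import gammaln

from driftome.stats import (
    ISplineBasis,
    build_site_pairs,
    fit_gdm,
    fit_smooth_glm,
    gdm_importance,
    tost_paired,
    welch_t,
    wilcoxon_z,
)


def make_samples(n, seed=0, preds=("x", "y", "z")):
    rng = np.random.default_rng(seed)
    data = {p: rng.uniform(0, 10, n) for p in preds}
    return pd.DataFrame(data, index=[f"s{i}" for i in range(n)])


def gdm_response(sd, driver="x", scale=10.0, a0=0.1):
    resp = {}
    for a, b in itertools.combinations(list(sd.index), 2):
        dx = abs(sd.loc[a, driver] - sd.loc[b, driver]) / scale
        resp[(a, b)] = 1 - np.exp(-(a0 + dx))
    return resp


class TestISpline:
    def test_monotone_non_decreasing_on_grid(self):
        rng = np.random.default_rng(0)
        basis = ISplineBasis(rng.uniform(-3, 7, 200))
        grid = np.linspace(-3, 7, 500)
        T = basis.transform(grid)
        assert (np.diff(T, axis=0) >= -1e-12).all()

    def test_range_zero_to_one(self):
        basis = ISplineBasis(np.linspace(0, 1, 50))
        T = basis.transform(np.linspace(-1, 2, 100))
        assert T.min() >= 0 and T.max() <= 1
        np.testing.assert_allclose(basis.transform([0.0])[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(basis.transform([1.0])[0], 1.0, atol=1e-12)

    def test_three_functions_by_default(self):
        assert ISplineBasis(np.linspace(0, 1, 9)).n_splines == 3


class TestSitePairs:
    def test_combinatorics(self):
        sd = make_samples(7)
        pairs = build_site_pairs(sd, {k: 0.5 for k in
                                      itertools.combinations(list(sd.index), 2)})
        assert len(pairs.pairs) == 7 * 6 // 2

    def test_identical_samples_zero_response(self):
        sd = make_samples(4)
        resp = gdm_response(sd)
        sd.loc["s1"] = sd.loc["s0"]
        resp[("s0", "s1")] = 0.0
        pairs = build_site_pairs(sd, resp)
        row = pairs.pairs.query("sample_a == 's0' and sample_b == 's1'")
        assert row.response.iloc[0] == 0.0

    def test_missing_predictor_listed(self):
        sd = make_samples(4)
        sd.loc["s2", "y"] = np.nan
        with pytest.raises(ValueError, match="s2"):
            build_site_pairs(sd, {})

    def test_csv_round_trip(self, tmp_path):
        sd = make_samples(5)
        pairs = build_site_pairs(sd, gdm_response(sd))
        p = tmp_path / "pairs.csv"
        pairs.to_csv(p)
        back = pd.read_csv(p)
        pd.testing.assert_frame_equal(back, pairs.pairs, check_exact=False, atol=1e-12)


class TestGDM:
    def test_self_consistent_recovery(self):
        sd = make_samples(20, seed=1)
        fit = fit_gdm(build_site_pairs(sd, gdm_response(sd)))
        assert fit.deviance_explained > 99.0
        curve = fit.spline_curve("x")
        assert (np.diff(curve.f) >= -1e-10).all()

    def test_null_near_zero(self):
        sd = make_samples(45, seed=2)
        rng = np.random.default_rng(3)
        resp = {k: float(rng.uniform(0.2, 0.8))
                for k in itertools.combinations(list(sd.index), 2)}
        fit = fit_gdm(build_site_pairs(sd, resp))
        assert fit.deviance_explained < 2.0

    def test_predictions_in_unit_interval(self):
        sd = make_samples(15, seed=4)
        pairs = build_site_pairs(sd, gdm_response(sd))
        fit = fit_gdm(pairs)
        pred = fit.predict(pairs.pairs)
        assert (pred >= 0).all() and (pred < 1).all()

    def test_intercept_only_when_no_predictors(self):
        sd = make_samples(8, seed=5)
        resp = gdm_response(sd)
        pairs = build_site_pairs(sd, resp, predictors=[])
        fit = fit_gdm(pairs)
        assert fit.deviance_explained == pytest.approx(0.0, abs=1e-6)

    def test_too_few_pairs(self):
        sd = make_samples(4, seed=6)
        with pytest.raises(ValueError, match="10"):
            fit_gdm(build_site_pairs(sd, gdm_response(sd)))

    def test_importance_sums_to_100_and_finds_driver(self):
        sd = make_samples(16, seed=7)
        pairs = build_site_pairs(sd, gdm_response(sd))
        fit = fit_gdm(pairs)
        imp, p = gdm_importance(fit, pairs, n_perm=25, seed=8)
        assert imp.sum() == pytest.approx(100.0)
        assert imp.idxmax() == "x"
        assert p["x"] < 0.05

    def test_noise_predictor_not_significant(self):
        sd = make_samples(16, seed=9)
        pairs = build_site_pairs(sd, gdm_response(sd, driver="x"))
        fit = fit_gdm(pairs)
        _, p = gdm_importance(fit, pairs, n_perm=30, seed=10)
        assert p["z"] > 0.05

    def test_low_n_perm_warns(self):
        sd = make_samples(12, seed=11)
        pairs = build_site_pairs(sd, gdm_response(sd))
        fit = fit_gdm(pairs)
        with pytest.warns(UserWarning, match="unstable"):
            gdm_importance(fit, pairs, n_perm=5, seed=12)


class TestSmoothGLM:
    def test_hump_recovery(self):
        rng = np.random.default_rng(0)
        n = 120
        sigma = rng.uniform(0, 3, n)
        mu = 20 * np.exp(-((sigma - 1.2) ** 2) / 0.5) + 5
        y = rng.poisson(mu)
        data = pd.DataFrame({"richness": y, "sigma_sst": sigma,
                             "status": rng.choice(["raft", "non_raft"], n)})
        fit = fit_smooth_glm(data, "richness", ["sigma_sst"], ["status"],
                             family="negative_binomial")
        grid = np.linspace(0, 3, 200)
        eff = fit.predict_term("sigma_sst", grid)
        peak = grid[np.argmax(eff)]
        assert abs(peak - 1.2) <= 0.2 * 1.2

    def test_constant_response_flat_fit(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame({"y": np.full(60, 7.0), "x": rng.uniform(0, 1, 60)})
        fit = fit_smooth_glm(data, "y", ["x"], family="negative_binomial")
        grid = np.linspace(0, 1, 50)
        eff = fit.predict_term("x", grid)
        assert np.ptp(eff) < 0.05  # essentially flat on the link scale

    def test_nb_loglik_closed_form(self):
        # 5-point hand example, theta = 2, mu = 3
        from driftome.stats import _nb_loglik

        y = np.array([0.0, 1, 2, 3, 10])
        mu = np.full(5, 3.0)
        theta = 2.0
        expected = sum(
            gammaln(v + theta) - gammaln(theta) - gammaln(v + 1)
            + theta * np.log(theta / (theta + 3.0))
            + v * np.log(3.0 / (theta + 3.0))
            for v in y
        )
        assert _nb_loglik(y, mu, theta) == pytest.approx(float(expected))

    def test_beta_family_domain_check(self):
        data = pd.DataFrame({"y": [0.2, 0.5, 1.0, 0.4] * 10,
                             "x": np.linspace(0, 1, 40)})
        with pytest.raises(ValueError, match="boundary transformation"):
            fit_smooth_glm(data, "y", ["x"], family="beta")

    def test_beta_family_fits_in_unit_interval(self):
        rng = np.random.default_rng(2)
        n = 80
        x = rng.uniform(0, 1, n)
        mu = 1 / (1 + np.exp(-(0.5 + 2 * x)))
        y = np.clip(mu + rng.normal(0, 0.05, n), 0.01, 0.99)
        data = pd.DataFrame({"y": y, "x": x})
        fit = fit_smooth_glm(data, "y", ["x"], family="beta")
        assert fit.family == "beta"
        assert np.isfinite(fit.aic)

    def test_concurvity_reported(self):
        rng = np.random.default_rng(3)
        n = 70
        x = rng.uniform(0, 1, n)
        data = pd.DataFrame({
            "y": rng.poisson(5 + 10 * x),
            "x": x,
            "w": x + rng.normal(0, 0.01, n),  # nearly collinear with x
        })
        fit = fit_smooth_glm(data, "y", ["x", "w"], family="negative_binomial")
        assert fit.concurvity["w"] > 0.9


class TestTOST:
    def test_tight_cluster_equivalence_with_raw_bound(self):
        rng = np.random.default_rng(0)
        x = 10 + rng.normal(0, 0.01, 21)
        y = 10 + rng.normal(0, 0.01, 21)
        r = tost_paired(x, y, bound_d=0.25, bound_type="raw")
        assert r.equivalent
        assert r.df == 20

    def test_closed_form_t_statistics(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 15)
        y = rng.normal(0, 1, 15)
        r = tost_paired(x, y, bound_d=0.5)
        d = x - y
        se = d.std(ddof=1) / np.sqrt(15)
        delta = 0.5 * d.std(ddof=1)
        assert r.t_lower == pytest.approx((d.mean() + delta) / se)
        assert r.t_upper == pytest.approx((d.mean() - delta) / se)
        assert r.p == pytest.approx(
            max(sps.t.sf(r.t_lower, 14), sps.t.cdf(r.t_upper, 14))
        )

    def test_large_shift_not_equivalent(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 21)
        y = x - 2 * np.std(x - (x - 2), ddof=1)  # mean difference = +2 sd of d
        r = tost_paired(x, y, bound_d=0.25)
        assert not r.equivalent
        assert r.p > 0.5

    def test_monotone_in_bound(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0, 1, 25)
        ps = [tost_paired(x, y, bound_d=b).p for b in (0.1, 0.25, 0.5, 1.0, 2.0)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            tost_paired([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_validation(self):
        with pytest.raises(ValueError):
            tost_paired([1, 2], [1, 2])
        with pytest.raises(ValueError):
            tost_paired([1, 2, 3], [1, 2, 3.5], bound_d=-1)


class TestWilcoxon:
    def test_exact_enumeration_tiny_samples(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        # exact two-sided p by enumeration of all C(6,3)=20 assignments
        pooled = x + y
        obs = sum(sps.rankdata(pooled)[:3])
        stats = []
        for comb in itertools.combinations(range(6), 3):
            ranks = sps.rankdata(pooled)
            stats.append(sum(ranks[list(comb)]))
        extreme = np.mean([abs(s - 10.5) >= abs(obs - 10.5) for s in stats])
        assert extreme == pytest.approx(0.1)
        z, p = wilcoxon_z(x, y)
        assert abs(p - extreme) < 0.05
        assert z < 0  # first group ranks lower

    def test_identical_groups_z_zero(self):
        z, p = wilcoxon_z([1, 2, 3, 4], [4, 3, 2, 1])
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_swap_flips_sign(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 12)
        y = rng.normal(1, 1, 15)
        z1, _ = wilcoxon_z(x, y)
        z2, _ = wilcoxon_z(y, x)
        assert z1 == pytest.approx(-z2)

    def test_all_tied_undefined(self):
        z, p = wilcoxon_z([2, 2, 2], [2, 2])
        assert np.isnan(z) and np.isnan(p)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            x = rng.normal(0, 1, 20)
            y = rng.normal(0, 1, 20)
            _, p = wilcoxon_z(x, y)
            rejections += p < 0.05
        rate = rejections / n_sim
        assert 0.025 <= rate <= 0.075

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_z([], [1.0])


class TestWelch:
    def test_closed_form(self):
        t, df, p = welch_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0)

    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 2, 14)
        t1, df1, _ = welch_t(x, y)
        t2, df2, _ = welch_t(x * 3.7, y * 3.7)
        assert t1 == pytest.approx(t2)
        assert df1 == pytest.approx(df2)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 12)
        y = rng.normal(1, 3, 9)
        t, df, p = welch_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestPermutationCalibration:
    def test_gdm_null_pvalues_controlled(self):
        # under the null, p < 0.05 should be rare across simulations
        hits = 0
        n_sim = 12
        for s in range(n_sim):
            sd = make_samples(10, seed=100 + s, preds=("x",))
            rng = np.random.default_rng(200 + s)
            resp = {k: float(rng.uniform(0.2, 0.8))
                    for k in itertools.combinations(list(sd.index), 2)}
            pairs = build_site_pairs(sd, resp)
            fit = fit_gdm(pairs)
            _, p = gdm_importance(fit, pairs, n_perm=25, seed=300 + s)
            hits += p["x"] < 0.05
        assert hits / n_sim <= 0.25
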