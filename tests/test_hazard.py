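"""Cox fits, PAF, splines, joint grid and interaction statistics."""
import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import stats, optimize

from bioaccel import (fit_ph, joint_grid, multiplicative_interaction, paf,
                      rcs_basis, rcs_curve, reri_ap, reri_ap_bootstrap,
                      generate_binary_interaction_cohort, grs_tertiles,
                      quantile_categories, quantile_hr_table)
from bioaccel._cox import cox_newton, ConvergenceError


def _simple_cohort(n, beta, rng, baseline=0.01, horizon=10.0):
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-(np.log(baseline) + beta * x)))
    return pd.DataFrame({"x": x, "time": np.minimum(t, horizon),
                         "event": (t <= horizon).astype(int)})


class TestCoxSolver:
    def test_binary_covariate_matches_score_equation_oracle(self):
        """Six subjects, no ties: coefficient solves the partial-likelihood
        score equation, found independently by bracketing/bisection."""
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])

        def score(beta):
            s = 0.0
            for i in range(6):
                if event[i]:
                    risk = time >= time[i]
                    w = np.exp(beta * x[risk])
                    s += x[i] - np.sum(w * x[risk]) / np.sum(w)
            return s

        oracle = optimize.brentq(score, -5, 5, xtol=1e-12)
        res = cox_newton(x[:, None], time, event, tol=1e-12)
        assert res.coef[0] == pytest.approx(oracle, abs=1e-8)

    def test_matches_lifelines_with_ties(self, rng):
        n = 3000
        X = rng.normal(size=(n, 3))
        beta = np.array([0.5, -0.3, 0.0])
        t = rng.exponential(np.exp(-(np.log(0.05) + X @ beta)))
        t = np.ceil(t * 4) / 4  # coarse grid -> heavy ties, Efron path
        e = (t <= 8.0).astype(int)
        t = np.minimum(t, 8.0)
        res = cox_newton(X, t, e)
        df = pd.DataFrame(X, columns=["a", "b", "c"]).assign(time=t, event=e)
        ll = CoxPHFitter().fit(df, "time", "event")
        np.testing.assert_allclose(res.coef, ll.params_.values, atol=1e-6)
        np.testing.assert_allclose(res.se, ll.standard_errors_.values, atol=1e-6)

    def test_null_exposure_ci_coverage(self):
        """Two groups with identical event processes: 95% CI contains HR=1
        in at least 94 of 100 simulations."""
        cover = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            df = _simple_cohort(5000, 0.0, r)
            df["group"] = (r.uniform(size=5000) < 0.5).astype(float)
            fit = fit_ph(df, "group", adjustment=None)
            _, lo, hi = fit.hr_ci("group")
            cover += lo <= 1.0 <= hi
        assert cover >= 94

    def test_permuted_event_labels_destroy_association(self, rng):
        betas = []
        for n in (500, 5000):
            df = _simple_cohort(n, 0.6, rng)
            perm = rng.permutation(n)
            df["event"] = df["event"].to_numpy()[perm]
            df["time"] = df["time"].to_numpy()[perm]
            betas.append(abs(fit_ph(df, "x", adjustment=None).result.coef[0]))
        assert betas[1] < 0.1

    def test_error_paths(self, rng):
        df = _simple_cohort(100, 0.0, rng)
        with pytest.raises(ValueError, match="one event"):
            cox_newton(df[["x"]].to_numpy(), df["time"].to_numpy(), np.zeros(100))
        df["copy"] = df["x"]
        with pytest.raises(ValueError, match="collinear"):
            fit_ph(df, ["x", "copy"], adjustment=None)
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_ph(df, "flat", adjustment=None)


class TestPAF:
    @pytest.mark.parametrize("cases,hr,expected", [
        (3501, 2.28, 22.05),  # highest-quartile acceleration group
        (2090, 1.39, 6.58),
        (1744, 1.17, 2.84),
        (4032, 2.31, 25.65),
        (2051, 1.34, 5.84),
        (1616, 1.18, 2.77),
    ])
    def test_case_based_worked_examples(self, cases, hr, expected):
        assert paf(cases / 8915, hr) == pytest.approx(expected, abs=0.01)

    def test_null_hr_gives_zero(self):
        for pc in (0.0, 0.3, 1.0):
            assert paf(pc, 1.0) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            paf(1.2, 2.0)
        with pytest.raises(ValueError):
            paf(0.5, 0.0)


class TestRCS:
    def test_basis_matches_truncated_power_transcription(self):
        """Harrell basis equals an independent literal evaluation of the
        truncated-power formula."""
        x = np.linspace(-3, 3, 101)
        knots = np.array([-1.2, 0.1, 1.7])
        t1, t2, t3 = knots

        def plus3(v):
            return np.where(v > 0, v, 0.0) ** 3

        nonlin = (plus3(x - t1)
                  - plus3(x - t2) * (t3 - t1) / (t3 - t2)
                  + plus3(x - t3) * (t2 - t1) / (t3 - t2)) / (t3 - t1) ** 2
        B = rcs_basis(x, knots)
        np.testing.assert_allclose(B[:, 0], x, atol=1e-12)
        np.testing.assert_allclose(B[:, 1], nonlin, atol=1e-10)

    def test_basis_linear_beyond_boundary_knots(self):
        knots = np.array([-1.0, 0.0, 1.0])
        x = np.linspace(2, 5, 50)  # beyond the last knot
        B = rcs_basis(x, knots)
        # second differences of each column vanish -> linear tails
        assert np.abs(np.diff(B[:, 1], 2)).max() < 1e-9

    def test_reference_hr_is_one(self, rng):
        df = _simple_cohort(3000, 0.4, rng)
        curve = rcs_curve(df, "x", adjustment=None, grid=np.array([0.0, 1.0]))
        assert curve.hr[0] == pytest.approx(1.0, abs=1e-12)
        assert curve.p_overall < 0.01

    def test_nonlinearity_p_uniform_under_linear_truth(self):
        """With a truly linear log hazard the nonlinearity p-value is uniform
        (KS test over 200 simulations)."""
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            df = _simple_cohort(5000, 0.3, r)
            curve = rcs_curve(df, "x", adjustment=None, grid=np.array([0.0]))
            ps.append(curve.p_nonlinear)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_distinct_values(self):
        df = pd.DataFrame({"x": [0.0, 1.0] * 50, "time": np.arange(1, 101, dtype=float),
                           "event": [1, 0] * 50})
        with pytest.raises(ValueError, match="distinct"):
            rcs_curve(df, "x", adjustment=None)


def _interaction_frame(n, hr10, hr01, hr11, seed):
    df = generate_binary_interaction_cohort(n, hr10, hr01, hr11, seed=seed)
    df["both"] = ((df.expo_a == 1) & (df.expo_b == 1)).astype(float)
    df["a_only"] = ((df.expo_a == 1) & (df.expo_b == 0)).astype(float)
    df["b_only"] = ((df.expo_a == 0) & (df.expo_b == 1)).astype(float)
    return df


class TestRERI:
    def test_printed_arithmetic(self):
        # AP from reported additive-interaction numbers: RERI 0.37, joint HR 2.83
        assert round(0.37 / 2.83, 2) == 0.13
        st = reri_ap(2.0, 1.5, 1.2, np.eye(3) * 1e-4)
        assert st.reri == pytest.approx(0.3, abs=1e-12)
        assert st.ap == pytest.approx(0.15, abs=1e-12)

    def test_additivity_null(self):
        st = reri_ap(1.5 + 1.2 - 1.0, 1.5, 1.2, np.eye(3) * 1e-4)
        assert st.reri == pytest.approx(0.0, abs=1e-12)

    def test_ap_times_hr11_equals_reri(self, rng):
        for _ in range(20):
            hrs = np.exp(rng.normal(0.3, 0.4, 3))
            st = reri_ap(hrs[0], hrs[1], hrs[2], np.eye(3) * 0.01)
            assert st.ap * hrs[0] == pytest.approx(st.reri, abs=1e-12)

    def test_covariance_validation(self):
        with pytest.raises(ValueError, match="positive"):
            reri_ap(2.0, 0.0, 1.2, np.eye(3))
        with pytest.raises(ValueError, match="symmetric"):
            reri_ap(2.0, 1.5, 1.2, np.arange(9.0).reshape(3, 3))

    def test_bootstrap_variant_close_to_delta(self, rng):
        df = _interaction_frame(20_000, 1.6, 2.0, 3.4, seed=5)
        fit = fit_ph(df, ["both", "a_only", "b_only"], adjustment=None)
        hr = np.exp(fit.result.coef[:3])
        sub = fit.result.cov[:3, :3]
        delta = reri_ap(hr[0], hr[1], hr[2], sub)
        draws = rng.multivariate_normal(fit.result.coef[:3], sub, size=2000)
        boot = reri_ap_bootstrap(draws)
        assert boot.reri == pytest.approx(delta.reri, abs=0.15)
        assert boot.ap_ci[0] < delta.ap < boot.ap_ci[1]


class TestJointGrid:
    @pytest.fixture(scope="class")
    def null_grid_fit(self):
        """Null grid (all rate ratios 1): fit once at moderate n."""
        from bioaccel import SynthConfig, generate_cohort, generate_reference, KDMBioAge
        cfg = SynthConfig(n_reference=3000, n_cohort=20_000, seed=17,
                          joint_rate_ratio_grid=np.ones((3, 4)).tolist(),
                          baseline_hazard=0.01)
        rng = np.random.default_rng(17)
        ref = generate_reference(cfg, rng)
        kdm = KDMBioAge().fit(ref)
        coh = generate_cohort(cfg, kdm.params_, mode="joint_grid", rng=rng)
        coh["grs_tertile"] = grs_tertiles(coh["grs"].to_numpy())
        coh["accel_quartile"] = quantile_categories(coh["true_accel_z"].to_numpy(), 4)
        return joint_grid(coh, adjustment="model1")

    def test_reference_cell_is_identically_one(self, null_grid_fit):
        assert null_grid_fit.hr[0, 0] == 1.0

    def test_null_grid_cis_cover_one(self, null_grid_fit):
        covered = (null_grid_fit.hr_lo <= 1.0) & (1.0 <= null_grid_fit.hr_hi)
        covered[0, 0] = True
        assert covered.sum() >= 11  # at most one of the 11 free cells misses

    def test_corner_extraction_consistent(self, null_grid_fit):
        hr11, hr10, hr01, sub = null_grid_fit.corner_stats()
        assert hr11 == pytest.approx(null_grid_fit.hr[2, 3])
        assert hr10 == pytest.approx(null_grid_fit.hr[2, 0])
        assert hr01 == pytest.approx(null_grid_fit.hr[0, 3])
        assert sub.shape == (3, 3)
        assert np.all(np.linalg.eigvalsh(sub) > 0)


class TestMultiplicativeInteraction:
    def test_duplicated_exposure_flagged(self, rng):
        df = _simple_cohort(500, 0.0, rng)
        df["g"] = (df["x"] > 0).astype(float)
        with pytest.raises(ValueError, match="distinct"):
            multiplicative_interaction(df, "g", "g", adjustment=None)

    def test_strong_product_effect_detected(self):
        df = _interaction_frame(20_000, 1.3, 1.3, 4.0, seed=3)  # far above multiplicative
        p, _ = multiplicative_interaction(df, "expo_a", "expo_b", adjustment=None)
        assert p < 0.01

    def test_null_p_uniform(self):
        """Multiplicative rate ratios: product-term p is uniform under the null."""
        ps = []
        for seed in range(100):
            df = _interaction_frame(4000, 1.5, 2.0, 3.0, seed=seed)  # 3.0 = 1.5 x 2.0
            p, _ = multiplicative_interaction(df, "expo_a", "expo_b", adjustment=None)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_quantile_hr_table_shape_and_wiring(cohort, kdm_fitted):
    from bioaccel import build_accel_table
    coh = cohort.copy()
    coh["bioage"] = kdm_fitted.predict(coh)
    coh["phenoage"] = coh["bioage"]
    tab = build_accel_table(coh, ba_cols=("bioage",)).table
    out = quantile_hr_table(tab, "bioage_accel_z", "bioage_accel_q",
                            adjustments=("model1", "model2"))
    assert list(out["group"]) == ["Q1", "Q2", "Q3", "Q4", "per_sd"]
    assert out.loc[0, "hr_model2"] == 1.0 and np.isnan(out.loc[0, "paf_pct"])
    # PAF wiring: recompute from the table's own cases and HRs
    total = out.loc[out["group"] != "per_sd", "cases"].sum()
    for i in (1, 2, 3):
        expected = paf(out.loc[i, "cases"] / total, out.loc[i, "hr_model2"])
        assert out.loc[i, "paf_pct"] == pytest.approx(expected, abs=1e-12)
    # per-SD row equals a standalone fit
    fit = fit_ph(tab, "bioage_accel_z", "model2")
    assert out.loc[4, "hr_model2"] == pytest.approx(fit.hr("bioage_accel_z"))
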