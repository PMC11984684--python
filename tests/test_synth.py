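"""Synthetic-cohort generator: determinism, trends, hazards, missingness."""
import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import multivariate_logrank_test

from bioaccel import (KDMBioAge, SynthConfig, generate_cohort, generate_reference,
                      inject_missingness, quantile_categories)
from bioaccel.synth import BIOMARKERS


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="positive"):
            SynthConfig(n_reference=0)
        with pytest.raises(ValueError, match="age range"):
            SynthConfig(age_range=(60, 60))
        with pytest.raises(ValueError, match="3x4"):
            SynthConfig(joint_rate_ratio_grid=[[1.0]])
        with pytest.raises(ValueError, match="reference cell"):
            SynthConfig(joint_rate_ratio_grid=(2 * np.ones((3, 4))).tolist())

    def test_yaml_round_trip(self):
        cfg = SynthConfig(n_reference=100, n_cohort=200, seed=9)
        back = SynthConfig.from_yaml(cfg.to_yaml())
        assert back == cfg


class TestDeterminism:
    def test_same_seed_identical_tables(self, small_config, kdm_fitted):
        a = generate_reference(small_config)
        b = generate_reference(small_config)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()  # byte-identical serialization
        c1 = generate_cohort(small_config, kdm_fitted.params_)
        c2 = generate_cohort(small_config, kdm_fitted.params_)
        assert c1.to_csv() == c2.to_csv()

    def test_different_seed_differs(self, small_config):
        other = SynthConfig(**{**small_config.truth_dict(), "seed": 8})
        assert not generate_reference(other).equals(generate_reference(small_config))


class TestReference:
    def test_noise_free_biomarkers_exactly_linear(self):
        cfg = SynthConfig(n_reference=500, n_cohort=10, seed=1, frailty_strength=0.0)
        for per_sex in cfg.biomarker_models.values():
            for m in per_sex.values():
                m["sd"] = 0.0
        ref = generate_reference(cfg)
        for sex in ("female", "male"):
            sub = ref[ref.sex == sex]
            m = cfg.biomarker_models["sbp"][sex]
            np.testing.assert_allclose(
                sub["sbp"], m["intercept"] + m["slope"] * sub["age"], atol=1e-9)

    def test_positive_slope_gives_positive_age_correlation(self):
        cfg = SynthConfig(n_reference=10_000, n_cohort=10, seed=2)
        ref = generate_reference(cfg)
        assert np.corrcoef(ref["age"], ref["sbp"])[0, 1] > 0

    def test_structure_invariants(self, reference):
        assert reference[BIOMARKERS].notna().all().all()
        assert np.isfinite(reference[BIOMARKERS].to_numpy()).all()
        assert set(reference["sex"]) == {"female", "male"}
        assert reference["time"].gt(0).all()
        assert set(reference["event"].unique()) <= {0, 1}
        assert reference["age"].between(*reference["age"].agg(["min", "max"])).all()


class TestCohortHazards:
    def test_null_acceleration_effect_logrank_nonsignificant(self):
        cfg = SynthConfig(n_reference=3000, n_cohort=5000, seed=3,
                          true_loghr_per_sd_accel=0.0,
                          grs_loghr_per_point=0.0,
                          behavior_direct_loghr_per_10pt=0.0)
        rng = np.random.default_rng(3)
        ref = generate_reference(cfg, rng)
        kdm = KDMBioAge().fit(ref)
        coh = generate_cohort(cfg, kdm.params_, rng=rng)
        q = quantile_categories(coh["true_accel_z"].to_numpy(), 4)
        res = multivariate_logrank_test(coh["time"], q, coh["event"])
        assert res.p_value > 0.01

    def test_joint_grid_cell_rate_ratio_converges(self):
        """Crude person-time incidence ratio of the top corner cell approaches
        its configured value (2.69) and the error shrinks with n."""
        errors = {}
        for n in (40_000, 200_000):
            cfg = SynthConfig(n_reference=3000, n_cohort=n, seed=4)
            rng = np.random.default_rng(4)
            ref = generate_reference(cfg, rng)
            kdm = KDMBioAge().fit(ref)
            coh = generate_cohort(cfg, kdm.params_, mode="joint_grid", rng=rng)
            top = (coh.true_grs_tertile == 2) & (coh.true_accel_quartile == 3)
            refc = (coh.true_grs_tertile == 0) & (coh.true_accel_quartile == 0)
            irr = ((coh.event[top].sum() / coh.time[top].sum())
                   / (coh.event[refc].sum() / coh.time[refc].sum()))
            errors[n] = abs(irr - 2.69)
        assert errors[200_000] < 0.15 * 2.69
        assert errors[200_000] <= errors[40_000] + 0.05

    def test_degenerate_horizon_censors_everyone(self, small_config, kdm_fitted):
        cfg = SynthConfig(**{**small_config.truth_dict(), "censor_horizon": 1e-4})
        coh = generate_cohort(cfg, kdm_fitted.params_)
        assert coh["event"].sum() <= 2
        assert coh["time"].gt(0).all()

    def test_requires_fitted_kdm_and_known_mode(self, small_config, kdm_fitted):
        with pytest.raises(ValueError, match="KDM"):
            generate_cohort(small_config, None)
        with pytest.raises(ValueError, match="mode"):
            generate_cohort(small_config, kdm_fitted.params_, mode="bogus")

    def test_dosages_and_follow_up_invariants(self, cohort):
        snp_cols = [c for c in cohort.columns if c.startswith("snp_")]
        assert len(snp_cols) == 12
        d = cohort[snp_cols].to_numpy()
        assert ((d >= 0) & (d <= 2)).all()
        assert cohort["time"].gt(0).all()
        assert set(cohort["event"].unique()) <= {0, 1}

    def test_acceleration_is_recoverable_from_biomarkers(self, cohort, kdm_fitted):
        """The latent acceleration is realized in the panel, not a hidden column."""
        from bioaccel import residual_acceleration, standardize
        ba = kdm_fitted.predict(cohort)
        z = standardize(residual_acceleration(ba, cohort["age"].to_numpy()))
        assert np.corrcoef(z, cohort["true_accel_z"])[0, 1] > 0.99


class TestMissingness:
    def test_rate_zero_unchanged(self, cohort):
        out = inject_missingness(cohort, 0.0)
        pd.testing.assert_frame_equal(out, cohort)

    def test_cap_enforced(self, cohort):
        out = inject_missingness(cohort.head(2000), rate=0.3, max_missing_per_subject=1, seed=1)
        assert out[BIOMARKERS].isna().sum(axis=1).max() <= 1

    def test_count_matches_binomial_oracle(self, cohort):
        """rate 0.05, cap 1, 9 columns: expected missing rows follow the
        documented flag-then-thin scheme, P(row hit) = 1 - 0.95^9."""
        n, rate, cols = 1000, 0.05, BIOMARKERS[:9]
        out = inject_missingness(cohort.head(n), rate=rate,
                                 max_missing_per_subject=1, seed=2, columns=cols)
        observed = int(out[cols].isna().sum().sum())
        p_row = 1 - (1 - rate) ** len(cols)
        expected = n * p_row
        sd = np.sqrt(n * p_row * (1 - p_row))
        assert abs(observed - expected) <= 3 * sd

    def test_rate_validation(self, cohort):
        with pytest.raises(ValueError, match="rate"):
            inject_missingness(cohort, 1.5)
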