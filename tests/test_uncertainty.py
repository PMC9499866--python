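"""Correlation estimation, PSD repair, resampling CIs, delta method, sex tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genedaly.attribution import AttributionConfig, allele_level_set, attributable_fraction
from genedaly.uncertainty import (
    ResampleConfig,
    daly_gradient,
    delta_method_disease_ci,
    estimate_logHR_correlation,
    nearest_psd_repair,
    resample_total_dalys,
    sex_difference_test,
)


def _null_estimates(log_hr_matrix, disease_ids, se=0.05):
    """Estimate table + shrinkage table marking every pair null."""
    n_exp, n_dis = log_hr_matrix.shape
    est = pd.DataFrame(
        {
            "exposure_id": np.repeat([f"e{i}" for i in range(n_exp)], n_dis),
            "disease_id": disease_ids * n_exp,
            "log_hr": log_hr_matrix.ravel(),
            "se": se,
        }
    )
    shr = est[["exposure_id", "disease_id"]].copy()
    shr["null_prob"] = 1.0
    shr["retained"] = False
    return est, shr


class TestCorrelationEstimation:
    def test_independent_noise_gives_near_zero_off_diagonals(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(0, 0.05, size=(400, 4))
        est, shr = _null_estimates(mat, ["a", "b", "c", "d"])
        C = estimate_logHR_correlation(est, shr).C
        off = C[~np.eye(4, dtype=bool)]
        assert (np.abs(off) < 3 / np.sqrt(400)).mean() >= 0.95

    def test_recovers_known_noise_correlation(self):
        rng = np.random.default_rng(1)
        cov = 0.05**2 * np.array([[1.0, 0.5], [0.5, 1.0]])
        mat = rng.multivariate_normal([0, 0], cov, size=2_000)
        est, shr = _null_estimates(mat, ["a", "b"])
        C = estimate_logHR_correlation(est, shr).C
        assert C[0, 1] == pytest.approx(0.5, abs=0.06)

    def test_duplicated_disease_column_has_unit_correlation(self):
        rng = np.random.default_rng(2)
        col = rng.normal(0, 0.05, size=(100, 1))
        est, shr = _null_estimates(np.hstack([col, col]), ["a", "b"])
        C = estimate_logHR_correlation(est, shr).C
        assert C[0, 1] == pytest.approx(1.0)

    def test_entries_below_support_floor_are_zeroed(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(0, 0.05, size=(5, 2))
        est, shr = _null_estimates(mat, ["a", "b"])
        C = estimate_logHR_correlation(est, shr, min_pairs=10).C
        assert C[0, 1] == 0.0

    def test_fewer_than_two_diseases_rejected(self):
        est, shr = _null_estimates(np.zeros((20, 1)) + 0.01, ["a"])
        with pytest.raises(ValueError):
            estimate_logHR_correlation(est, shr, disease_ids=["a"])


class TestPsdRepair:
    def test_identity_and_psd_inputs_pass_through(self):
        I3 = np.eye(3)
        np.testing.assert_allclose(nearest_psd_repair(I3), I3)
        C = np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.0]])
        np.testing.assert_allclose(nearest_psd_repair(C), C, atol=1e-12)

    def test_indefinite_matrix_repaired_with_bounded_change(self):
        C = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        w = np.linalg.eigvalsh(C)
        assert w.min() < 0
        fixed = nearest_psd_repair(C)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-10
        np.testing.assert_allclose(np.diag(fixed), 1.0)
        assert np.abs(fixed - C).max() <= abs(w.min()) + 1e-8

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            nearest_psd_repair(np.array([[1.0, 0.2], [0.4, 1.0]]))


@pytest.fixture
def single_disease_setup():
    levels = allele_level_set(0.3, [0.3], ["d"])
    cfg = AttributionConfig(life_expectancy=80.0)
    return levels, cfg


class TestResampling:
    def test_vanishing_se_collapses_ci_to_point(self, single_disease_setup):
        levels, cfg = single_disease_setup
        res = resample_total_dalys(
            np.array([0.3]),
            np.array([1e-12]),
            np.eye(1),
            levels,
            np.array([1000.0]),
            ResampleConfig(n_draws=500, seed=0),
            cfg,
        )
        assert res["ind"]["ci_high"] - res["ind"]["ci_low"] < 1e-9
        assert res["ind"]["ci_low"] == pytest.approx(res["ind"]["total"], abs=1e-9)

    def test_single_disease_percentiles_match_closed_form_transform(self, single_disease_setup):
        # the log HR -> individual DALY map is monotone, so the percentile CI
        # must equal the map applied to beta_hat +- 1.96 se
        levels, cfg = single_disease_setup
        b, se, rate = 0.3, 0.05, 1000.0
        res = resample_total_dalys(
            np.array([b]),
            np.array([se]),
            np.eye(1),
            levels,
            np.array([rate]),
            ResampleConfig(n_draws=10_000, seed=1),
            cfg,
        )

        def ind_dalys(bb):
            lv = allele_level_set(0.3, [bb], ["d"])
            afp = attributable_fraction(lv, "d")
            return afp * rate / (100_000 * lv.exposed_fraction) * 80.0

        lo = ind_dalys(b - 1.959964 * se)
        hi = ind_dalys(b + 1.959964 * se)
        assert res["ind"]["ci_low"] == pytest.approx(lo, rel=0.03)
        assert res["ind"]["ci_high"] == pytest.approx(hi, rel=0.03)

    def test_non_psd_covariance_and_tiny_b_rejected(self, single_disease_setup):
        levels, cfg = single_disease_setup
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="repair"):
            resample_total_dalys(
                np.array([0.1, 0.1]), np.array([0.05, 0.05]), bad, levels,
                np.array([1000.0, 1000.0]), ResampleConfig(n_draws=500, seed=0), cfg,
            )
        with pytest.raises(ValueError):
            ResampleConfig(n_draws=50, seed=0)

    def test_identity_correlation_matches_independent_resampling(self, single_disease_setup):
        # totals drawn with C = I must be distributed like totals computed
        # from independently resampled per-disease log HRs
        _, cfg = single_disease_setup
        levels = allele_level_set(0.3, [0.2, 0.1], ["a", "b"])
        b = np.array([0.2, 0.1])
        se = np.array([0.05, 0.08])
        rates = np.array([1000.0, 500.0])
        res = resample_total_dalys(
            b, se, np.eye(2), levels, rates, ResampleConfig(n_draws=4_000, seed=2), cfg
        )
        rng = np.random.default_rng(3)
        draws = rng.normal(b, se, size=(4_000, 2))
        hr = np.exp(np.arange(3)[None, None, :] * draws[:, :, None])
        S = hr @ levels.P
        Sp = hr @ levels.P_prime
        pop = (S - Sp) / S * rates[None, :]
        ind = pop.sum(axis=1) / (100_000 * levels.exposed_fraction) * 80.0
        assert stats.ks_2samp(res["ind"]["draws"], ind).pvalue > 0.01


class TestDeltaMethod:
    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        cfg = AttributionConfig(life_expectancy=80.0)
        for _ in range(20):
            maf = rng.uniform(0.02, 0.5)
            b = rng.uniform(-0.8, 0.8)
            rate = rng.uniform(10, 5_000)
            levels = allele_level_set(maf, [b], ["d"])

            def ind(bb):
                e = np.exp(np.arange(3) * bb)
                afp = (levels.P @ e - levels.P_prime @ e) / (levels.P @ e)
                return afp * rate / (100_000 * levels.exposed_fraction) * 80.0

            h = 1e-6
            fd = (ind(b + h) - ind(b - h)) / (2 * h)
            _, grad = daly_gradient(b, levels, rate, cfg)
            assert grad == pytest.approx(fd, rel=1e-6)

    def test_zero_se_gives_zero_width_and_width_linear_in_se(self):
        cfg = AttributionConfig(life_expectancy=80.0)
        levels = allele_level_set(0.3, [0.3], ["d"])
        with pytest.raises(ValueError):
            delta_method_disease_ci(levels, 0.3, 0.0, 1000.0, cfg)
        w1 = delta_method_disease_ci(levels, 0.3, 1e-4, 1000.0, cfg)
        w2 = delta_method_disease_ci(levels, 0.3, 2e-4, 1000.0, cfg)
        width1 = w1["ind"]["ci_high"] - w1["ind"]["ci_low"]
        width2 = w2["ind"]["ci_high"] - w2["ind"]["ci_low"]
        assert width2 == pytest.approx(2 * width1, rel=1e-6)

    def test_agrees_with_resampling_for_small_se(self, single_disease_setup):
        levels, cfg = single_disease_setup
        b, se, rate = 0.3, 0.01, 1000.0
        delta = delta_method_disease_ci(levels, b, se, rate, cfg)
        res = resample_total_dalys(
            np.array([b]), np.array([se]), np.eye(1), levels, np.array([rate]),
            ResampleConfig(n_draws=20_000, seed=5), cfg,
        )
        for bound in ("ci_low", "ci_high"):
            assert res["ind"][bound] == pytest.approx(delta["ind"][bound], rel=0.05)


class TestSexDifference:
    def test_identical_totals_give_zero_z_unit_p(self):
        z, p = sex_difference_test(0.2, 0.05, 0.2, 0.05)
        assert z == 0.0 and p == 1.0

    def test_clear_difference_is_significant_in_the_right_direction(self):
        z, p = sex_difference_test(0.27, 0.015, 0.05, 0.01)
        assert z > 0 and p < 1e-10

    def test_swapping_strata_flips_sign_only(self):
        z1, p1 = sex_difference_test(0.3, 0.02, 0.1, 0.03)
        z2, p2 = sex_difference_test(0.1, 0.03, 0.3, 0.02)
        assert z2 == pytest.approx(-z1)
        assert p2 == pytest.approx(p1)

    def test_missing_sds_rejected(self):
        with pytest.raises(ValueError):
            sex_difference_test(0.2, np.nan, 0.1, 0.05)
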