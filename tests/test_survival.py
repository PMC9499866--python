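"""Cox fits, exposure encodings, meta-analysis, composite mortality score."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from genedaly.survival import (
    Estimate,
    composite_linear_predictor,
    encode_exposure,
    fit_cox,
    meta_fixed_effects,
)
from genedaly.synthetic_data import (
    CohortConfig,
    Cohort,
    EffectMatrix,
    ExposureSpec,
    generate_cohort,
    hazard_for_incidence,
    null_effects,
)


class TestEncodeExposure:
    def test_top_decile_of_1_to_100_flags_exactly_ten(self):
        out = encode_exposure(np.arange(1, 101), "top_quantile", q=0.10)
        assert out.sum() == 10
        assert out[-10:].all() and not out[:-10].any()

    def test_additive_dosage_passthrough_and_carrier(self):
        dosages = np.array([0.0, 1.0, 2.0, 0.0])
        np.testing.assert_array_equal(encode_exposure(dosages, "additive_dosage"), dosages)
        np.testing.assert_array_equal(encode_exposure(dosages, "carrier"), [0, 1, 1, 0])

    def test_top_decile_threshold_near_normal_quantile(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20_000)
        flags = encode_exposure(x, "top_quantile", q=0.10)
        threshold = x[flags == 1].min()
        assert threshold == pytest.approx(stats.norm.ppf(0.9), abs=0.05)

    def test_empty_input_and_bad_quantile_rejected(self):
        with pytest.raises(ValueError):
            encode_exposure(np.array([]), "additive_dosage")
        with pytest.raises(ValueError):
            encode_exposure(np.ones(5), "top_quantile", q=1.5)


class TestFitCox:
    def test_recovers_generative_log_hazard_ratio(self, recovery_cohort):
        cohort, effects = recovery_cohort
        est = fit_cox(cohort, "e0", "d0")
        assert est.status == "ok"
        assert abs(est.log_hr - 0.30) < 3 * est.se

    def test_permuted_exposure_is_null_calibrated(self, recovery_cohort):
        cohort, _ = recovery_cohort
        sub = Cohort(
            cohort.data.iloc[:10_000].reset_index(drop=True), cohort.exposure_ids, cohort.disease_ids
        )
        rng = np.random.default_rng(11)
        for _ in range(10):
            perm = rng.permutation(sub.data["e0"].to_numpy())
            est = fit_cox(sub, "e0", "d0", exposure_values=perm)
            assert abs(est.log_hr / est.se) < 4

    def test_matches_brute_force_partial_likelihood_on_tiny_dataset(self):
        # six individuals, untied event ages; the exposure coefficient must
        # maximize the hand-written Cox partial likelihood
        import pandas as pd

        times = np.array([2.0, 3.0, 5.0, 7.0, 8.0, 9.0])
        events = np.array([1, 0, 1, 1, 0, 1])
        x = np.array([1.0, 0.0, 2.0, 0.0, 1.0, 1.0])
        data = pd.DataFrame(
            {
                "id": range(6),
                "sex": 0,
                "entry_age": 0.0,
                "exit_age": times,
                "event_d0": np.where(events == 1, times, np.nan),
                "e0": x,
            }
        )
        cohort = Cohort(data, ["e0"], ["d0"])

        def neg_pl(beta):
            ll = 0.0
            for i in np.flatnonzero(events):
                at_risk = times >= times[i]
                ll += beta * x[i] - np.log(np.exp(beta * x[at_risk]).sum())
            return -ll

        oracle = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded").x
        est = fit_cox(cohort, "e0", "d0", covariates=())
        assert est.log_hr == pytest.approx(oracle, abs=1e-4)

    def test_invariant_to_id_relabeling_and_age_shift(self):
        eff = EffectMatrix(np.array([[0.4]]), np.array([[False]]), np.array([1.0]))
        cfg = CohortConfig(
            5_000, [ExposureSpec("e0", "allele_dosage", 0.3)], 1, hazard_for_incidence(0.2, 80.0), seed=13
        )
        cohort = generate_cohort(cfg, eff)
        base = fit_cox(cohort, "e0", "d0")

        shuffled = cohort.data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled["id"] = np.arange(len(shuffled))
        est_shuffled = fit_cox(Cohort(shuffled, ["e0"], ["d0"]), "e0", "d0")
        assert est_shuffled.log_hr == pytest.approx(base.log_hr, abs=1e-8)

        shifted = cohort.data.copy()
        for col in ("entry_age", "exit_age", "event_d0", "death_age"):
            shifted[col] = shifted[col] + 5.0
        shifted["entry_age"] = 0.0  # pure timescale shift with proportional baseline
        est_shifted = fit_cox(Cohort(shifted, ["e0"], ["d0"]), "e0", "d0")
        assert est_shifted.log_hr == pytest.approx(base.log_hr, abs=1e-6)

    def test_rare_outcome_hazard_ratio_approximates_risk_ratio(self):
        b = 0.5
        eff = EffectMatrix(np.array([[b]]), np.array([[False]]), np.array([1.0]))
        cfg = CohortConfig(
            200_000,
            [ExposureSpec("e0", "burden", 0.3)],
            1,
            hazard_for_incidence(0.015, 80.0),
            death_hazard=1e-6,
            seed=17,
        )
        cohort = generate_cohort(cfg, eff)
        carrier = cohort.data["e0"] == 1
        risk = cohort.data["event_d0"].notna()
        rr = risk[carrier].mean() / risk[~carrier].mean()
        est = fit_cox(cohort, "e0", "d0")
        assert np.exp(est.log_hr) == pytest.approx(rr, rel=0.05)

    def test_non_estimable_pairs_flagged_not_dropped(self):
        cfg = CohortConfig(500, [ExposureSpec("e0", "allele_dosage", 0.2)], 1, 1e-7, seed=19)
        cohort = generate_cohort(cfg, null_effects(1, 1))
        est = fit_cox(cohort, "e0", "d0")
        assert est.status == "too_few_events"

        cohort.data["e0"] = 1.0
        cohort.data["event_d0"] = np.where(np.arange(500) < 50, 30.0, np.nan)
        est = fit_cox(cohort, "e0", "d0")
        assert est.status == "constant_exposure"


class TestMetaAnalysis:
    def test_identical_inputs_shrink_se_by_sqrt2(self):
        e = Estimate("e", "d", 0.2, 0.1)
        combined = meta_fixed_effects([e, e])
        assert combined.log_hr == pytest.approx(0.2)
        assert combined.se == pytest.approx(0.1 / np.sqrt(2))

    def test_hand_computed_weights(self):
        # weights (100, 25): combined = (100*0.1 + 25*0.3)/125 = 0.14,
        # se = 125^-0.5 = 0.08944
        a = Estimate("e", "d", 0.1, 0.1)
        b = Estimate("e", "d", 0.3, 0.2)
        combined = meta_fixed_effects([a, b])
        assert combined.log_hr == pytest.approx(0.14)
        assert combined.se == pytest.approx(0.0894, abs=5e-4)

    def test_single_estimate_unchanged_and_mixed_keys_rejected(self):
        e = Estimate("e", "d", 0.2, 0.1)
        assert meta_fixed_effects([e]) is e
        with pytest.raises(ValueError):
            meta_fixed_effects([e, Estimate("e", "other", 0.2, 0.1)])

    def test_combined_se_never_exceeds_smallest_input(self):
        rng = np.random.default_rng(3)
        ests = [Estimate("e", "d", rng.normal(), rng.uniform(0.05, 0.5)) for _ in range(5)]
        assert meta_fixed_effects(ests).se <= min(e.se for e in ests)


@pytest.fixture(scope="module")
def score_cohort():
    # two score exposures; only the first raises death hazard
    effects = EffectMatrix(
        np.array([[0.05], [0.05]]), np.array([[False], [False]]), np.array([1.0, 1.0])
    )
    cfg = CohortConfig(
        20_000,
        [ExposureSpec("s0", "score"), ExposureSpec("s1", "score")],
        1,
        0.0005,
        death_hazard=0.004,
        seed=23,
    )
    cohort = generate_cohort(cfg, effects)
    # overwrite death with a score-dependent exponential process
    rng = np.random.default_rng(24)
    rate = 0.004 * np.exp(0.3 * cohort.data["s0"].to_numpy())
    death = rng.exponential(1.0 / rate)
    cohort.data["death_age"] = np.where(death <= 80.0, death, np.nan)
    cohort.data["exit_age"] = np.minimum(death, 80.0)
    return cohort


class TestCompositeScore:
    def test_single_score_predictor_is_rank_identical(self, score_cohort):
        lp = composite_linear_predictor(score_cohort, ["s0"])
        assert stats.spearmanr(lp, score_cohort.data["s0"]).statistic == pytest.approx(1.0)

    def test_null_score_coefficient_near_zero(self, score_cohort):
        import warnings
        from lifelines import CoxPHFitter
        import pandas as pd

        df = score_cohort.data
        died = df["death_age"].notna()
        model = pd.DataFrame(
            {
                "T": np.where(died, df["death_age"], df["exit_age"]),
                "E": died.astype(int),
                "s0": df["s0"],
                "s1": df["s1"],
                "sex": df["sex"],
            }
        )
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(model, duration_col="T", event_col="E")
        assert abs(cph.params_["s1"]) < 3 * cph.standard_errors_["s1"]
        assert cph.params_["s0"] == pytest.approx(0.3, abs=3 * cph.standard_errors_["s0"])

    def test_top_decile_of_composite_has_elevated_death_hazard(self, score_cohort):
        lp = composite_linear_predictor(score_cohort, ["s0", "s1"])
        flags = encode_exposure(lp, "top_quantile", q=0.10)
        # refit death on the dichotomized composite directly
        import warnings
        import pandas as pd
        from lifelines import CoxPHFitter

        df = score_cohort.data
        died = df["death_age"].notna()
        model = pd.DataFrame(
            {"T": np.where(died, df["death_age"], df["exit_age"]), "E": died.astype(int), "top": flags}
        )
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(model, duration_col="T", event_col="E")
        assert np.exp(cph.params_["top"]) > 1.0

    def test_no_deaths_raises(self):
        cfg = CohortConfig(200, [ExposureSpec("s0", "score")], 1, 0.001, death_hazard=1e-9, seed=29)
        cohort = generate_cohort(cfg, null_effects(1, 1))
        cohort.data["death_age"] = np.nan
        with pytest.raises(ValueError, match="no deaths"):
            composite_linear_predictor(cohort, ["s0"])
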