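"""Estimation pipeline: sensitivities, contrasts, oversampling, volumes."""

import itertools

import numpy as np
import pandas as pd
import pytest

from circlequest.agents import default_cohort_config, simulate_cohort
from circlequest.analysis import (
    cliffs_delta,
    cohens_d,
    fit_choice_sensitivities,
    group_contrast,
    icv_adjust,
    oversampling_metrics,
    uncertainty_estimation_accuracy,
    volume_sensitivity_regression,
)


def simulate_choices(rng, n, betas, subject_id="s1"):
    """Logistic choices on a crossed reward x EE design."""
    reward = rng.choice([40, 65, 90, 115], n)
    ee = rng.choice([20, 33, 58, 74, 92], n)
    zr = (reward - reward.mean()) / reward.std()
    zu = (ee - ee.mean()) / ee.std()
    logit = betas[0] + betas[1] * zr + betas[2] * zu
    p = 1 / (1 + np.exp(-logit))
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "reward": reward,
            "ee": ee,
            "accepted": rng.random(n) < p,
        }
    )


class TestChoiceSensitivities:
    def test_asymptotic_recovery(self, rng):
        truth = (0.4, 1.2, -1.5)
        choices = simulate_choices(rng, 10_000, truth)
        fit = fit_choice_sensitivities(choices, "exp2").iloc[0]
        assert fit["intercept"] == pytest.approx(truth[0], abs=0.1)
        assert fit["reward"] == pytest.approx(truth[1], abs=0.1)
        assert fit["uncertainty"] == pytest.approx(truth[2], abs=0.1)
        assert fit["converged"] and not fit["separation"]

    def test_null_reward_ci_covers_zero(self, rng):
        """Nominal coverage of the reward-sensitivity confidence interval."""
        covered = 0
        reps = 40
        for _ in range(reps):
            choices = simulate_choices(rng, 200, (0.3, 0.0, -1.0))
            fit = fit_choice_sensitivities(choices, "exp2").iloc[0]
            lo = fit["reward"] - 1.96 * fit["se_reward"]
            hi = fit["reward"] + 1.96 * fit["se_reward"]
            covered += lo <= 0 <= hi
        assert covered / reps >= 0.85

    def test_deterministic_rule_raises_separation_flag(self, rng):
        choices = simulate_choices(rng, 120, (0, 1, -1))
        choices["accepted"] = choices["reward"] > choices["reward"].median()
        fit = fit_choice_sensitivities(choices, "exp2").iloc[0]
        assert fit["separation"]
        assert np.isfinite(fit["reward"])  # Firth fallback keeps it finite

    def test_all_accept_subject_flagged_not_fit(self, rng):
        choices = simulate_choices(rng, 50, (0, 1, -1))
        choices["accepted"] = True
        fit = fit_choice_sensitivities(choices, "exp2").iloc[0]
        assert not fit["converged"]
        assert np.isnan(fit["reward"])

    def test_estimation_invariant_to_row_order(self, rng):
        choices = simulate_choices(rng, 500, (0.2, 1.0, -1.2))
        fit1 = fit_choice_sensitivities(choices, "exp2").iloc[0]
        shuffled = choices.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = fit_choice_sensitivities(shuffled, "exp2").iloc[0]
        assert fit1["reward"] == pytest.approx(fit2["reward"], abs=1e-6)


class TestEstimationAccuracy:
    def test_perfect_rater_slope(self):
        ee = np.array([10.0, 30, 50, 70, 90] * 4)
        conf = pd.DataFrame(
            {"subject_id": "s1", "ee": ee, "confidence": 100 - ee}
        )
        out = uncertainty_estimation_accuracy(conf)
        # z-scored sign-flipped confidence on EE: slope = 1/sd(EE), R^2 = 1
        assert out["slope"].iloc[0] == pytest.approx(1.0 / ee.std(), rel=1e-9)
        assert out["r2"].iloc[0] == pytest.approx(1.0)

    def test_flat_rater_slope_near_zero(self, rng):
        conf = pd.DataFrame(
            {
                "subject_id": "s1",
                "ee": rng.uniform(10, 90, 100),
                "confidence": 60 + rng.normal(0, 5, 100),
            }
        )
        out = uncertainty_estimation_accuracy(conf)
        assert abs(out["slope"].iloc[0]) < 0.05

    def test_zero_ee_variance_rejected(self):
        conf = pd.DataFrame(
            {"subject_id": "s1", "ee": [50.0] * 5, "confidence": [1, 2, 3, 4, 5]}
        )
        with pytest.raises(ValueError, match="variance"):
            uncertainty_estimation_accuracy(conf)


class TestGroupContrast:
    def test_identical_groups_null(self):
        vals = np.r_[np.arange(8.0), np.arange(8.0)]
        groups = np.r_[["a"] * 8, ["b"] * 8]
        c = group_contrast(vals, groups)
        assert c.p_value > 0.9
        assert abs(c.effect_size) < 1e-9

    def test_cliffs_delta_complete_dominance(self):
        assert cliffs_delta(np.array([1.0, 2, 3]), np.array([4.0, 5, 6])) == -1.0
        assert cliffs_delta(np.array([4.0, 5, 6]), np.array([1.0, 2, 3])) == 1.0

    def test_ranksum_matches_permutation_enumeration(self):
        """Exact rank-sum p on a 5-vs-5 fixture by exhausting assignments."""
        a = np.array([1.2, 2.5, 3.1, 4.7, 5.0])
        b = np.array([2.0, 3.3, 6.1, 7.2, 8.4])
        c = group_contrast(np.r_[a, b], np.r_[["a"] * 5, ["b"] * 5],
                           normality_alpha=1.0)  # force the rank path
        pooled = np.r_[a, b]
        ranks = pooled.argsort().argsort() + 1
        observed = ranks[:5].sum()
        null = [
            sum(comb)
            for comb in itertools.combinations(ranks, 5)
        ]
        mean_null = np.mean(null)
        p_exact = np.mean(
            [abs(s - mean_null) >= abs(observed - mean_null) - 1e-12 for s in null]
        )
        assert c.test == "ranksum"
        assert c.p_value == pytest.approx(p_exact, abs=0.02)

    def test_degenerate_variance_uses_rank_path(self):
        vals = np.r_[[3.0] * 5, [1.0, 2, 3, 4, 5]]
        groups = np.r_[["a"] * 5, ["b"] * 5]
        assert group_contrast(vals, groups).test == "ranksum"


class TestOversampling:
    @pytest.fixture(scope="class")
    def exp1_tables(self):
        cfg = default_cohort_config(n_per_group=2, seed=31)
        return simulate_cohort(cfg, "exp1")

    def test_lesion_cohort_oversamples(self, exp1_tables):
        cells, index = oversampling_metrics(exp1_tables["sampling"])
        by_group = cells.groupby("group")["mean_deviation"].mean()
        assert by_group["lesion"] > by_group["control"]
        # cost-blind sampling -> larger deviation at high cost
        lesion = cells[cells["group"] == "lesion"]
        assert (
            lesion[lesion["cost_level"] == "high"]["mean_deviation"].mean()
            > lesion[lesion["cost_level"] == "low"]["mean_deviation"].mean()
        )

    def test_cost_sensitivity_index_separates_groups(self, exp1_tables):
        _, index = oversampling_metrics(exp1_tables["sampling"])
        by_group = index.groupby("group")["cost_sensitivity_index"].mean()
        assert by_group["control"] > by_group["lesion"]


class TestVolumes:
    def test_icv_identity_at_mean_and_zero_slope(self):
        df = pd.DataFrame({"volume": [3000.0, 3200], "icv": [1.5e6, 1.5e6]})
        out = icv_adjust(df, reference_slope=0.002, reference_mean_icv=1.5e6)
        assert out["adjusted_volume"].tolist() == [3000.0, 3200.0]
        out = icv_adjust(
            pd.DataFrame({"volume": [3000.0, 3200], "icv": [1.4e6, 1.6e6]}),
            reference_slope=0.0,
            reference_mean_icv=1.5e6,
        )
        assert out["adjusted_volume"].tolist() == [3000.0, 3200.0]

    def test_adjustment_decorrelates_from_icv(self, rng):
        icv = rng.normal(1.5e6, 1.2e5, 200)
        vol = 3000 + 0.002 * (icv - icv.mean()) + rng.normal(0, 40, 200)
        df = pd.DataFrame({"volume": vol, "icv": icv})
        out = icv_adjust(df)
        r = np.corrcoef(out["adjusted_volume"], icv)[0, 1]
        assert abs(r) < 0.1

    def test_robust_regression_recovers_noise_free_slope(self):
        vol = np.linspace(2500, 3500, 20)
        sens = 0.004 * vol - 9.0
        out = volume_sensitivity_regression(vol, sens)
        assert out["slope"] == pytest.approx(0.004, rel=1e-6)
        assert out["r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_robust_to_gross_outlier(self, rng):
        vol = np.linspace(2500, 3500, 20)
        sens = 0.004 * vol - 9.0 + rng.normal(0, 0.05, 20)
        clean_slope = np.polyfit(vol, sens, 1)[0]
        sens_out = sens.copy()
        sens_out[3] += 25.0
        robust = volume_sensitivity_regression(vol, sens_out)
        assert robust["slope"] == pytest.approx(clean_slope, rel=0.1)

    def test_rank_deficient_design_rejected(self):
        vol = np.full(6, 3000.0)
        with pytest.raises(ValueError, match="rank"):
            volume_sensitivity_regression(vol, np.arange(6.0))

    def test_null_slope_ci_covers_zero(self, rng):
        covered = 0
        reps = 40
        for _ in range(reps):
            vol = rng.normal(3000, 200, 25)
            sens = rng.normal(1.0, 0.3, 25)
            out = volume_sensitivity_regression(vol, sens)
            lo, hi = out["slope_ci"]
            covered += lo <= 0 <= hi
        assert covered / reps >= 0.85
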