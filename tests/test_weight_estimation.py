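"""Half-split CV weight estimation: splits, logistic MLE, weight comparison."""

import numpy as np
import pandas as pd
import pytest

from smecki import CohortSpec, compare_weights, cv_recalibrate, fit_logistic, half_split
from smecki import generate_cohort
from smecki.score_engine import COEFFICIENT_NAMES, COVARIATES
from smecki.weight_estimation import (
    ConvergenceError,
    DegenerateOutcomeError,
    comparison_symbols,
)


def small_cohort(n=60, seed=0, sex="F"):
    spec = CohortSpec(
        n_female=n if sex == "F" else 0,
        n_male=n if sex == "M" else 0,
        seed=seed,
    )
    return generate_cohort(spec)


class TestHalfSplit:
    @pytest.mark.parametrize("n,expected", [(4, (2, 2)), (5, (3, 2)), (101, (51, 50))])
    def test_sizes_disjoint_union(self, n, expected):
        cohort = pd.DataFrame({"x": range(n), "event": [0] * n, "sex": "F"})
        train, test = half_split(cohort, np.random.default_rng(0))
        assert (len(train), len(test)) == expected
        merged = pd.concat([train, test]).sort_index()
        pd.testing.assert_frame_equal(merged, cohort)

    def test_deterministic_given_rng_state(self):
        cohort = pd.DataFrame({"x": range(20), "event": [0] * 20})
        t1, _ = half_split(cohort, np.random.default_rng(42))
        t2, _ = half_split(cohort, np.random.default_rng(42))
        pd.testing.assert_frame_equal(t1, t2)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            half_split(pd.DataFrame({"x": [1]}), np.random.default_rng(0))


class TestFitLogistic:
    def test_intercept_only_closed_forms(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        beta = fit_logistic(np.empty((20, 0)), y)
        assert beta[0] == pytest.approx(0.0, abs=1e-8)

        y = np.r_[np.ones(20), np.zeros(80)]
        beta = fit_logistic(np.empty((100, 0)), y)
        assert beta[0] == pytest.approx(np.log(0.25), abs=1e-8)

    def test_two_by_two_table_log_odds_ratio(self):
        # x=0: 10 events / 40 non-events; x=1: 20 events / 30 non-events
        x = np.r_[np.zeros(50), np.ones(50)]
        y = np.r_[np.ones(10), np.zeros(40), np.ones(20), np.zeros(30)]
        beta = fit_logistic(x, y)
        assert beta[1] == pytest.approx(np.log(8 / 3), abs=1e-6)
        assert beta[0] == pytest.approx(np.log(10 / 40), abs=1e-6)

    def test_matches_grid_search_oracle_on_tiny_instance(self):
        """Brute-force likelihood maximisation over a refined 2-parameter
        grid agrees with the Newton solution to 2e-4 per coefficient."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = (rng.random(30) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)

        def nll(b0, b1):
            eta = b0 + b1 * x
            return -np.sum(y * eta - np.logaddexp(0, eta))

        center, width = np.zeros(2), 4.0
        while width > 5e-5:
            b0s = np.linspace(center[0] - width, center[0] + width, 41)
            b1s = np.linspace(center[1] - width, center[1] + width, 41)
            grid = np.array([[nll(a, b) for b in b1s] for a in b0s])
            i, j = np.unravel_index(np.argmin(grid), grid.shape)
            center, width = np.array([b0s[i], b1s[j]]), width / 8

        beta = fit_logistic(x, y)
        assert beta == pytest.approx(center, abs=2e-4)

    def test_matches_statsmodels_on_random_instance(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        X = rng.normal(size=(300, 3))
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.2 + X @ [0.5, -0.4, 0.1])))).astype(float)
        beta = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0).params
        assert beta == pytest.approx(np.asarray(ref), abs=1e-6)

    def test_degenerate_outcomes_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            fit_logistic(np.zeros((5, 1)), np.ones(5))

    def test_rank_deficiency_rejected(self):
        X = np.ones((20, 2))
        y = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(ValueError, match="rank"):
            fit_logistic(X, y)

    def test_complete_separation_flagged_and_ridge_fallback_fits(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10), np.ones(10)]  # perfectly separated
        with pytest.raises(ConvergenceError):
            fit_logistic(x, y)
        beta = fit_logistic(x, y, ridge=1e-4)
        assert np.isfinite(beta).all()
        assert beta[1] > 0


class TestCVRecalibrate:
    @pytest.fixture(scope="class")
    def cohort(self):
        return small_cohort(n=900, seed=5, sex="M")

    def test_single_repetition_equals_direct_fit(self, cohort):
        result = cv_recalibrate(cohort, n_reps=1, master_seed=3)
        rng = np.random.default_rng(np.random.SeedSequence((3, 0)))
        train, _ = half_split(cohort, rng)
        direct = fit_logistic(train[list(COVARIATES)].to_numpy(), train["event"].to_numpy())
        assert result.mean_betas == pytest.approx(direct, abs=1e-12)

    def test_deterministic_given_master_seed(self, cohort):
        r1 = cv_recalibrate(cohort, n_reps=8, master_seed=9)
        r2 = cv_recalibrate(cohort, n_reps=8, master_seed=9)
        assert np.array_equal(r1.beta_matrix, r2.beta_matrix)
        assert np.array_equal(r1.test_aucs, r2.test_aucs)

    def test_result_invariants(self, cohort):
        result = cv_recalibrate(cohort, n_reps=12, master_seed=1)
        assert (result.ci_lower <= result.mean_betas).all()
        assert (result.mean_betas <= result.ci_upper).all()
        assert len(result.test_aucs) == result.n_reps - result.n_failed
        assert ((result.test_aucs >= 0) & (result.test_aucs <= 1)).all()

    def test_mixed_sex_cohort_rejected(self):
        mixed = generate_cohort(CohortSpec(n_female=50, n_male=50, seed=2))
        with pytest.raises(ValueError, match="single-sex"):
            cv_recalibrate(mixed, n_reps=2, master_seed=0)

    def test_interval_method_switch(self, cohort):
        pct = cv_recalibrate(cohort, n_reps=12, master_seed=4, interval_method="percentile")
        mean = cv_recalibrate(cohort, n_reps=12, master_seed=4, interval_method="mean")
        # interval of the mean is much narrower than the repetition spread
        assert ((mean.ci_upper - mean.ci_lower) < (pct.ci_upper - pct.ci_lower)).all()
        assert np.array_equal(pct.mean_betas, mean.mean_betas)

    def test_export_round_trip(self, cohort, tmp_path):
        result = cv_recalibrate(cohort, n_reps=5, master_seed=0)
        result.to_csv(tmp_path / "reps.csv")
        frame = pd.read_csv(tmp_path / "reps.csv")
        assert list(frame.columns) == list(COEFFICIENT_NAMES) + ["test_auc"]
        assert len(frame) == 5


# Published per-sex CV weight means and 95% intervals (the printed
# cross-validation table), canonical coefficient order.
PUBLISHED_TABLE = {
    "intercept": ((4.111, (3.116, 5.107)), (9.79, (9.465, 10.115)), "<"),
    "lvef": ((-0.027, (-0.025, -0.03)), (-0.036, (-0.035, -0.037)), "<"),
    "hb": ((-0.172, (-0.158, -0.186)), (-0.078, (-0.073, -0.084)), ">"),
    "na": ((-0.017, (-0.01, -0.024)), (-0.059, (-0.057, -0.061)), "<"),
    "mdrd": ((-0.009, (-0.007, -0.01)), (-0.011, (-0.01, -0.011)), "="),
    "vevco2_slope": ((0.025, (0.022, 0.027)), (0.028, (0.027, 0.029)), "="),
    "peakvo2_pct": ((-0.034, (-0.032, -0.035)), (-0.047, (-0.046, -0.047)), "<"),
}


class TestCompareWeights:
    @pytest.mark.parametrize("name", list(PUBLISHED_TABLE))
    def test_reproduces_published_symbol_column(self, name):
        (mean_f, ci_f), (mean_m, ci_m), symbol = PUBLISHED_TABLE[name]
        assert compare_weights(ci_f, ci_m, mean_f, mean_m) == symbol

    def test_touching_endpoints_count_as_overlap(self):
        assert compare_weights((-0.010, -0.007), (-0.011, -0.010), -0.009, -0.011) == "="

    def test_direction_reflects_magnitudes_when_disjoint(self):
        assert compare_weights((0.9, 1.1), (0.1, 0.2), 1.0, 0.15) == ">"
        assert compare_weights((-0.2, -0.1), (-1.1, -0.9), -0.15, -1.0) == "<"

    def test_interval_not_containing_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            compare_weights((0.1, 0.2), (0.3, 0.4), 0.5, 0.35)
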