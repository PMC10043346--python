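"""Validation statistics: APE/MAPE, the published fixed equations, Bland-Altman
identities, subgroup-consistency power, and cross-validation behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taclss.errors import InvalidExposureError, ValidationError
from taclss.lss_builder import fit_ols, wide_concentrations
from taclss.lss_validation import (
    REFERENCE_EQUATIONS,
    absolute_prediction_error,
    apply_external_equation,
    bland_altman,
    crossvalidate_lss,
    mape_summary,
    subgroup_consistency,
)


class TestApe:
    @pytest.mark.parametrize(
        "predicted, observed, expected",
        [(200.0, 200.0, 0.0), (230.0, 200.0, 15.0), (170.0, 200.0, 15.0)],
    )
    def test_known_values(self, predicted, observed, expected):
        assert absolute_prediction_error(predicted, observed) == pytest.approx(expected)

    def test_invalid_reference(self):
        with pytest.raises(InvalidExposureError):
            absolute_prediction_error(200.0, 0.0)

    @given(
        predicted=st.floats(10.0, 500.0),
        observed=st.floats(10.0, 500.0),
        c=st.floats(0.1, 50.0),
    )
    @settings(max_examples=60, derandomize=True)
    def test_scale_invariance(self, predicted, observed, c):
        assert absolute_prediction_error(c * predicted, c * observed) == pytest.approx(
            absolute_prediction_error(predicted, observed), rel=1e-9
        )


class TestMapeSummary:
    def test_hand_counted(self):
        s = mape_summary([5.0, 10.0, 20.0])
        assert s.median == 10.0
        assert s.fraction_above == pytest.approx(1 / 3)

    def test_all_zero(self):
        s = mape_summary([0.0, 0.0, 0.0])
        assert (s.median, s.mean, s.sd, s.fraction_above) == (0.0, 0.0, 0.0, 0.0)

    def test_threshold_strict(self):
        assert mape_summary([15.0, 15.0], threshold=15.0).fraction_above == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mape_summary([])


class TestExternalEquations:
    def test_published_three_point_values(self):
        """Hand-recomputed: Eq with C0/C1/C4 gives 39.179+52.632+34.455+79.26."""
        conc = {"C0": 6.0, "C1": 15.0, "C2": 14.0, "C4": 10.0}
        assert apply_external_equation(REFERENCE_EQUATIONS["almeida_c0c1c4"], conc) == pytest.approx(205.526)
        # 46.062 + 9.129*6 + 2.768*14 + 6.450*10 = 204.088
        assert apply_external_equation(REFERENCE_EQUATIONS["almeida_c0c2c4"], conc) == pytest.approx(204.088)

    def test_zero_profile_returns_intercept(self):
        zeros = {"C0": 0.0, "C1": 0.0, "C2": 0.0, "C4": 0.0}
        for eq in REFERENCE_EQUATIONS.values():
            assert apply_external_equation(eq, zeros) == pytest.approx(eq.intercept)

    def test_missing_time_point(self):
        from taclss.errors import MissingSampleError

        with pytest.raises(MissingSampleError, match="C4"):
            apply_external_equation(REFERENCE_EQUATIONS["model7"], {"C0": 6.0})


class TestBlandAltman:
    def test_identity(self):
        ba = bland_altman([100.0, 200.0, 300.0], [100.0, 200.0, 300.0])
        assert (ba.mean_diff, ba.sd_diff, ba.loa_low, ba.loa_high) == (0.0, 0.0, 0.0, 0.0)

    def test_constant_offset(self):
        a = np.array([100.0, 200.0, 300.0])
        ba = bland_altman(a, a + 10.0)
        assert ba.mean_diff == pytest.approx(-10.0)
        assert ba.sd_diff == pytest.approx(0.0)

    def test_closed_form_two_pairs(self):
        ba = bland_altman([1.0, 3.0], [2.0, 2.0])  # differences [-1, 1]
        assert ba.mean_diff == 0.0
        assert ba.sd_diff == pytest.approx(np.sqrt(2))
        assert ba.loa_high == pytest.approx(1.96 * np.sqrt(2))

    def test_mean_diff_equals_mean_difference(self, rng):
        a, b = rng.normal(200, 30, 25), rng.normal(195, 30, 25)
        ba = bland_altman(a, b)
        assert ba.mean_diff == pytest.approx(a.mean() - b.mean(), rel=1e-12)

    def test_pairing_error(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0, 2.0], [1.0])

    def test_in_sample_fit_centers_differences_at_zero(self, rng):
        """OLS residuals sum to zero, so predicted-minus-observed averages to
        zero for any in-sample LSS fit."""
        x = pd.DataFrame(rng.normal(10, 3, size=(40, 2)), columns=["C0", "C4"])
        y = 30 + 11 * x["C0"] + 8 * x["C4"] + rng.normal(0, 10, 40)
        m = fit_ols(x, y)
        predicted = m.intercept + x.to_numpy() @ np.array([m.coefficients["C0"], m.coefficients["C4"]])
        ba = bland_altman(predicted, y.to_numpy())
        assert ba.mean_diff == pytest.approx(0.0, abs=1e-9)


class TestSubgroupConsistency:
    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            subgroup_consistency([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], ["x", "x", "x"])

    def test_detects_group_offset(self, rng):
        """A +50 ng*h/mL offset in one group at n=200 is flagged in >90% of
        replicates at a = 0.05."""
        hits = 0
        for _ in range(50):
            pred = rng.normal(225, 40, 200)
            labels = np.where(np.arange(200) % 2 == 0, "innovator", "bioequivalent")
            obs = 5 + 0.98 * pred + rng.normal(0, 20, 200)
            obs = np.where(labels == "innovator", obs + 50.0, obs)
            _, _, _, p = subgroup_consistency(pred, obs, labels)
            hits += p < 0.05
        assert hits > 45

    def test_null_keeps_f_small(self, rng):
        pred = rng.normal(225, 40, 120)
        obs = 5 + 0.98 * pred + rng.normal(0, 20, 120)
        labels = rng.choice(["a", "b", "c"], size=120)
        f, df1, df2, p = subgroup_consistency(pred, obs, labels)
        assert df1 == 2
        assert p > 0.001  # not a guaranteed bound, but a seeded sanity check


class TestCrossValidation:
    @staticmethod
    def _cohort_tables(default_cohort, default_exposure):
        wide = wide_concentrations(default_cohort.concentrations)
        auc = default_exposure.set_index("patient_id")["auc_0_24"]
        return wide, auc

    def test_noise_free_linear_target_gives_zero_mape(self, rng):
        wide = pd.DataFrame(rng.normal(12, 3, size=(30, 2)), columns=["C0", "C4"])
        wide.index = [f"P{i}" for i in range(30)]
        auc = pd.Series(30 + 11 * wide["C0"] + 8 * wide["C4"], index=wide.index)
        s = crossvalidate_lss(wide, auc, ["C0", "C4"], folds=5, seed=1)
        assert s.median == pytest.approx(0.0, abs=1e-8)

    def test_deterministic_given_seed(self, default_cohort, default_exposure):
        wide, auc = self._cohort_tables(default_cohort, default_exposure)
        s1 = crossvalidate_lss(wide, auc, ["C0", "C4"], folds=5, seed=3)
        s2 = crossvalidate_lss(wide, auc, ["C0", "C4"], folds=5, seed=3)
        assert s1 == s2

    def test_out_of_sample_mape_exceeds_in_sample_on_average(self):
        """Optimism: held-out APE is larger than in-sample APE over seeds."""
        from taclss.cohort_sim import SimulationConfig, simulate_cohort
        from taclss.pk_exposure import exposure_table

        gaps = []
        for seed in range(12):
            tables = simulate_cohort(SimulationConfig(seed=seed))
            expo = exposure_table(tables.metadata, tables.concentrations)
            wide = wide_concentrations(tables.concentrations)
            auc = expo.set_index("patient_id")["auc_0_24"]
            aligned_x, aligned_y = wide[["C0", "C1", "C4"]].align(auc, join="inner", axis=0)
            in_sample = fit_ols(aligned_x, aligned_y).mape
            out_sample = crossvalidate_lss(wide, auc, ["C0", "C1", "C4"], folds=5, seed=seed).median
            gaps.append(out_sample - in_sample)
        assert np.mean(gaps) > 0

    def test_better_subsets_win_out_of_sample(self):
        """The three-point C0-C1-C4 equation beats trough-only prediction in
        nearly every simulated cohort."""
        from taclss.cohort_sim import SimulationConfig, simulate_cohort
        from taclss.pk_exposure import exposure_table

        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            tables = simulate_cohort(SimulationConfig(seed=seed))
            expo = exposure_table(tables.metadata, tables.concentrations)
            wide = wide_concentrations(tables.concentrations)
            auc = expo.set_index("patient_id")["auc_0_24"]
            m3 = crossvalidate_lss(wide, auc, ["C0", "C1", "C4"], folds=5, seed=seed).median
            m1 = crossvalidate_lss(wide, auc, ["C0"], folds=5, seed=seed).median
            wins += m3 < m1
        assert wins >= int(0.95 * n_seeds)
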