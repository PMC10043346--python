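"""Simulator correctness: genotype sampling, the two-compartment steady-state
model against independent closed forms, dose titration, assay noise, and
whole-cohort reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from taclss.cohort_sim import (
    PKParameters,
    SimulationConfig,
    add_assay_noise,
    analytic_auc_ss,
    concentration_ss,
    noise_free,
    sample_genotype,
    sample_pk_parameters,
    simulate_cohort,
    simulate_patient,
    titrate_dose,
    write_cohort,
)
from taclss.errors import ConfigError
from taclss.pk_exposure import trapezoid

PARAMS = PKParameters(cl_f=16.0, q_f=60.0, vc_f=60.0, vp_f=800.0, ka=0.3, weight=40.0)


def _config(**overrides):
    return SimulationConfig(**overrides).validate()


def _zero_iiv(cfg):
    cfg.iiv_cv = {k: 0.0 for k in cfg.iiv_cv}
    cfg.iov_cv = {k: 0.0 for k in cfg.iov_cv}
    return cfg


class TestGenotypeSampling:
    def test_degenerate_frequencies(self, rng):
        assert all(sample_genotype(1.0, rng) == "*3/*3" for _ in range(20))
        assert all(sample_genotype(0.0, rng) == "*1/*1" for _ in range(20))

    def test_invalid_frequency_rejected(self, rng):
        with pytest.raises(ConfigError):
            sample_genotype(1.2, rng)

    def test_hardy_weinberg_proportions(self, rng):
        """10,000 draws at q3=0.8125 must not reject HW (chi-square, a=0.001),
        and the *3/*3 fraction must sit within 3 SE of q3^2 = 0.660."""
        q3 = 0.8125
        draws = [sample_genotype(q3, rng) for _ in range(10_000)]
        counts = pd.Series(draws).value_counts()
        expected = 10_000 * np.array([(1 - q3) ** 2, 2 * q3 * (1 - q3), q3**2])
        observed = np.array([counts.get(g, 0) for g in ("*1/*1", "*1/*3", "*3/*3")])
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=2) > 0.001
        frac33 = observed[2] / 10_000
        se = np.sqrt(q3**2 * (1 - q3**2) / 10_000)
        assert abs(frac33 - 0.660) < 3 * se + 1e-3


class TestParameterSampling:
    def test_zero_variance_returns_medians(self, rng):
        cfg = _zero_iiv(_config())
        p = sample_pk_parameters("*3/*3", cfg, rng)
        for name, median in cfg.medians.items():
            assert getattr(p, name) == pytest.approx(median)

    def test_expressor_multiplier_applied(self, rng):
        cfg = _zero_iiv(_config(cl_expressor_multiplier=1.6))
        p = sample_pk_parameters("*1/*3", cfg, rng)
        assert p.cl_f == pytest.approx(1.6 * cfg.medians["cl_f"])

    def test_clearance_ratio_recovers_multiplier(self, rng):
        """Monte Carlo: mean expressor/non-expressor clearance ratio -> 1.6."""
        cfg = _config(cl_expressor_multiplier=1.6)
        ex = np.mean([sample_pk_parameters("*1/*3", cfg, rng).cl_f for _ in range(4000)])
        ne = np.mean([sample_pk_parameters("*3/*3", cfg, rng).cl_f for _ in range(4000)])
        assert ex / ne == pytest.approx(1.6, rel=0.03)


class TestConcentrationModel:
    def test_zero_dose_and_proportionality(self):
        t = np.array([0.0, 1.0, 2.0, 4.0, 12.0, 24.0])
        assert np.all(concentration_ss(PARAMS, 0.0, t) == 0.0)
        c1 = concentration_ss(PARAMS, 3.0, t)
        c2 = concentration_ss(PARAMS, 6.0, t)
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-12)

    def test_periodicity(self):
        assert concentration_ss(PARAMS, 5.0, 0.0) == pytest.approx(
            concentration_ss(PARAMS, 5.0, 24.0), rel=1e-12
        )

    def test_steady_state_mass_balance(self):
        """Dense-grid integral over one interval equals 1000*D/CL to <1e-6."""
        t = np.linspace(0.0, 24.0, 200_001)
        auc = trapezoid(t, concentration_ss(PARAMS, 5.0, t))
        assert auc == pytest.approx(analytic_auc_ss(PARAMS, 5.0), rel=1e-6)

    def test_one_compartment_limit(self):
        """q->0 collapses onto the independent one-compartment closed form."""
        p = PKParameters(cl_f=16.0, q_f=1e-7, vc_f=60.0, vp_f=800.0, ka=0.3, weight=40.0)
        k, ka, vc, tau, dose = p.cl_f / p.vc_f, p.ka, p.vc_f, 24.0, 5.0

        def one_compartment(t):
            pref = 1000.0 * dose * ka / (vc * (ka - k))
            return pref * (
                np.exp(-k * t) / -np.expm1(-k * tau) - np.exp(-ka * t) / -np.expm1(-ka * tau)
            )

        for t in (0.0, 1.0, 2.0, 4.0, 12.0, 24.0):
            assert concentration_ss(p, dose, t) == pytest.approx(one_compartment(t), rel=1e-3)

    def test_ka_collision_perturbed(self):
        base = PKParameters(cl_f=16.0, q_f=60.0, vc_f=60.0, vp_f=800.0, ka=0.3, weight=40.0)
        alpha, _ = base.hybrid_constants()
        collided = PKParameters(cl_f=16.0, q_f=60.0, vc_f=60.0, vp_f=800.0, ka=alpha, weight=40.0)
        a2, b2 = collided.hybrid_constants()
        assert collided.ka not in (a2, b2)
        assert np.isfinite(concentration_ss(collided, 5.0, 2.0))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigError):
            PKParameters(cl_f=-1.0, q_f=60.0, vc_f=60.0, vp_f=800.0, ka=0.3, weight=40.0)


class TestTitration:
    def test_fixed_point_when_initial_in_range(self):
        # initial dose 3.0 mg already puts the predicted trough inside 5-7
        cfg = _zero_iiv(_config(initial_dose_per_kg=0.075))
        initial = 0.075 * PARAMS.weight
        assert cfg.target_c0[0] <= initial * concentration_ss(PARAMS, 1.0, 24.0) <= cfg.target_c0[1]
        dose, on_target = titrate_dose(PARAMS, cfg)
        assert dose == pytest.approx(initial)
        assert on_target

    def test_monotone_in_clearance(self):
        cfg = _zero_iiv(_config())
        fast = PKParameters(
            cl_f=2 * PARAMS.cl_f, q_f=PARAMS.q_f, vc_f=PARAMS.vc_f,
            vp_f=PARAMS.vp_f, ka=PARAMS.ka, weight=PARAMS.weight,
        )
        assert titrate_dose(fast, cfg)[0] >= titrate_dose(PARAMS, cfg)[0]

    def test_expressor_dose_ratio_tracks_multiplier(self, rng):
        """With no between-subject variability the titrated dose ratio matches
        the clearance multiplier to within one grid increment."""
        cfg = _zero_iiv(_config(cl_expressor_multiplier=1.6))
        d_ne, _ = titrate_dose(sample_pk_parameters("*3/*3", cfg, rng), cfg)
        d_ex, _ = titrate_dose(sample_pk_parameters("*1/*3", cfg, rng), cfg)
        assert abs(d_ex - 1.6 * d_ne) <= 1.6 * cfg.dose_increment

    def test_unreachable_window_flagged(self):
        cfg = _zero_iiv(_config(dose_min=0.5, dose_max=0.5))
        dose, on_target = titrate_dose(PARAMS, cfg)
        assert dose == 0.5 and not on_target


class TestAssayNoise:
    def test_zero_noise_identity(self, rng):
        cfg = _config(assay_cv=0.0, assay_sd=0.0)
        measured, below = add_assay_noise(np.array([0.9, 5.0, 20.0]), cfg, rng)
        np.testing.assert_array_equal(measured, [0.9, 5.0, 20.0])
        assert not below.any()

    def test_lloq_imputation(self, rng):
        cfg = _config(assay_cv=0.0, assay_sd=0.0, lloq=0.5)
        measured, below = add_assay_noise(np.array([0.0]), cfg, rng)
        assert measured[0] == pytest.approx(0.25)
        assert below.all()

    def test_proportional_error_sd(self, rng):
        cfg = _config(assay_cv=0.1, assay_sd=0.0)
        measured, _ = add_assay_noise(np.full(10_000, 10.0), cfg, rng)
        assert measured.std(ddof=1) == pytest.approx(1.0, rel=0.05)


class TestCohortSimulation:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = _config(seed=7)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(simulate_cohort(cfg), d1)
        write_cohort(simulate_cohort(_config(seed=7)), d2)
        for name in ("cohort_metadata.csv", "concentrations.csv", "ground_truth.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_patient_reproducible_independent_of_cohort_size(self):
        small = simulate_patient(2, _config(n_patients=5, seed=3))
        large = simulate_patient(2, _config(n_patients=40, seed=3))
        np.testing.assert_array_equal(small.conc_measured, large.conc_measured)
        assert small.daily_dose == large.daily_dose

    def test_genotype_tallies_near_hardy_weinberg(self):
        """Pooled tallies over several seeds stay within the binomial band
        around the HW expectations at q3 = 0.8125."""
        q3 = 0.8125
        pooled = np.zeros(3)
        n_seeds = 10
        for seed in range(n_seeds):
            meta = simulate_cohort(_config(seed=seed)).metadata
            counts = meta["genotype"].value_counts()
            pooled += [counts.get(g, 0) for g in ("*1/*1", "*1/*3", "*3/*3")]
        n = pooled.sum()
        probs = np.array([(1 - q3) ** 2, 2 * q3 * (1 - q3), q3**2])
        for obs, p in zip(pooled, probs):
            se = np.sqrt(n * p * (1 - p))
            assert abs(obs - n * p) < 3 * se + 1.0

    def test_noise_free_trapezoid_close_to_true_auc(self):
        """Without assay noise the 6-point trapezoid AUC stays within 15% of
        the analytic dose/clearance value for every patient."""
        tables = simulate_cohort(noise_free(_config(seed=11)))
        truth = tables.ground_truth.set_index("patient_id")["true_auc_ng_h_ml"]
        for pid, grp in tables.concentrations.groupby("patient_id"):
            grp = grp.sort_values("time_h")
            auc = trapezoid(grp["time_h"].to_numpy(), grp["conc_ng_ml"].to_numpy())
            assert auc == pytest.approx(truth[pid], rel=0.15)

    def test_tac_d_consistency(self, default_cohort):
        meta = default_cohort.metadata
        np.testing.assert_allclose(
            meta["tac_d_mg_per_kg"], meta["daily_dose_mg"] / meta["weight_kg"], rtol=1e-12
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            _config(q3=1.5)
        with pytest.raises(ConfigError):
            _config(target_c0=(7.0, 5.0))
        with pytest.raises(ConfigError):
            _config(dose_increment=-0.5)
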