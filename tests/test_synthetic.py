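"""Synthetic-data generator: determinism, limits, parameter recovery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from ptvmargin.motion_range import peak_to_trough_amplitudes, summarize_motion
from ptvmargin.step_uncertainty import (
    correlation_uncertainty,
    fraction_step_uncertainties,
    sr_error_series,
)
from ptvmargin.synthetic import SimulationParams, make_cohort, simulate_fraction

QUIET = SimulationParams(
    seed_jitter_sd_mm=0.0,
    correlation_mu_mm=(0.0, 0.0, 0.0),
    correlation_sd_mm=(0.0, 0.0, 0.0),
    prediction_sd_scale=0.0,
    period_jitter=0.0,
    drift_mm_per_min=0.0,
    fraction_duration_s=300.0,
)


class TestContracts:
    def test_determinism_bit_identical(self):
        p = replace(SimulationParams(), fraction_duration_s=300.0, random_seed=11)
        ds1, _ = simulate_fraction(p)
        ds2, _ = simulate_fraction(p)
        pd.testing.assert_frame_equal(ds1.correlation, ds2.correlation)
        pd.testing.assert_frame_equal(ds1.prediction, ds2.prediction)
        for a, b in zip(ds1.live_images, ds2.live_images):
            assert a.timestamp == b.timestamp
            assert np.array_equal(a.positions, b.positions)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(n_seeds=1).validate()
        with pytest.raises(ValueError):
            SimulationParams(fraction_duration_s=30.0).validate()
        with pytest.raises(ValueError):
            SimulationParams(correlation_sd_mm=(-0.1, 0, 0)).validate()

    def test_dataset_passes_validation_and_schema(self):
        ds, _ = simulate_fraction(replace(SimulationParams(), fraction_duration_s=300.0))
        ds.validate()
        assert len(ds.live_images) == 4  # one x-ray per minute over 5 min

    def test_cohort_shape_and_determinism(self):
        cohort = make_cohort(4, replace(SimulationParams(), fraction_duration_s=240.0), master_seed=5)
        assert len(cohort) == 4
        assert all(3 <= len(p.fractions) <= 5 for p in cohort)
        again = make_cohort(4, replace(SimulationParams(), fraction_duration_s=240.0), master_seed=5)
        for p, q in zip(cohort, again):
            assert p.patient_id == q.patient_id
            for a, b in zip(p.fractions, q.fractions):
                pd.testing.assert_frame_equal(a.correlation, b.correlation)


class TestNoiseFreeLimit:
    def test_all_error_streams_identically_zero(self):
        ds, truth = simulate_fraction(QUIET)
        assert (ds.correlation[["err_si", "err_lat", "err_ap"]] == 0).all().all()
        assert (ds.prediction[["err_si", "err_lat", "err_ap"]] == 0).all().all()
        series = sr_error_series(ds.fiducials, ds.live_images)
        assert np.allclose(series.values, 0.0, atol=1e-9)

    def test_combined_uncertainty_reduces_to_deformation_alone(self):
        from ptvmargin.combine import patient_uncertainty_from_steps

        ds, truth = simulate_fraction(QUIET)
        steps = fraction_step_uncertainties(ds, truth.geometry)
        pu = patient_uncertainty_from_steps(
            "q", steps["deformation"].u, steps["seeds"].u,
            steps["correlation"].u, steps["prediction"].u,
        )
        assert np.allclose(pu.u_combined, truth.u_deformation, atol=1e-9)

    def test_pure_sinusoid_peak_to_trough_is_2a(self):
        p = replace(QUIET, waveform="sin", amplitude_mm=(4.0, 0.8, 1.5))
        ds, truth = simulate_fraction(p)
        amps = peak_to_trough_amplitudes(ds.modeled_trace())
        assert np.allclose(amps, np.broadcast_to(2 * np.array(p.amplitude_mm), amps.shape), atol=0.05)


class TestParameterRecovery:
    def test_correlation_estimator_monte_carlo(self):
        # sigma_c = 0.75, mu = 0, ~1e4 retained samples -> U within 5% of 1.5
        p = replace(
            SimulationParams(),
            correlation_mu_mm=(0.0, 0.0, 0.0),
            correlation_sd_mm=(0.75, 0.75, 0.75),
            fraction_duration_s=2520.0,
            random_seed=2,
        )
        ds, truth = simulate_fraction(p)
        steps = fraction_step_uncertainties(ds, truth.geometry)
        assert steps["correlation"].n_samples >= 10_000 - 100
        assert np.allclose(steps["correlation"].u, 1.5, rtol=0.05)
        assert np.allclose(truth.u_correlation, 1.5)

    def test_all_estimators_recover_ground_truth_over_fractions(self):
        # averaged over >=20 fractions, each estimator lands within 10%
        # of its generating value
        base = replace(SimulationParams(), fraction_duration_s=600.0)
        us = {"seeds": [], "correlation": [], "prediction": []}
        truth = None
        for k in range(20):
            ds, truth = simulate_fraction(replace(base, random_seed=100 + k))
            steps = fraction_step_uncertainties(ds, truth.geometry)
            for name in us:
                us[name].append(steps[name].u)
        mean_u = {name: np.stack(v).mean(axis=0) for name, v in us.items()}
        assert np.allclose(mean_u["seeds"], truth.u_seeds, rtol=0.10)
        assert np.allclose(mean_u["correlation"], truth.u_correlation, rtol=0.10)
        assert np.allclose(mean_u["prediction"], truth.u_prediction, rtol=0.10)

    def test_motion_range_matches_requested_amplitude(self):
        # template tuned to a large mover (Rm SI target 13.5 mm)
        p = replace(
            SimulationParams(),
            amplitude_mm=(6.75, 0.5, 0.8),
            fraction_duration_s=600.0,
            random_seed=3,
        )
        ds, truth = simulate_fraction(p)
        s = summarize_motion(peak_to_trough_amplitudes(ds.modeled_trace()))
        assert s.rm[0] == pytest.approx(13.5, rel=0.10)
        assert truth.rm[0] == pytest.approx(13.5)

    def test_error_range_rank_correlation_across_cohort(self):
        # larger movers have larger correlation/prediction errors
        from scipy.stats import spearmanr

        cohort = make_cohort(10, replace(SimulationParams(), fraction_duration_s=420.0), master_seed=9)
        r95s, u_corr, u_pred = [], [], []
        for pat in cohort:
            ds = pat.fractions[0]
            s = summarize_motion(peak_to_trough_amplitudes(ds.modeled_trace()))
            steps = fraction_step_uncertainties(ds, pat.geometry)
            r95s.append(s.r95[0])
            u_corr.append(steps["correlation"].u[0])
            u_pred.append(steps["prediction"].u[0])
        assert spearmanr(r95s, u_corr).statistic > 0
        assert spearmanr(r95s, u_pred).statistic > 0
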