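"""The four step-uncertainty estimators and their exclusion rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_correlation, make_prediction
from ptvmargin.log_model import (
    CorrelationFlag,
    FiducialSet,
    LiveImageRecord,
    PatientGeometry,
    TrackingInfeasibleError,
)
from ptvmargin.step_uncertainty import (
    DeformationRuleNotApplicable,
    assign_deformation_uncertainty,
    correlation_uncertainty,
    detect_seed_migration,
    filter_correlation_samples,
    pairwise_distance_deltas,
    prediction_uncertainty,
    seeds_uncertainty,
    solid_rigid_error,
    sr_error_series,
)


def geom(border, pid="x"):
    return PatientGeometry(pid, 3, 3, abs(border) + 5.0, border)


class TestDeformationRule:
    def test_com_inside_ctv(self):
        su = assign_deformation_uncertainty(geom(-4.2, "2"))
        assert np.allclose(su.u, 2.1)
        assert np.allclose(su.e, 1.05)

    def test_com_outside_within_30mm(self):
        su = assign_deformation_uncertainty(geom(12.2, "6"))
        assert np.allclose(su.u, 3.0)

    def test_boundary_zero_counts_as_inside(self):
        assert assign_deformation_uncertainty(geom(0.0)).u[0] == 2.1

    def test_far_outside_is_flagged_not_numbered(self):
        with pytest.raises(DeformationRuleNotApplicable):
            assign_deformation_uncertainty(geom(35.0))


class TestSolidRigidError:
    def test_identical_configurations_give_zero(self, two_seed_ct):
        live = LiveImageRecord(1.0, two_seed_ct.positions.copy())
        assert solid_rigid_error(two_seed_ct, live) == pytest.approx(0.0)

    def test_rigid_shift_gives_zero(self, two_seed_ct):
        live = LiveImageRecord(1.0, two_seed_ct.positions + np.array([3.0, -2.0, 1.0]))
        assert solid_rigid_error(two_seed_ct, live) == pytest.approx(0.0)

    def test_single_pair_distance_change(self, two_seed_ct):
        live = LiveImageRecord(1.0, [[0, 0, 0], [11.2, 0, 0]])
        assert solid_rigid_error(two_seed_ct, live) == pytest.approx(1.2)

    def test_max_of_absolute_pair_deltas(self):
        # pair deltas +0.5 (a-b), -2.0 (a-c), +1.0 (b-c) -> SRerror = 2.0
        ct = FiducialSet(["a", "b", "c"], [[0, 0, 0], [10, 0, 0], [0, 10, 0]])
        live = LiveImageRecord(
            1.0, [[0, 0, 0], [10.5, 0, 0], [0, 8, 0]]
        )
        # |a-b|: 10.5 (delta +0.5); |a-c|: 8 (delta -2); |b-c|: sqrt(10.5^2+8^2)
        d_bc = np.hypot(10.5, 8.0) - np.hypot(10.0, 10.0)
        expected = max(0.5, 2.0, abs(d_bc))
        assert solid_rigid_error(ct, live) == pytest.approx(expected)

    def test_needs_two_common_valid_seeds(self, two_seed_ct):
        live = LiveImageRecord(1.0, two_seed_ct.positions, valid=[True, False])
        with pytest.raises(TrackingInfeasibleError):
            solid_rigid_error(two_seed_ct, live)

    def test_series_threshold_flags(self, two_seed_ct):
        lives = [
            LiveImageRecord(1.0, [[0, 0, 0], [12.0, 0, 0]]),  # 2.0 mm
            LiveImageRecord(2.0, [[0, 0, 0], [16.0, 0, 0]]),  # 6.0 mm
        ]
        series = sr_error_series(two_seed_ct, lives)
        assert list(series.over_standard) == [True, True]
        assert list(series.over_removal) == [False, True]
        assert list(series.over_treat) == [False, True]


class TestSeedMigration:
    def test_quiet_series_disables_nothing(self, two_seed_ct):
        lives = [LiveImageRecord(t, two_seed_ct.positions.copy()) for t in (1.0, 2.0)]
        disabled, flagged = detect_seed_migration(two_seed_ct, lives)
        assert disabled == set() and not flagged

    def test_displaced_seed_is_disabled(self):
        ct = FiducialSet(["a", "b", "c"], [[0, 0, 0], [20, 0, 0], [0, 20, 0]])
        lives = []
        for t in (60.0, 120.0, 180.0):
            pos = ct.positions.copy()
            pos[2] += [0.0, 5.0, 0.0]  # seed c migrated 5 mm
            lives.append(LiveImageRecord(t, pos))
        disabled, flagged = detect_seed_migration(ct, lives)
        assert disabled == {"c"} and not flagged

    def test_two_seeds_only_flagged_never_removed(self, two_seed_ct):
        lives = [LiveImageRecord(t, [[0, 0, 0], [14.0, 0, 0]]) for t in (1.0, 2.0)]
        disabled, flagged = detect_seed_migration(two_seed_ct, lives)
        assert disabled == set() and flagged


class TestSeedsUncertainty:
    def test_distance_deltas_signed_per_pair_and_image(self, two_seed_ct):
        lives = [
            LiveImageRecord(1.0, [[0, 0, 0], [10.5, 0, 0]]),
            LiveImageRecord(2.0, [[0, 0, 0], [9.5, 0, 0]]),
            LiveImageRecord(3.0, [[0, 0, 0], [10.0, 0, 0]]),
        ]
        deltas = pairwise_distance_deltas(two_seed_ct, lives)
        assert np.allclose(sorted(deltas), [-0.5, 0.0, 0.5])

    def test_sample_count_is_pairs_times_images(self):
        ct = FiducialSet(["a", "b", "c"], [[0, 0, 0], [10, 0, 0], [0, 10, 0]])
        lives = [LiveImageRecord(t, ct.positions.copy()) for t in (1.0, 2.0)]
        assert pairwise_distance_deltas(ct, lives).size == 6

    def test_halving_then_mu_plus_two_sigma(self):
        su = seeds_uncertainty(np.array([1.0, -1.0]))
        # halved {0.5, -0.5}: mu=0, sigma=0.7071 -> U = 1.414
        assert su.u[0] == pytest.approx(2.0 * np.std([0.5, -0.5], ddof=1), abs=1e-12)
        assert su.u[0] == pytest.approx(1.41421, abs=1e-4)
        assert np.allclose(su.e, su.u / 2.0)

    def test_all_zero_samples_give_zero(self):
        assert seeds_uncertainty(np.zeros(5)).u[0] == 0.0

    def test_degenerate_constant_samples(self):
        su = seeds_uncertainty(np.full(4, 2.0))
        assert su.u[0] == pytest.approx(1.0)  # halved mean 1.0, sigma 0

    def test_literal_variance_mode(self):
        su = seeds_uncertainty(np.array([1.0, -1.0]), literal_variance=True)
        assert su.u[0] == pytest.approx(2.0 * 0.5**2 * 2.0)  # 2*sigma^2 = 2*0.5 = 1.0

    def test_same_value_on_all_axes(self):
        su = seeds_uncertainty(np.array([0.4, -0.2, 0.1]))
        assert su.u[0] == su.u[1] == su.u[2]


class TestCorrelationFiltering:
    def test_unflagged_small_errors_all_retained(self):
        df = make_correlation(np.full((5, 3), 0.5))
        assert len(filter_correlation_samples(df)) == 5

    def test_model_build_samples_dropped(self):
        flags = [CorrelationFlag.MODEL_BUILD.value] * 2 + ["normal"] * 3
        df = make_correlation(np.zeros((5, 3)), flags=flags)
        assert len(filter_correlation_samples(df)) == 3

    def test_three_consecutive_over_3mm_dropped(self):
        errs = np.zeros((9, 3))
        errs[3:6, 0] = 3.5
        kept = filter_correlation_samples(make_correlation(errs))
        assert len(kept) == 6
        assert (kept["err_si"].abs() <= 3.0).all()

    def test_short_excursions_survive(self):
        # two consecutive over-threshold samples do not trigger a rebuild
        errs = np.zeros((6, 3))
        errs[2:4, 2] = 4.0
        assert len(filter_correlation_samples(make_correlation(errs))) == 6

    def test_only_model_build_leaves_empty_set_and_downstream_error(self):
        df = make_correlation(np.zeros((3, 3)), flags=[CorrelationFlag.MODEL_BUILD.value] * 3)
        kept = filter_correlation_samples(df)
        assert len(kept) == 0
        with pytest.raises(ValueError):
            correlation_uncertainty(kept)


class TestDistributionEstimators:
    def test_constant_errors_give_abs_value(self):
        df = make_correlation(np.full((4, 3), -0.7))
        assert np.allclose(correlation_uncertainty(df).u, 0.7)

    def test_hand_computed_sd(self):
        df = make_correlation(np.column_stack([[-1.0, 0.0, 1.0], np.zeros(3), np.zeros(3)]))
        su = correlation_uncertainty(df)
        assert su.u[0] == pytest.approx(2.0)  # mu=0, sigma=1
        assert su.u[1] == su.u[2] == 0.0

    def test_prediction_hand_computation(self):
        df = make_prediction(np.column_stack([[0.1, 0.3], np.zeros(2), np.zeros(2)]))
        su = prediction_uncertainty(df)
        assert su.u[0] == pytest.approx(0.2 + 2.0 * np.std([0.1, 0.3], ddof=1))
        assert su.u[0] == pytest.approx(0.48284, abs=1e-4)

    def test_beam_flag_does_not_matter(self):
        errs = np.random.default_rng(0).normal(0.1, 0.2, size=(50, 3))
        all_on = prediction_uncertainty(make_prediction(errs))
        mixed = prediction_uncertainty(make_prediction(errs, beam_on=[i % 2 == 0 for i in range(50)]))
        assert np.allclose(all_on.u, mixed.u)

    @settings(deadline=None, max_examples=40)
    @given(
        errs=st.lists(st.floats(-5, 5), min_size=2, max_size=30),
        perm_seed=st.integers(0, 10_000),
    )
    def test_order_invariance_and_symmetry(self, errs, perm_seed):
        errs = np.asarray(errs)
        e3 = np.column_stack([errs, errs, errs])
        base = correlation_uncertainty(make_correlation(e3)).u[0]
        perm = np.random.default_rng(perm_seed).permutation(errs.size)
        shuffled = correlation_uncertainty(make_correlation(e3[perm])).u[0]
        assert shuffled == pytest.approx(base, rel=1e-9, abs=1e-12)
        # sign flip of a symmetrized set leaves U unchanged
        sym = np.concatenate([errs, -errs])
        s3 = np.column_stack([sym, sym, sym])
        assert correlation_uncertainty(make_correlation(s3)).u[0] == pytest.approx(
            correlation_uncertainty(make_correlation(-s3)).u[0], rel=1e-9, abs=1e-12
        )

    def test_mu_two_sigma_recovers_generating_normal(self):
        # |mu|+2*sigma of 1e4 draws from N(0.3, 0.75) within a few percent
        rng = np.random.default_rng(42)
        errs = rng.normal(0.3, 0.75, size=(10_000, 3))
        su = correlation_uncertainty(make_correlation(errs))
        assert np.allclose(su.u, 0.3 + 2 * 0.75, rtol=0.05)
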