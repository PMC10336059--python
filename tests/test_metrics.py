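"""Metric correctness against brute-force oracles and closed forms."""

import numpy as np
import pytest
from scipy import stats

from ethotype import (
    Track,
    compute_metricset,
    fit_von_mises,
    interaction_time,
    min_distance_to_point,
    px_to_cm,
    time_outside_refuge,
    total_distance,
    turning_angles,
    utilization_area,
)
from ethotype.metrics import InsufficientDataError

from conftest import make_random_track


def _track(points, duration=3600, test="activity"):
    pts = np.asarray(points, float)
    return Track(id="X", trial=1, test=test, duration_s=duration,
                 t_s=np.arange(len(pts)), x_px=pts[:, 0], y_px=pts[:, 1])


EMPTY = Track(id="E", trial=1, test="exploration", duration_s=3600,
              t_s=np.empty(0, int), x_px=np.empty(0), y_px=np.empty(0))


class TestSimpleMetrics:
    def test_time_outside_counts_detected_seconds(self, rng):
        assert time_outside_refuge(EMPTY) == 0
        full = Track(id="F", trial=1, test="activity", duration_s=3600,
                     t_s=np.arange(3600), x_px=np.zeros(3600) + 1,
                     y_px=np.zeros(3600) + 1)
        assert time_outside_refuge(full) == 3600
        tr = make_random_track(rng, n=137)
        assert time_outside_refuge(tr) == 137

    def test_min_distance_imputed_when_never_detected(self):
        assert min_distance_to_point(EMPTY, (0, 0), 250.0) == 250.0
        assert min_distance_to_point(EMPTY, (0, 0), 350.0) == 350.0

    def test_min_distance_zero_at_the_point(self):
        tr = _track([(10.0, 20.0)])
        assert min_distance_to_point(tr, (10.0, 20.0), 250.0) == 0.0

    def test_min_distance_matches_exhaustive_scan(self, rng):
        tr = make_random_track(rng, n=1000)
        point = (400.0, 300.0)
        brute = min(np.hypot(x - point[0], y - point[1])
                    for x, y in zip(tr.x_px, tr.y_px))
        assert min_distance_to_point(tr, point, 250.0) == brute

    def test_interaction_time_boundary_is_inclusive(self):
        inside = _track([(100.0, 0.0)] * 5)
        assert interaction_time(inside, (0.0, 0.0), 100.0) == 5
        outside = _track([(100.5, 0.0)] * 5)
        assert interaction_time(outside, (0.0, 0.0), 100.0) == 0

    def test_interaction_time_matches_brute_force(self, rng):
        tr = make_random_track(rng, n=1000, hi=300.0)
        point = (150.0, 150.0)
        brute = sum(np.hypot(x - 150.0, y - 150.0) <= 100.0
                    for x, y in zip(tr.x_px, tr.y_px))
        assert interaction_time(tr, point, 100.0) == brute

    def test_total_distance_on_3_4_5_triangles(self):
        assert total_distance(_track([(0, 0), (3, 4), (6, 8)])) == pytest.approx(10.0)
        assert total_distance(_track([(5, 5)])) == 0.0

    def test_total_distance_matches_brute_force(self, rng):
        tr = make_random_track(rng, n=500)
        brute = sum(float(np.hypot(tr.x_px[i + 1] - tr.x_px[i],
                                   tr.y_px[i + 1] - tr.y_px[i]))
                    for i in range(499))
        assert total_distance(tr) == pytest.approx(brute, rel=1e-12)

    @pytest.mark.parametrize("angle", [0.3, 1.2, 2.9])
    def test_total_distance_rigid_motion_invariant(self, rng, angle):
        tr = make_random_track(rng, n=200)
        R = np.array([[np.cos(angle), -np.sin(angle)],
                      [np.sin(angle), np.cos(angle)]])
        xy = tr.xy @ R.T + [37.0, -12.0]
        moved = Track(id=tr.id, trial=1, test=tr.test, duration_s=tr.duration_s,
                      t_s=tr.t_s, x_px=xy[:, 0], y_px=xy[:, 1])
        assert total_distance(moved) == pytest.approx(total_distance(tr), rel=1e-9)


class TestTurningAngles:
    def test_collinear_motion_has_zero_turns(self):
        tr = _track([(0, 0), (1, 1), (2, 2), (3, 3)])
        np.testing.assert_allclose(turning_angles(tr), 0.0)

    def test_square_path_turns_by_right_angles(self):
        tr = _track([(0, 0), (1, 0), (1, 1), (0, 1)])
        np.testing.assert_allclose(turning_angles(tr), [np.pi / 2, np.pi / 2])

    def test_angles_match_atan2_oracle_per_triple(self, rng):
        tr = make_random_track(rng, n=50)
        ang = turning_angles(tr)
        k = 0
        for i in range(48):
            v1 = tr.xy[i + 1] - tr.xy[i]
            v2 = tr.xy[i + 2] - tr.xy[i + 1]
            expected = np.arctan2(v1[0] * v2[1] - v1[1] * v2[0], v1 @ v2)
            assert ang[k] == pytest.approx(expected, abs=1e-12)
            k += 1

    def test_zero_length_displacements_skipped(self):
        tr = _track([(0, 0), (1, 0), (1, 0), (2, 0)])
        np.testing.assert_allclose(turning_angles(tr), [0.0])

    def test_too_few_detections_raise(self):
        with pytest.raises(InsufficientDataError):
            turning_angles(_track([(0, 0), (1, 1)]))


class TestVonMises:
    def test_identical_angles_saturate_kappa(self):
        fit = fit_von_mises(np.zeros(50))
        assert fit.mu == pytest.approx(0.0)
        assert fit.kappa == 500.0
        assert fit.saturated

    def test_antipodal_angles_give_zero_concentration(self):
        fit = fit_von_mises(np.array([0.0, np.pi] * 25))
        assert fit.kappa == pytest.approx(0.0, abs=1e-6)

    def test_mle_recovers_generator_parameters(self, rng):
        draws = rng.vonmises(1.0, 3.0, 100_000)
        fit = fit_von_mises(draws)
        assert fit.mu == pytest.approx(1.0, abs=0.02)
        assert fit.kappa == pytest.approx(3.0, abs=0.1)

    @pytest.mark.parametrize("mu,kappa", [(0.5, 0.8), (-1.2, 2.5), (2.0, 8.0)])
    def test_agrees_with_scipy_mle(self, rng, mu, kappa):
        draws = rng.vonmises(mu, kappa, 20_000)
        fit = fit_von_mises(draws)
        kap_sp, loc_sp, _ = stats.vonmises.fit(draws, fscale=1)
        assert fit.mu == pytest.approx(loc_sp, abs=1e-6)
        assert fit.kappa == pytest.approx(kap_sp, rel=1e-4)

    def test_needs_two_angles(self):
        with pytest.raises(InsufficientDataError):
            fit_von_mises([0.1])


class TestUtilizationArea:
    def test_core_area_nested_in_full_area(self, random_track):
        a50 = utilization_area(random_track, 0.50)
        a95 = utilization_area(random_track, 0.95)
        assert a50 <= a95

    def test_monotone_in_probability(self, random_track):
        areas = [utilization_area(random_track, p)
                 for p in (0.2, 0.4, 0.6, 0.8, 0.95)]
        assert all(a <= b for a, b in zip(areas, areas[1:]))

    def test_uniform_density_area_equals_mass_fraction_of_support(self, rng):
        n = 100_000
        tr = Track(id="U", trial=1, test="activity", duration_s=n,
                   t_s=np.arange(n), x_px=rng.uniform(0, 500, n),
                   y_px=rng.uniform(0, 500, n))
        a = utilization_area(tr, 0.95, bounds=(0, 500, 0, 500))
        assert a == pytest.approx(0.95 * 250_000, rel=0.10)

    def test_point_mass_matches_single_kernel_closed_form(self):
        n = 50
        tr = Track(id="P", trial=1, test="activity", duration_s=n,
                   t_s=np.arange(n), x_px=np.full(n, 250.0),
                   y_px=np.full(n, 250.0))
        areas = []
        for h in (10.0, 20.0):
            a = utilization_area(tr, 0.95, bounds=(0, 500, 0, 500),
                                 bandwidth_px=(h, h))
            # Gaussian HDR: area = 2*pi*h^2 * ln(1/(1-p))
            assert a == pytest.approx(2 * np.pi * h * h * np.log(20.0), rel=0.05)
            areas.append(a)
        assert areas[0] < areas[1]

    def test_too_few_positions_raise(self, rng):
        tr = make_random_track(rng, n=19)
        with pytest.raises(InsufficientDataError):
            utilization_area(tr, 0.95)


class TestMetricSetDispatch:
    def test_exploration_never_detected_gets_imputed_triplet(self, arena):
        ms = compute_metricset(EMPTY, arena, "exploration")
        assert ms.time_outside_s == 0
        assert ms.min_distance_px == 250.0
        assert ms.interaction_time_s == 0

    def test_sociability_impute_is_350(self, arena):
        ms = compute_metricset(EMPTY, arena, "sociability")
        assert ms.min_distance_px == 350.0

    def test_activity_below_20_positions_flagged_absent(self, arena, rng):
        tr = make_random_track(rng, n=19, test="activity")
        ms = compute_metricset(tr, arena)
        assert np.isnan(ms.total_distance_px) and np.isnan(ms.area95_px2)
        assert ms.flags

    def test_sociability_at_conspecific_interacts_every_second(self, arena):
        pts = [arena.conspecific_point] * 30
        tr = _track(pts, test="sociability")
        ms = compute_metricset(tr, arena)
        assert ms.interaction_time_s == ms.time_outside_s == 30

    def test_unknown_test_rejected(self, arena, random_track):
        with pytest.raises(ValueError, match="unknown test"):
            compute_metricset(random_track, arena, "flying")


class TestCalibration:
    @pytest.mark.parametrize("px,cm", [(250.0, 15.0), (100.0, 6.0)])
    def test_paper_scale_conversions(self, px, cm):
        assert px_to_cm(px) == pytest.approx(cm, abs=0.05)

    def test_minimum_approach_distance(self):
        assert round(px_to_cm(33.0), 2) == 1.98

    def test_calibration_identity(self):
        assert px_to_cm(16.7) == 1.0
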