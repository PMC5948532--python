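import math

import numpy as np
import pytest

from semgkit import game as gm
from semgkit import gestures as G
from semgkit import synthetic as syn


def straight_trace(n=50, dt=0.1, cursor_v=(10.0, 0.0), target_xy=(1000.0, 0.0), q=None):
    """Cursor moving at constant velocity toward a stationary target."""
    t = dt * np.arange(n)
    cursor = np.outer(t, cursor_v)
    target = np.tile(target_xy, (n, 1))
    return gm.GameTrace(times=t, cursor=cursor, target=target, q=q)


class TestDownsample:
    def test_dense_long_trace_is_capped_at_hundred_points(self):
        t = np.linspace(0, 100, 2000)
        trace = gm.GameTrace(
            times=t, cursor=np.zeros((2000, 2)) + t[:, None], target=np.ones((2000, 2))
        )
        sparse = gm.downsample(trace)
        assert len(sparse) <= 100

    def test_endpoints_preserved_exactly(self):
        t = np.linspace(0, 10, 500)
        cursor = np.column_stack([t, t**2])
        trace = gm.GameTrace(times=t, cursor=cursor, target=cursor + 1.0)
        sparse = gm.downsample(trace)
        assert sparse.times[0] == t[0] and sparse.times[-1] == t[-1]
        assert np.allclose(sparse.cursor[0], cursor[0])
        assert np.allclose(sparse.cursor[-1], cursor[-1])

    def test_already_sparse_trace_unchanged(self):
        trace = straight_trace(n=30)
        assert gm.downsample(trace) is trace

    def test_single_point_rejected(self):
        trace = straight_trace(n=2)
        with pytest.raises(ValueError, match="fewer than 2"):
            gm.downsample(
                gm.GameTrace(
                    times=trace.times[:1],
                    cursor=trace.cursor[:1],
                    target=trace.target[:1],
                )
            )


class TestVelocities:
    def test_uniform_motion_gives_constant_velocity(self):
        trace = straight_trace(cursor_v=(3.0, -4.0))
        w = gm.velocities(trace.cursor, trace.times)
        assert np.allclose(w, [3.0, -4.0])

    def test_stationary_gives_zero(self):
        t = 0.1 * np.arange(20)
        w = gm.velocities(np.ones((20, 2)), t)
        assert np.allclose(w, 0.0)

    def test_output_one_shorter_than_input(self):
        trace = straight_trace(n=17)
        assert gm.velocities(trace.cursor, trace.times).shape == (16, 2)

    def test_repeated_timestamps_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            gm.velocities(np.zeros((3, 2)), np.array([0.0, 0.0, 1.0]))


class TestBestDirection:
    def test_stationary_target_gives_line_of_sight(self):
        n = gm.best_direction([0, 0], [1.0, 0.0], [3.0, 4.0], [0.0, 0.0], 0.1)
        assert np.allclose(n, [0.6, 0.8])
        t = gm.interception_time([0, 0], [1.0, 0.0], [3.0, 4.0], [0.0, 0.0])
        assert t == pytest.approx(5.0)  # ||d|| / ||omega_p||

    def test_head_on_interception_hand_solved(self):
        # d=(10,0), target approaching at (-1,0), cursor speed 1:
        # quadratic reduces to -20 t + 100 = 0 -> t*=5, n=(1,0)
        t = gm.interception_time([0, 0], [1.0, 0.0], [10.0, 0.0], [-1.0, 0.0])
        assert t == pytest.approx(5.0)
        n = gm.best_direction([0, 0], [1.0, 0.0], [10.0, 0.0], [-1.0, 0.0], 0.1)
        assert np.allclose(n, [1.0, 0.0])

    def test_receding_faster_target_falls_back_to_lead_pursuit(self):
        # target receding along d at twice the cursor speed: no root
        d = np.array([10.0, 0.0])
        wc = np.array([2.0, 0.0])
        dt = 0.5
        assert gm.interception_time([0, 0], [1.0, 0.0], d, wc) is None
        n = gm.best_direction([0, 0], [1.0, 0.0], d, wc, dt)
        expected = (d + wc * dt) / np.linalg.norm(d + wc * dt)
        assert np.allclose(n, expected)

    def test_motionless_cursor_uses_fallback(self):
        n = gm.best_direction([0, 0], [0.0, 0.0], [5.0, 0.0], [0.0, 1.0], 0.1)
        expected = np.array([5.0, 0.1]) / np.hypot(5.0, 0.1)
        assert np.allclose(n, expected)

    def test_coincident_positions_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            gm.best_direction([1, 1], [1, 0], [1, 1], [0, 0], 0.1)

    def test_returns_unit_vector_on_random_geometries(self, rng):
        for _ in range(300):
            rho_p = rng.uniform(-50, 50, 2)
            rho_c = rng.uniform(-50, 50, 2)
            if np.allclose(rho_p, rho_c):
                continue
            n = gm.best_direction(
                rho_p,
                rng.uniform(-5, 5, 2),
                rho_c,
                rng.uniform(-5, 5, 2),
                0.05,
            )
            assert np.hypot(*n) == pytest.approx(1.0, abs=1e-9)


def brute_force_interception(rho_p, speed, rho_c, omega_c, n, dt=1e-3, horizon=500.0):
    """Step the cursor along the fixed direction n at constant speed and
    return the first time it comes within one step of the target."""
    p = np.asarray(rho_p, float).copy()
    c = np.asarray(rho_c, float).copy()
    t = 0.0
    tol = speed * dt + np.linalg.norm(omega_c) * dt
    while t < horizon:
        if np.linalg.norm(c - p) <= tol:
            return t
        p += speed * np.asarray(n) * dt
        c += np.asarray(omega_c) * dt
        t += dt
    return None


class TestInterceptionConsistency:
    def test_pursuit_along_best_direction_arrives_at_t_star(self, rng):
        checked = 0
        for _ in range(100):
            rho_p = rng.uniform(-20, 20, 2)
            rho_c = rng.uniform(-20, 20, 2)
            if np.linalg.norm(rho_c - rho_p) < 1.0:
                continue
            speed = rng.uniform(0.5, 5.0)
            omega_p = speed * np.array([1.0, 0.0])
            omega_c = rng.uniform(-3, 3, 2)
            t_star = gm.interception_time(rho_p, omega_p, rho_c, omega_c)
            if t_star is None or t_star > 100:
                continue
            n = gm.best_direction(rho_p, omega_p, rho_c, omega_c, 0.05)
            t_brute = brute_force_interception(rho_p, speed, rho_c, omega_c, n)
            assert t_brute is not None
            assert abs(t_brute - t_star) <= 2e-3 + 0.01 * t_star
            checked += 1
        assert checked >= 50


class TestAngularDeviation:
    def test_straight_pursuit_of_stationary_target_is_zero(self):
        trace = straight_trace()
        alpha = gm.angular_deviation(trace)
        assert np.allclose(alpha, 0.0, atol=1e-9)

    def test_moving_opposite_to_best_direction_is_pi(self):
        trace = straight_trace(cursor_v=(-10.0, 0.0), target_xy=(1000.0, 0.0))
        alpha = gm.angular_deviation(trace)
        assert np.allclose(np.abs(alpha), math.pi)

    def test_mirror_reflection_negates_angles(self, rng):
        t = 0.1 * np.arange(40)
        cursor = np.cumsum(rng.uniform(-1, 2, (40, 2)), axis=0)
        target = np.column_stack([50 + 2 * t, 30 - t])
        trace = gm.GameTrace(times=t, cursor=cursor, target=target)
        mirrored = gm.GameTrace(
            times=t,
            cursor=cursor * [1, -1],
            target=target * [1, -1],
        )
        a = gm.angular_deviation(trace)
        b = gm.angular_deviation(mirrored)
        assert np.allclose(a, -b, atol=1e-9)


class TestDecisionStats:
    def test_all_zero_angles_peak_at_zero_with_no_spread(self):
        stats = gm.decision_stats(np.zeros(100))
        assert abs(stats.peak_location) < 2 * math.pi / 36
        assert stats.spread == pytest.approx(0.0, abs=1e-9)
        assert stats.peak_stable

    def test_uniform_angles_flagged_unstable_with_large_spread(self, rng):
        alpha = rng.uniform(-math.pi, math.pi, 5000)
        stats = gm.decision_stats(alpha)
        assert not stats.peak_stable
        assert stats.spread > 1.5

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            gm.decision_stats(np.zeros(5))

    def test_narrower_intent_noise_shrinks_spread(self):
        spreads = []
        for noise in (0.8, 0.4, 0.1):
            vals = []
            for seed in range(6):
                profile = syn.SubjectProfile(
                    reaction_delay=0.1,
                    angular_noise_sd=noise,
                    per_gesture_error_rate={g: 0.0 for g in G.DIRECTIONAL},
                )
                trace = syn.simulate_game_trace(
                    syn.GameScenario(duration=60.0), profile, seed=seed
                )
                alpha = gm.angular_deviation(gm.downsample(trace))
                vals.append(gm.decision_stats(alpha).spread)
            spreads.append(np.mean(vals))
        assert spreads[0] > spreads[1] > spreads[2]


class TestGestureFidelity:
    def test_cone_threshold_matches_arccos(self):
        # the printed 0.92 rad cone is arccos of the 0.6 threshold
        assert math.acos(0.6) == pytest.approx(0.927, abs=5e-4)

    def test_cone_membership_on_dense_angle_grid(self):
        """δ at angle θ from n is optimal exactly when θ < arccos(d_th)."""
        angles = np.linspace(-math.pi, math.pi, 73, endpoint=False)
        n_pts = len(angles)
        q = np.zeros((n_pts, 4))
        q[:, 1] = 0.5 + 0.5 * np.cos(angles)  # qr - ql = cos
        q[:, 0] = 0.5 - 0.5 * np.cos(angles)
        q[:, 2] = 0.5 + 0.5 * np.sin(angles)
        q[:, 3] = 0.5 - 0.5 * np.sin(angles)
        trace = straight_trace(n=n_pts, q=q)  # n = (1, 0) everywhere
        d_th = 0.6
        stats = gm.gesture_fidelity(trace, d_th=d_th)
        n_vecs = gm.best_directions(trace)
        inside = [
            abs(a) < math.acos(d_th)
            for a, nv in zip(angles[:-1], n_vecs)
            if not np.any(np.isnan(nv))
        ]
        opt_total = sum(v for (d, k), v in stats.rates.items() if k == "opt")
        # every grid point has |δ|=1 and a dominant component except the
        # exact diagonals; optimal rate tracks the cone fraction
        assert opt_total == pytest.approx(np.mean(inside), abs=0.05)

    def test_rate_sets_are_disjoint_and_bounded(self, rng):
        q = rng.random((80, 4))
        trace = straight_trace(n=80, q=q)
        stats = gm.gesture_fidelity(trace)
        assert all(0.0 <= v <= 1.0 for v in stats.rates.values())
        assert sum(stats.rates.values()) <= 1.0 + 1e-12

    def test_left_pointing_intent_lands_in_left_set(self):
        # target to the LEFT of the moving cursor; δ points left
        n_pts = 40
        q = np.tile([0.9, 0.1, 0.5, 0.5], (n_pts, 1))
        q += 0.01 * np.random.default_rng(0).standard_normal((n_pts, 4))
        t = 0.1 * np.arange(n_pts)
        cursor = np.column_stack([100 - 10 * t, np.zeros(n_pts)])
        target = np.tile([-1000.0, 0.0], (n_pts, 1))
        trace = gm.GameTrace(times=t, cursor=cursor, target=target, q=q)
        stats = gm.gesture_fidelity(trace)
        assert stats.rates[("left", "opt")] > 0.9

    def test_all_zero_intent_rejected(self):
        q = np.full((30, 4), 0.5)
        trace = straight_trace(n=30, q=q)
        with pytest.raises(ValueError, match="all-zero intent"):
            gm.gesture_fidelity(trace)

    def test_missing_q_rejected(self):
        with pytest.raises(ValueError, match="no classifier output"):
            gm.gesture_fidelity(straight_trace())


def test_trace_csv_round_trip(tmp_path, rng):
    trace = straight_trace(n=25, q=rng.random((25, 4)))
    path = tmp_path / "trace.csv"
    trace.to_csv(path)
    back = gm.GameTrace.from_csv(path)
    assert np.allclose(back.cursor, trace.cursor)
    assert np.allclose(back.q, trace.q)
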