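"""Trajectory generator: baseline reach, injected response, artifacts."""

import numpy as np
import pytest
from scipy.integrate import quad

from endpointmotion import (
    Condition,
    NoiseModel,
    ReachModel,
    ResponseModel,
    TrialSpec,
    build_schedule,
    simulate_session,
    simulate_trial,
)
from endpointmotion.synthetic import (
    DT,
    injected_displacement,
    injected_velocity,
    injected_window_mean,
    response_kernel,
    response_kernel_integral,
)


def _spec(direction="right", onset=0.35, side=7.0, kind="frame"):
    return TrialSpec(0, 0, Condition(kind, side, direction), 0.6, onset)


class TestKernel:
    def test_unit_peak_and_compact_support(self):
        s = np.linspace(-0.5, 1.5, 2001)
        k = response_kernel(s)
        assert k.max() == pytest.approx(1.0)
        assert np.all(k[(s < 0) | (s > 1)] == 0)

    def test_closed_form_integral_matches_quadrature(self):
        # independent oracle: numerical quadrature of the kernel
        for s in (0.1, 0.3, 0.5, 0.77, 1.0):
            expected, _ = quad(response_kernel, 0, s)
            assert response_kernel_integral(s) == pytest.approx(expected, abs=1e-10)

    def test_window_mean_matches_quadrature(self, geom, resp):
        cond = Condition("frame", 7.0, "right")
        lo, hi = 0.15, 0.20
        n = int(round((hi - lo) / DT)) + 1
        num, _ = quad(
            lambda t: injected_velocity(t, 0.0, cond, resp, geom), lo, lo + n * DT
        )
        assert injected_window_mean(cond, resp, geom) == pytest.approx(
            2 * num / (n * DT), rel=1e-9
        )


class TestTrajectoryShape:
    def test_exact_2ms_grid_and_nonnegative_z(self, clean_session):
        for traj in clean_session:
            assert np.allclose(np.diff(traj.sample_times), DT, atol=1e-12)
            pre_contact = traj.sample_times <= traj.contact_time
            assert np.all(traj.positions[pre_contact, 2] >= 0)

    def test_recording_covers_trial(self, clean_session):
        for traj in clean_session:
            assert traj.sample_times[0] >= -traj.trial.start_delay - DT
            assert traj.sample_times[-1] >= traj.contact_time + 0.1

    def test_session_deterministic(self, small_schedule, resp, geom):
        a = simulate_session(small_schedule, resp, NoiseModel(), geom, seed=42)
        b = simulate_session(small_schedule, resp, NoiseModel(), geom, seed=42)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.positions, tb.positions, equal_nan=True)
            assert np.array_equal(ta.missing_mask, tb.missing_mask)
            assert ta.contact_time == tb.contact_time

    def test_one_trajectory_per_trial(self, full_session):
        assert len(full_session) == 600


class TestBaselineReach:
    def test_minimum_jerk_rest_at_both_ends(self, geom, silent_noise):
        # lateral/vertical velocity and acceleration vanish at movement onset
        # and at contact (checked by finite differences on the clean path)
        resp = ResponseModel().with_uniform_gain(0.0)
        traj = simulate_trial(_spec(), resp, silent_noise, geom, seed=8)
        t = traj.sample_times
        x = traj.positions[:, 0]
        v = np.diff(x) / DT
        a = np.diff(v) / DT
        reach = ReachModel()
        for t_edge in (reach.reaction_time, traj.contact_time):
            i = np.searchsorted(t, t_edge)
            near = slice(max(i - 2, 0), i + 2)
            assert np.all(np.abs(v[near]) < 1.5)    # cm/s
            assert np.all(np.abs(a[near]) < 120.0)  # cm/s^2

    def test_contact_with_configured_approach_speed(self, geom, silent_noise, resp):
        traj = simulate_trial(_spec(), resp, silent_noise, geom, seed=8)
        z = traj.positions[:, 2]
        i = int(np.searchsorted(traj.sample_times, traj.contact_time))
        approach = (z[i - 2] - z[i - 1]) / DT
        assert approach == pytest.approx(ReachModel().approach_speed, rel=0.05)

    def test_inconsistent_reach_rejected(self, geom, silent_noise, resp):
        late_start = ReachModel(reaction_time=0.7)
        with pytest.raises(ValueError, match="inconsistent"):
            simulate_trial(_spec(), resp, silent_noise, geom, seed=0, reach=late_start)


class TestInjectedResponse:
    def test_zero_gain_makes_directions_identical(self, geom, silent_noise):
        resp = ResponseModel().with_uniform_gain(0.0)
        right = simulate_trial(_spec("right"), resp, silent_noise, geom, seed=3)
        left = simulate_trial(_spec("left"), resp, silent_noise, geom, seed=3)
        assert np.array_equal(right.positions, left.positions)

    def test_direction_difference_is_twice_injected_profile(self, geom, silent_noise, resp):
        spec_r, spec_l = _spec("right", onset=0.3), _spec("left", onset=0.3)
        right = simulate_trial(spec_r, resp, silent_noise, geom, seed=3)
        left = simulate_trial(spec_l, resp, silent_noise, geom, seed=3)
        t = right.sample_times
        diff = right.positions[:, 0] - left.positions[:, 0]
        cond_r = spec_r.condition
        expected = 2 * injected_displacement(
            np.minimum(t, right.contact_time), 0.3, cond_r, resp, geom
        )
        assert np.allclose(diff, expected, atol=1e-9)

    def test_total_injected_displacement_independent_of_onset_phase(
        self, geom, silent_noise, resp
    ):
        # the bump integrates to gain * speed * width / 2 regardless of how
        # the onset falls relative to the 2-ms sampling grid
        expected = resp.gain_for(Condition("frame", 7.0, "right")) * geom.square_speed * resp.kernel_width / 2
        for onset in (0.300, 0.3007, 0.3013):
            r = simulate_trial(_spec("right", onset=onset), resp, silent_noise, geom, seed=3)
            l = simulate_trial(_spec("left", onset=onset), resp, silent_noise, geom, seed=3)
            shift = (r.positions[-1, 0] - l.positions[-1, 0]) / 2
            assert shift == pytest.approx(expected, abs=expected * 0.01)

    def test_gain_scales_with_size_and_not_kind(self, resp):
        g = {s: resp.gain_for(Condition("frame", s, "right")) for s in (7.0, 37.0, 67.0)}
        assert g[7.0] > g[37.0] > g[67.0]
        for s in (7.0, 37.0, 67.0):
            assert resp.gain_for(Condition("tile", s, "left")) == resp.gain_for(
                Condition("frame", s, "left")
            )


class TestArtifacts:
    def test_missing_trial_count_within_binomial_bounds(self, geom, resp):
        from scipy.stats import binom

        noise = NoiseModel(missing_rate=0.01, timing_issue_rate=0.0)
        schedule = build_schedule(25, 2, seed=6)
        session = simulate_session(schedule, resp, noise, geom, seed=6)
        n_missing = sum(t.missing_mask.any() for t in session)
        lo, hi = binom.ppf([0.005, 0.995], 600, 0.01)
        assert lo <= n_missing <= hi

    def test_missing_gap_is_contiguous(self, geom, resp):
        noise = NoiseModel(missing_rate=1.0)
        traj = simulate_trial(_spec(), resp, noise, geom, seed=1)
        idx = np.flatnonzero(traj.missing_mask)
        assert 10 <= len(idx) <= 50
        assert np.all(np.diff(idx) == 1)
        assert np.all(np.isnan(traj.positions[idx]))

    def test_timing_issue_shifts_recorded_onset_past_one_frame(self, geom, resp):
        noise = NoiseModel(timing_issue_rate=1.0, missing_rate=0.0)
        for seed in range(5):
            traj = simulate_trial(_spec(), resp, noise, geom, seed=seed)
            dev = abs(traj.recorded_square_onset - traj.trial.square_onset)
            assert dev > 1 / 120
            offset_dev = abs(
                traj.recorded_square_offset
                - (traj.trial.square_onset + geom.square_motion_duration)
            )
            assert offset_dev > 1 / 120

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            NoiseModel(missing_rate=1.5)
        with pytest.raises(ValueError):
            NoiseModel(position_sd=-0.1)
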