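"""Exclusion rules, response curves, magnitudes and group aggregation."""

import dataclasses

import numpy as np
import pytest

from endpointmotion import (
    Condition,
    NoiseModel,
    ResponseModel,
    ResponseCurve,
    ResponseMagnitude,
    TrialSpec,
    build_schedule,
    exclude_trials,
    group_summary,
    response_curve,
    response_magnitude,
    simulate_session,
    simulate_trial,
)
from endpointmotion.analysis import N_LAGS, lag_grid
from endpointmotion.synthetic import DT, injected_displacement, injected_velocity


def _spec(direction, onset=0.35, side=7.0, kind="frame", index=0):
    return TrialSpec(index, 0, Condition(kind, side, direction), 0.6, onset)


def _pair(resp, silent_noise, geom, onset=0.35, side=7.0, seed=3):
    right = simulate_trial(_spec("right", onset, side), resp, silent_noise, geom, seed=seed)
    left = simulate_trial(_spec("left", onset, side), resp, silent_noise, geom, seed=seed)
    return [right, left]


class TestExclusion:
    def test_clean_session_fully_kept(self, clean_session):
        kept, report = exclude_trials(clean_session)
        assert len(kept) == len(clean_session)
        assert report.n_timing == report.n_missing == 0

    def test_missing_outside_analysis_window_is_kept(self, clean_session):
        traj = dataclasses.replace(clean_session[0])
        traj.missing_mask = traj.missing_mask.copy()
        traj.missing_mask[:5] = True  # long before square-motion onset
        kept, report = exclude_trials([traj])
        assert len(kept) == 1
        assert report.n_missing == 0

    def test_missing_inside_window_is_excluded(self, clean_session):
        traj = dataclasses.replace(clean_session[0])
        traj.missing_mask = traj.missing_mask.copy()
        i = int(np.searchsorted(traj.sample_times, traj.recorded_square_onset + 0.1))
        traj.missing_mask[i] = True
        kept, report = exclude_trials([traj])
        assert len(kept) == 0
        assert report.n_missing == 1

    def test_timing_shift_beyond_one_frame_is_excluded(self, clean_session):
        traj = dataclasses.replace(
            clean_session[0],
            recorded_square_onset=clean_session[0].trial.square_onset + 0.012,
            recorded_square_offset=clean_session[0].trial.square_onset + 0.112,
        )
        kept, report = exclude_trials([traj])
        assert len(kept) == 0 and report.n_timing == 1

    def test_removal_counts_within_binomial_bounds(self, full_session):
        from scipy.stats import binom

        _, report = exclude_trials(full_session)
        lo_t, hi_t = binom.ppf([0.005, 0.995], 600, 0.005)
        lo_m, hi_m = binom.ppf([0.005, 0.995], 600, 0.01)
        assert lo_t <= report.n_timing <= hi_t
        assert lo_m <= report.n_missing <= hi_m


class TestResponseCurve:
    def test_zero_gain_gives_null_curve(self, silent_noise, geom):
        resp = ResponseModel().with_uniform_gain(0.0)
        curve = response_curve(_pair(resp, silent_noise, geom), geom)
        finite = np.isfinite(curve.values)
        assert finite.any()
        assert np.all(np.abs(curve.values[finite]) < 1e-9)

    def test_curve_equals_twice_injected_profile(self, resp, silent_noise, geom):
        onset = 0.35  # an exact multiple of the 2-ms sampling interval
        trials = _pair(resp, silent_noise, geom, onset=onset)
        curve = response_curve(trials, geom)
        cond = Condition("frame", 7.0, "right")
        edges = onset + np.arange(N_LAGS + 1) * DT
        d = injected_displacement(np.minimum(edges, trials[0].contact_time), onset, cond, resp, geom)
        expected = 2 * np.diff(d) / DT
        finite = np.isfinite(curve.values)
        assert np.allclose(curve.values[finite], expected[finite], atol=1e-9)
        # and, more loosely, the continuous injected velocity profile itself
        continuous = 2 * injected_velocity(onset + lag_grid() + DT / 2, onset, cond, resp, geom)
        assert np.max(np.abs(curve.values[finite] - continuous[finite])) < 0.3

    def test_relabelling_directions_negates_curve(self, resp, silent_noise, geom):
        trials = _pair(resp, silent_noise, geom)
        flipped = []
        for t in trials:
            cond = t.trial.condition
            other = "left" if cond.motion_direction == "right" else "right"
            flipped.append(
                dataclasses.replace(
                    t,
                    trial=dataclasses.replace(
                        t.trial, condition=dataclasses.replace(cond, motion_direction=other)
                    ),
                )
            )
        a = response_curve(trials, geom)
        b = response_curve(flipped, geom)
        both = np.isfinite(a.values) & np.isfinite(b.values)
        assert np.array_equal(a.values[both], -b.values[both])

    def test_direction_with_no_trials_is_diagnosed(self, resp, silent_noise, geom):
        only_right = [simulate_trial(_spec("right"), resp, silent_noise, geom, seed=1)]
        with pytest.raises(ValueError, match="leftward"):
            response_curve(only_right, geom)

    def test_mixed_conditions_rejected(self, resp, silent_noise, geom):
        mixed = [
            simulate_trial(_spec("right", side=7.0), resp, silent_noise, geom, seed=1),
            simulate_trial(_spec("left", side=37.0), resp, silent_noise, geom, seed=1),
        ]
        with pytest.raises(ValueError, match="multiple conditions"):
            response_curve(mixed, geom)


class TestResponseMagnitude:
    def test_constant_curve_gives_its_value(self):
        curve = ResponseCurve(lag_grid(), np.full(N_LAGS, 1.7), "p0", "frame", 7.0, 1, 1)
        assert response_magnitude(curve).value == pytest.approx(1.7)

    def test_window_uses_26_inclusive_points(self):
        values = np.zeros(N_LAGS)
        window = (lag_grid() >= 0.15 - 1e-9) & (lag_grid() <= 0.20 + 1e-9)
        assert window.sum() == 26
        values[window] = 2.0
        curve = ResponseCurve(lag_grid(), values, "p0", "frame", 7.0, 1, 1)
        assert response_magnitude(curve).value == pytest.approx(2.0)

    def test_uncovered_window_rejected(self):
        short = ResponseCurve(lag_grid()[:50], np.zeros(50), "p0", "frame", 7.0, 1, 1)
        with pytest.raises(ValueError, match="window"):
            response_magnitude(short)

    def test_magnitude_matches_injected_window_mean(self, resp, silent_noise, geom):
        from endpointmotion.synthetic import injected_window_mean

        trials = _pair(resp, silent_noise, geom, onset=0.35)
        mag = response_magnitude(response_curve(trials, geom))
        expected = injected_window_mean(Condition("frame", 7.0, "right"), resp, geom)
        assert mag.value == pytest.approx(expected, rel=0.02)


class TestGroupSummary:
    def _mags(self, values_by_participant):
        out = []
        for pid, vals in values_by_participant.items():
            for (kind, side), v in vals.items():
                out.append(ResponseMagnitude(pid, kind, side, v))
        return out

    def _curves(self, values_by_participant):
        out = []
        for pid, vals in values_by_participant.items():
            for (kind, side), v in vals.items():
                out.append(
                    ResponseCurve(lag_grid(), np.full(N_LAGS, v), pid, kind, side, 1, 1)
                )
        return out

    def test_identical_participants_have_zero_sem(self):
        vals = {("frame", 7.0): 2.0, ("tile", 7.0): 2.0}
        data = {"p0": vals, "p1": vals, "p2": vals}
        g = group_summary(self._curves(data), self._mags(data))
        assert np.allclose(g.magnitude_summary["sem_cm_s"], 0.0)
        assert np.allclose(g.curve_summary["sem_cm_s"], 0.0)

    def test_two_participants_closed_form(self):
        data = {
            "p0": {("frame", 7.0): 1.0},
            "p1": {("frame", 7.0): 3.0},
        }
        g = group_summary(self._curves(data), self._mags(data))
        row = g.magnitude_summary.iloc[0]
        assert row["mean_cm_s"] == pytest.approx(2.0)
        assert row["sem_cm_s"] == pytest.approx(1.0)  # |a - b| / 2

    def test_single_participant_rejected(self):
        data = {"p0": {("frame", 7.0): 1.0}}
        with pytest.raises(ValueError, match="participants"):
            group_summary(self._curves(data), self._mags(data))

    def test_pairing_matches_magnitudes(self):
        data = {
            "p0": {("frame", 7.0): 1.0, ("tile", 7.0): 1.5},
            "p1": {("frame", 7.0): 2.0, ("tile", 7.0): 2.5},
        }
        g = group_summary(self._curves(data), self._mags(data))
        assert set(g.pairing.columns) >= {"participant", "side_cm", "frame_cm_s", "tile_cm_s"}
        row = g.pairing.set_index("participant").loc["p0"]
        assert row["frame_cm_s"] == 1.0 and row["tile_cm_s"] == 1.5
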