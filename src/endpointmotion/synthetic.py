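"""Synthetic 500-Hz finger-marker trajectories with a known following response.

No raw kinematic data were deposited for this paradigm, so the pipeline is
validated by parameter recovery: this module generates whole sessions of
marker trajectories in which the manual following response is *injected* with
known latency, gain and time course, and the analysis must recover it.

A trial is built from three ingredients:

1. A stylized baseline reach.  Lateral (x) and vertical (y) position follow a
   minimum-jerk path from the start point to a planned tap point, arriving at
   a contact time drawn around 662 ms after target appearance.  The
   screen-normal coordinate z is a two-segment minimum-jerk profile: a lift
   from the screen to a peak height, then a strike through the screen plane
   toward a virtual point behind it.  Contact happens at the strike segment's
   velocity peak, so the finger meets the screen at a configurable approach
   speed (real taps decelerate abruptly on impact, which is what the
   deceleration-based tap detector keys on) and the contact time is exact by
   construction.

2. The following response: a lateral velocity perturbation
   ``v(t) = gain * square_speed * K((t - onset - latency) / width)`` in the
   square's motion direction, with ``K`` a raised-cosine bump of unit peak.
   Its time-integral (the injected displacement) is closed-form, which gives
   the analysis an analytic oracle.

3. Measurement artifacts: additive Gaussian position noise, tap-point
   scatter, an occasional contiguous dropped-sample gap, and an occasional
   square-motion timing error, at the rates the study reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .paradigm import Condition, Geometry, Schedule, TrialSpec, target_position

__all__ = [
    "DT",
    "SAMPLE_RATE_HZ",
    "ResponseModel",
    "NoiseModel",
    "ReachModel",
    "Trajectory",
    "RigidTransform",
    "minimum_jerk",
    "minimum_jerk_velocity",
    "response_kernel",
    "response_kernel_integral",
    "injected_velocity",
    "injected_window_mean",
    "simulate_trial",
    "simulate_session",
    "make_miscalibration",
    "calibration_correspondences",
]

SAMPLE_RATE_HZ = 500.0
DT = 1.0 / SAMPLE_RATE_HZ  # 2-ms marker sampling interval


# ---------------------------------------------------------------------------
# models

@dataclass(frozen=True)
class ResponseModel:
    """Parameters of the injected manual following response.

    ``gain`` is the peak lateral hand velocity as a fraction of the square's
    speed; per-size gains (and a per-kind multiplier) override it.  The
    defaults decrease with square size and are identical for frame and tile,
    i.e. the response scales with the proximity of the nearest moving edge
    and ignores the surface interpretation.  Latency 120 ms and width 150 ms
    place the response bump at ~120-270 ms after motion onset.
    """

    latency: float = 0.12
    gain: float = 0.1
    kernel_width: float = 0.15
    gain_by_size: dict[float, float] = field(
        default_factory=lambda: {7.0: 0.10, 37.0: 0.075, 67.0: 0.04}
    )
    gain_by_kind: dict[str, float] = field(
        default_factory=lambda: {"frame": 1.0, "tile": 1.0}
    )

    def __post_init__(self) -> None:
        if self.latency < 0:
            raise ValueError("latency must be >= 0")
        if self.kernel_width <= 0:
            raise ValueError("kernel_width must be positive")
        if self.gain < 0 or any(g < 0 for g in self.gain_by_size.values()):
            raise ValueError("gains must be >= 0")

    def gain_for(self, cond: Condition) -> float:
        base = self.gain_by_size.get(cond.square_side, self.gain)
        return base * self.gain_by_kind.get(cond.square_kind, 1.0)

    def with_uniform_gain(self, gain: float) -> "ResponseModel":
        sizes = set(self.gain_by_size)
        return replace(self, gain=gain, gain_by_size={s: gain for s in sizes})


@dataclass(frozen=True)
class NoiseModel:
    """Measurement artifacts injected into a simulated trial.

    ``position_sd`` is white marker noise per axis (Optotrak-class precision,
    default 0.005 cm).  ``endpoint_sd`` is the per-axis scatter of the tap
    point around the target; 0.65 cm makes ~70% of taps land within the 1-cm
    target radius.  ``missing_rate`` / ``timing_issue_rate`` are per-trial
    probabilities of a dropped-sample gap and of a square-motion timing error.
    """

    position_sd: float = 0.005
    endpoint_sd: float = 0.65
    missing_rate: float = 0.01
    timing_issue_rate: float = 0.005
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "timing_issue_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.position_sd < 0 or self.endpoint_sd < 0:
            raise ValueError("noise sds must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseModel":
        """All artifacts off; used for oracle comparisons."""
        return cls(position_sd=0.0, endpoint_sd=0.0, missing_rate=0.0, timing_issue_rate=0.0)


@dataclass(frozen=True)
class ReachModel:
    """Baseline reach kinematics (everything except the following response).

    ``contact_mean``/``contact_sd`` match the observed screen-contact times
    (662 +/- 27 ms after target appearance).  ``approach_speed`` is the
    screen-normal speed at impact; 100 cm/s gives a 2-mm approach step per
    sample, comfortably above the 1-mm tap-detection criterion.
    """

    reaction_time: float = 0.2      # s, target appearance -> movement onset
    contact_mean: float = 0.662     # s, target appearance -> screen contact
    contact_sd: float = 0.027
    lift_height: float = 4.0        # cm, peak finger height above the screen
    approach_speed: float = 100.0   # cm/s at screen contact
    record_after_contact: float = 0.12  # s of recording kept past contact

    def __post_init__(self) -> None:
        if self.lift_height <= 0 or self.approach_speed <= 0:
            raise ValueError("lift_height and approach_speed must be positive")

    @property
    def strike_duration(self) -> float:
        # min-jerk peak speed over amplitude 2h in time T is 1.875 * 2h / T
        return 3.75 * self.lift_height / self.approach_speed


@dataclass
class Trajectory:
    """Uniformly sampled 3-D marker positions for one trial.

    ``positions[:, 0]`` is lateral (x), ``[:, 1]`` vertical (y), ``[:, 2]``
    perpendicular distance to the screen (z), all cm.  ``sample_times`` are
    seconds after target appearance on an exact 2-ms grid.  Missing samples
    are flagged in ``missing_mask`` and NaN in ``positions``.
    ``recorded_square_onset``/``offset`` are what the recording system logged
    (equal to the commanded times except on timing-issue trials).
    ``contact_time`` is the generator's ground-truth screen-contact time.
    """

    sample_times: np.ndarray
    positions: np.ndarray
    missing_mask: np.ndarray
    trial: TrialSpec
    recorded_square_onset: float
    recorded_square_offset: float
    contact_time: float

    def __post_init__(self) -> None:
        steps = np.diff(self.sample_times)
        if len(steps) and not np.allclose(steps, DT, atol=1e-12):
            raise ValueError("sample_times must be on an exact 2-ms grid")

    @property
    def n_samples(self) -> int:
        return len(self.sample_times)


# ---------------------------------------------------------------------------
# analytic building blocks

def minimum_jerk(s: np.ndarray | float) -> np.ndarray:
    """Normalized minimum-jerk position profile 10s^3 - 15s^4 + 6s^5 on [0, 1]."""
    s = np.clip(np.asarray(s, dtype=float), 0.0, 1.0)
    return s**3 * (10.0 - 15.0 * s + 6.0 * s**2)


def minimum_jerk_velocity(s: np.ndarray | float) -> np.ndarray:
    """Derivative of :func:`minimum_jerk` with respect to s (zero outside [0, 1])."""
    s_arr = np.asarray(s, dtype=float)
    inside = (s_arr >= 0.0) & (s_arr <= 1.0)
    s_c = np.clip(s_arr, 0.0, 1.0)
    return np.where(inside, 30.0 * s_c**2 * (1.0 - s_c) ** 2, 0.0)


def response_kernel(s: np.ndarray | float) -> np.ndarray:
    """Raised-cosine bump of unit peak on s in [0, 1]: sin^2(pi s)."""
    s_arr = np.asarray(s, dtype=float)
    inside = (s_arr >= 0.0) & (s_arr <= 1.0)
    return np.where(inside, np.sin(np.pi * np.clip(s_arr, 0.0, 1.0)) ** 2, 0.0)


def response_kernel_integral(s: np.ndarray | float) -> np.ndarray:
    """Closed-form integral of :func:`response_kernel` from 0 to s.

    integral sin^2(pi u) du = u/2 - sin(2 pi u)/(4 pi); saturates at 1/2.
    """
    s_c = np.clip(np.asarray(s, dtype=float), 0.0, 1.0)
    return s_c / 2.0 - np.sin(2.0 * np.pi * s_c) / (4.0 * np.pi)


def injected_velocity(
    t: np.ndarray | float,
    onset: float,
    cond: Condition,
    resp: ResponseModel,
    geom: Geometry | None = None,
) -> np.ndarray:
    """Ground-truth response velocity (cm/s) at time(s) ``t`` after target appearance."""
    geom = geom or Geometry()
    s = (np.asarray(t, dtype=float) - onset - resp.latency) / resp.kernel_width
    return cond.direction_sign * resp.gain_for(cond) * geom.square_speed * response_kernel(s)


def injected_displacement(
    t: np.ndarray | float,
    onset: float,
    cond: Condition,
    resp: ResponseModel,
    geom: Geometry | None = None,
) -> np.ndarray:
    """Time-integral of :func:`injected_velocity` (cm of lateral displacement)."""
    geom = geom or Geometry()
    s = (np.asarray(t, dtype=float) - onset - resp.latency) / resp.kernel_width
    amp = cond.direction_sign * resp.gain_for(cond) * geom.square_speed * resp.kernel_width
    return amp * response_kernel_integral(s)


def injected_window_mean(
    cond: Condition,
    resp: ResponseModel,
    geom: Geometry | None = None,
    window: tuple[float, float] = (0.15, 0.20),
) -> float:
    """Expected rightward-minus-leftward window-mean velocity for a condition.

    The analysis averages forward-difference velocities over the inclusive
    2-ms lag grid ``[window[0], window[1]]``; the exact expectation of that
    discrete mean is the injected displacement accrued over
    ``[window[0], window[1] + DT]`` divided by the window duration, doubled
    because the right-left difference sums the two directions' responses.
    """
    geom = geom or Geometry()
    lo, hi = window
    n_intervals = int(round((hi - lo) / DT)) + 1
    right = replace(cond, motion_direction="right")
    d0 = injected_displacement(lo, 0.0, right, resp, geom)
    d1 = injected_displacement(lo + n_intervals * DT, 0.0, right, resp, geom)
    return float(2.0 * (d1 - d0) / (n_intervals * DT))


# ---------------------------------------------------------------------------
# trial simulation

def simulate_trial(
    spec: TrialSpec,
    resp: ResponseModel | None = None,
    noise: NoiseModel | None = None,
    geom: Geometry | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    reach: ReachModel | None = None,
) -> Trajectory:
    """Simulate one trial's 500-Hz marker trajectory.

    Recording runs from the moment the finger settles on the start point
    (``-start_delay``) to ``record_after_contact`` past screen contact.
    Raises ``ValueError`` if the reach geometry is inconsistent (contact
    would precede movement onset).
    """
    resp = resp or ResponseModel()
    noise = noise or NoiseModel()
    geom = geom or Geometry()
    reach = reach or ReachModel()
    rng = np.random.default_rng(seed)
    cond = spec.condition

    # contact time and movement onset
    t_contact = float(rng.normal(reach.contact_mean, reach.contact_sd))
    t_on = reach.reaction_time
    t_strike_start = t_contact - reach.strike_duration / 2.0
    if t_strike_start - t_on < 0.02:
        raise ValueError(
            "inconsistent reach geometry: contact at "
            f"{t_contact:.3f} s leaves no time for the reach after movement "
            f"onset at {t_on:.3f} s"
        )

    # square-motion timing (occasionally off by more than a display frame)
    actual_onset = spec.square_onset
    if rng.random() < noise.timing_issue_rate:
        shift = rng.uniform(0.010, 0.025) * (1 if rng.random() < 0.5 else -1)
        actual_onset += shift
    actual_offset = actual_onset + geom.square_motion_duration

    # planned tap point: the target's position at the planned contact time,
    # plus endpoint scatter
    tap_xy = target_position(t_contact, geom)
    tap_xy = tap_xy + rng.normal(0.0, noise.endpoint_sd, size=2)

    # sample grid (2-ms, spanning -start_delay .. contact + tail)
    k0 = -int(math.floor(spec.start_delay / DT))
    k1 = int(math.ceil((t_contact + reach.record_after_contact) / DT))
    t = np.arange(k0, k1 + 1) * DT

    # lateral/vertical baseline: minimum jerk from start point to tap point
    x0, y0 = geom.start_position
    s_xy = np.clip((t - t_on) / (t_contact - t_on), 0.0, 1.0)
    mj = minimum_jerk(s_xy)
    x = x0 + (tap_xy[0] - x0) * mj
    y = y0 + (tap_xy[1] - y0) * mj

    # screen-normal: lift then strike; contact at the strike velocity peak
    z = np.zeros_like(t)
    lift = (t >= t_on) & (t < t_strike_start)
    z[lift] = reach.lift_height * minimum_jerk(
        (t[lift] - t_on) / (t_strike_start - t_on)
    )
    strike = t >= t_strike_start
    z[strike] = reach.lift_height * (
        1.0 - 2.0 * minimum_jerk((t[strike] - t_strike_start) / reach.strike_duration)
    )
    z = np.maximum(z, 0.0)  # finger rests on the screen after contact

    # injected following response (frozen once the finger lands)
    d_resp = injected_displacement(np.minimum(t, t_contact), actual_onset, cond, resp, geom)
    x = x + d_resp

    positions = np.column_stack([x, y, z])
    if noise.position_sd > 0:
        positions = positions + rng.normal(0.0, noise.position_sd, positions.shape)
        positions[:, 2] = np.maximum(positions[:, 2], 0.0)

    # dropped-sample gap, placed inside the analysis window so that missing
    # data actually intersects the analyzed interval (as in the trials the
    # study removed)
    missing = np.zeros(len(t), dtype=bool)
    if rng.random() < noise.missing_rate:
        gap_len = int(rng.integers(10, 51))
        win_start = int(np.searchsorted(t, actual_onset))
        win_len = int(round(0.3 / DT))
        lo = win_start
        hi = max(lo + 1, win_start + win_len - gap_len)
        gap_start = int(rng.integers(lo, hi))
        missing[gap_start : gap_start + gap_len] = True
        positions[missing] = np.nan

    return Trajectory(
        sample_times=t,
        positions=positions,
        missing_mask=missing,
        trial=spec,
        recorded_square_onset=actual_onset,
        recorded_square_offset=actual_offset,
        contact_time=t_contact,
    )


def simulate_session(
    schedule: Schedule,
    resp: ResponseModel | None = None,
    noise: NoiseModel | None = None,
    geom: Geometry | None = None,
    seed: int = 0,
    reach: ReachModel | None = None,
) -> list[Trajectory]:
    """Simulate every trial of a schedule; per-trial seeds derive from ``seed``."""
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    children = np.random.SeedSequence(seed).spawn(len(schedule))
    return [
        simulate_trial(spec, resp, noise, geom, seed=child, reach=reach)
        for spec, child in zip(schedule, children)
    ]


# ---------------------------------------------------------------------------
# optional marker-to-screen miscalibration

@dataclass(frozen=True)
class RigidTransform:
    """Rigid map from screen coordinates to raw marker coordinates."""

    rotation: np.ndarray  # (3, 3)
    offset: np.ndarray    # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.offset

    def invert(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.offset) @ self.rotation


def make_miscalibration(seed: int = 0, max_angle_deg: float = 3.0, max_offset_cm: float = 2.0) -> RigidTransform:
    """A small random rotation + offset emulating an uncalibrated marker frame."""
    rng = np.random.default_rng(seed)
    angles = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg, 3))
    cx, sx = np.cos(angles[0]), np.sin(angles[0])
    cy, sy = np.cos(angles[1]), np.sin(angles[1])
    cz, sz = np.cos(angles[2]), np.sin(angles[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    offset = rng.uniform(-max_offset_cm, max_offset_cm, 3)
    return RigidTransform(rotation=rz @ ry @ rx, offset=offset)


def calibration_correspondences(
    transform: RigidTransform, geom: Geometry | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Four calibration point pairs: raw marker 3-D points and screen 2-D targets.

    The screen targets are placed near the screen corners; the raw points are
    those targets (on the screen plane, z = 0) pushed through ``transform``.
    """
    geom = geom or Geometry()
    w, h = geom.screen_width * 0.4, geom.screen_height * 0.4
    screen = np.array([[-w, -h], [w, -h], [w, h], [-w, h]])
    on_plane = np.column_stack([screen, np.zeros(4)])
    return transform.apply(on_plane), screen
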