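"""Task geometry, condition set, trial scheduling and ideal stimulus kinematics.

The paradigm is a manual interception task: a target disc moves rightward
across a patterned background toward a circular interception zone, and a
square centred on that zone (either an outline *frame* or a filled *tile*)
translates leftward or rightward for a brief epoch shortly after the target
appears.  Everything here is deterministic given a seed; the stimulus motion
functions are the analytic ground truth that the synthetic-data generator and
the analysis are checked against.

Coordinates are screen-plane centimetres with the origin at the screen
centre, x rightward and y upward.  Times are seconds after target appearance
unless a function says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Geometry",
    "Condition",
    "TrialSpec",
    "Schedule",
    "SQUARE_KINDS",
    "SQUARE_SIDES_CM",
    "DIRECTIONS",
    "all_conditions",
    "build_schedule",
    "target_position",
    "square_position",
    "nearest_edge_distance",
    "generate_scene",
]

SQUARE_KINDS: tuple[str, ...] = ("frame", "tile")
SQUARE_SIDES_CM: tuple[float, ...] = (7.0, 37.0, 67.0)
DIRECTIONS: tuple[str, ...] = ("left", "right")

#: Time from finger-on-start to target appearance is drawn uniformly from here (s).
START_DELAY_RANGE = (0.5, 0.7)
#: Time from target appearance to square-motion onset is drawn uniformly from here (s).
SQUARE_ONSET_RANGE = (0.3, 0.4)


@dataclass(frozen=True)
class Geometry:
    """Physical layout of the display, in screen-plane cm.

    Defaults reproduce the experiment: a 6-cm interception zone 10 cm above
    the screen centre, a 2-cm target appearing 20 cm to its left and moving
    rightward at 30 cm/s (so it reaches the zone centre after 2/3 s), and a
    square that translates at 20 cm/s for 100 ms (2 cm total).
    """

    zone_center: tuple[float, float] = (0.0, 10.0)
    zone_diameter: float = 6.0
    target_diameter: float = 2.0
    start_diameter: float = 4.0
    start_offset: float = 30.0          # start point this far below the zone
    target_start_offset: float = 20.0   # target appears this far left of the zone centre
    target_speed: float = 30.0          # cm/s, rightward
    square_speed: float = 20.0          # cm/s during the motion epoch
    square_motion_duration: float = 0.1  # s
    disc_count: int = 600
    disc_diameter: float = 1.0
    frame_width_fraction: float = 0.05
    screen_width: float = 125.0
    screen_height: float = 100.0

    def __post_init__(self) -> None:
        if self.target_speed <= 0:
            raise ValueError("target_speed must be positive")
        if self.square_motion_duration <= 0:
            raise ValueError("square_motion_duration must be positive")
        if self.disc_count < 0:
            raise ValueError("disc_count must be non-negative")

    @property
    def start_position(self) -> tuple[float, float]:
        return (self.zone_center[0], self.zone_center[1] - self.start_offset)

    @property
    def interception_time(self) -> float:
        """Time (s) for the target to travel from appearance to the zone centre."""
        return self.target_start_offset / self.target_speed


@dataclass(frozen=True)
class Condition:
    """One cell of the design: square kind x size x motion direction."""

    square_kind: Literal["frame", "tile"]
    square_side: float
    motion_direction: Literal["left", "right"]

    def __post_init__(self) -> None:
        if self.square_kind not in SQUARE_KINDS:
            raise ValueError(f"unknown square kind {self.square_kind!r}")
        if self.motion_direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.motion_direction!r}")
        if self.square_side <= 0:
            raise ValueError("square_side must be positive")

    @property
    def direction_sign(self) -> int:
        return 1 if self.motion_direction == "right" else -1


def all_conditions(sides: Sequence[float] = SQUARE_SIDES_CM) -> list[Condition]:
    """The 12 condition cells (2 kinds x len(sides) sizes x 2 directions)."""
    return [
        Condition(kind, side, direction)
        for kind in SQUARE_KINDS
        for side in sides
        for direction in DIRECTIONS
    ]


@dataclass(frozen=True)
class TrialSpec:
    """One trial: its condition plus the randomized timings.

    ``start_delay`` is the time from finger-on-start to target appearance;
    ``square_onset`` is the commanded time from target appearance to the
    onset of the square's motion.
    """

    trial_index: int
    block_index: int
    condition: Condition
    start_delay: float
    square_onset: float

    def __post_init__(self) -> None:
        lo, hi = START_DELAY_RANGE
        if not lo <= self.start_delay <= hi:
            raise ValueError(f"start_delay {self.start_delay} outside [{lo}, {hi}]")
        lo, hi = SQUARE_ONSET_RANGE
        if not lo <= self.square_onset <= hi:
            raise ValueError(f"square_onset {self.square_onset} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class Schedule:
    trials: tuple[TrialSpec, ...]
    seed: int
    reps_per_cell: int
    n_blocks: int

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


def build_schedule(reps_per_cell: int = 25, n_blocks: int = 2, seed: int = 0) -> Schedule:
    """Randomly interleaved schedule with exact per-cell counts.

    Each block is a shuffle of an exact-count list containing every
    kind x size x direction cell ``reps_per_cell`` times, so the counts are
    exactly uniform by construction (no rejection sampling).  Start delays and
    square onsets are drawn uniformly from their intervals.  Reproducible
    given ``seed``.
    """
    if reps_per_cell < 1:
        raise ValueError("reps_per_cell must be >= 1")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    cells = all_conditions()
    trials: list[TrialSpec] = []
    index = 0
    for block in range(n_blocks):
        order = np.repeat(np.arange(len(cells)), reps_per_cell)
        rng.shuffle(order)
        for cell_idx in order:
            trials.append(
                TrialSpec(
                    trial_index=index,
                    block_index=block,
                    condition=cells[int(cell_idx)],
                    start_delay=float(rng.uniform(*START_DELAY_RANGE)),
                    square_onset=float(rng.uniform(*SQUARE_ONSET_RANGE)),
                )
            )
            index += 1
    return Schedule(tuple(trials), seed=seed, reps_per_cell=reps_per_cell, n_blocks=n_blocks)


def target_position(t: float | np.ndarray, geom: Geometry | None = None) -> np.ndarray:
    """Screen position of the target ``t`` seconds after it appeared.

    The target appears ``target_start_offset`` cm to the left of the zone
    centre and moves rightward at ``target_speed``; its height is fixed at
    zone height.  Affine in ``t``.
    """
    geom = geom or Geometry()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0 (seconds after target appearance)")
    x = geom.zone_center[0] - geom.target_start_offset + geom.target_speed * t
    y = np.broadcast_to(geom.zone_center[1], x.shape)
    return np.stack([x, y], axis=-1)


def square_position(
    t: float | np.ndarray, spec: TrialSpec, geom: Geometry | None = None
) -> np.ndarray:
    """Horizontal offset (cm) of the square's centre from the zone centre.

    Zero before the motion onset, then a linear ramp at ``square_speed`` for
    ``square_motion_duration`` in the trial's direction, constant afterwards
    (the square stops and stays displaced).
    """
    geom = geom or Geometry()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    moving = np.clip(t - spec.square_onset, 0.0, geom.square_motion_duration)
    return spec.condition.direction_sign * geom.square_speed * moving


def nearest_edge_distance(cond: Condition) -> float:
    """Initial distance (cm) from the zone centre to the square's nearest vertical edge.

    The square is centred on the zone, so this is half the side length: the
    eccentricity of the nearest motion signal when the square starts to move.
    """
    return cond.square_side / 2.0


def generate_scene(seed: int = 0, geom: Geometry | None = None) -> np.ndarray:
    """Random background-disc centres, uniform over the screen extent.

    Returns an ``(disc_count, 2)`` array of (x, y) screen positions in cm;
    identical output for identical seeds.
    """
    geom = geom or Geometry()
    rng = np.random.default_rng(seed)
    x = rng.uniform(-geom.screen_width / 2, geom.screen_width / 2, geom.disc_count)
    y = rng.uniform(-geom.screen_height / 2, geom.screen_height / 2, geom.disc_count)
    return np.column_stack([x, y])
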