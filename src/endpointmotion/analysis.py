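"""Exclusion, direction-difference response curves, magnitudes, group summary.

The headline computation: per participant and condition, lateral finger
velocities are aligned to each trial's recorded square-motion onset, averaged
per 2-ms interval separately for leftward- and rightward-motion trials, and
subtracted (rightward minus leftward) to give the *response curve* over the
first 300 ms after motion onset.  A positive value is a response in the
square's motion direction.  The *response magnitude* is the curve's mean over
the 150-200 ms window; group-level results are means with standard errors
across participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .paradigm import Geometry
from .synthetic import DT, Trajectory
from .kinematics import TapEvent, detect_tap, lateral_velocity

__all__ = [
    "ANALYSIS_DURATION",
    "MAGNITUDE_WINDOW",
    "TIMING_TOLERANCE",
    "N_LAGS",
    "lag_grid",
    "ExclusionReport",
    "ResponseCurve",
    "ResponseMagnitude",
    "GroupSummary",
    "exclude_trials",
    "response_curve",
    "response_magnitude",
    "analyze_participant",
    "group_summary",
    "plot_time_courses",
    "plot_magnitudes",
]

#: Curves cover the first 300 ms after square-motion onset.
ANALYSIS_DURATION = 0.3
N_LAGS = int(round(ANALYSIS_DURATION / DT))  # 150 points, 0 .. 0.298 s
#: Response magnitude = mean of the curve over this lag window, inclusive.
MAGNITUDE_WINDOW = (0.15, 0.20)
#: Trials whose recorded square-motion timing deviates from the commanded
#: timing by more than one 120-Hz display frame are excluded.
TIMING_TOLERANCE = 1.0 / 120.0


def lag_grid() -> np.ndarray:
    """The 2-ms lag grid after square-motion onset: 0, 0.002, ..., 0.298 s."""
    return np.arange(N_LAGS) * DT


@dataclass
class ExclusionReport:
    n_total: int = 0
    n_timing: int = 0
    n_missing: int = 0
    excluded_indices: list[int] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.n_total - len(self.excluded_indices)


def exclude_trials(
    session: Sequence[Trajectory],
    timing_tolerance: float = TIMING_TOLERANCE,
    geom: Geometry | None = None,
) -> tuple[list[Trajectory], ExclusionReport]:
    """Remove trials with square-motion timing issues or missing data.

    A trial is excluded if its recorded square-motion onset or offset
    deviates from the commanded timing by more than ``timing_tolerance``
    (default one display frame, 8.3 ms), or if any sample inside its analysis
    window (onset to onset + 300 ms, plus the closing sample of the last
    interval) is missing.  All other trials are kept irrespective of task
    performance.  A trial can be counted in both categories but is removed
    once.
    """
    geom = geom or Geometry()
    kept: list[Trajectory] = []
    report = ExclusionReport(n_total=len(session))
    for traj in session:
        spec = traj.trial
        commanded_offset = spec.square_onset + geom.square_motion_duration
        timing_bad = (
            abs(traj.recorded_square_onset - spec.square_onset) > timing_tolerance
            or abs(traj.recorded_square_offset - commanded_offset) > timing_tolerance
        )
        t = traj.sample_times
        in_window = (t >= traj.recorded_square_onset) & (
            t <= traj.recorded_square_onset + ANALYSIS_DURATION + DT
        )
        missing_bad = bool(np.any(traj.missing_mask & in_window))
        if timing_bad:
            report.n_timing += 1
        if missing_bad:
            report.n_missing += 1
        if timing_bad or missing_bad:
            report.excluded_indices.append(spec.trial_index)
        else:
            kept.append(traj)
    return kept, report


@dataclass
class ResponseCurve:
    """Rightward-minus-leftward mean lateral velocity vs lag after motion onset."""

    lag_times: np.ndarray   # (150,) s
    values: np.ndarray      # (150,) cm/s; positive = with the square's motion
    participant: str
    square_kind: str
    square_side: float
    n_trials_right: int
    n_trials_left: int


@dataclass(frozen=True)
class ResponseMagnitude:
    participant: str
    square_kind: str
    square_side: float
    value: float  # cm/s


def _trial_lag_velocities(
    traj: Trajectory, tap: TapEvent | None
) -> np.ndarray:
    """One trial's lateral velocity on the lag grid after its recorded onset.

    Velocities are indexed to interval starts; intervals that start at or
    after the detected tap (the finger has landed) and intervals touching
    missing samples are NaN, as are lags past the end of the recording.
    """
    v = lateral_velocity(traj)
    i0 = int(round((traj.recorded_square_onset - traj.sample_times[0]) / DT))
    out = np.full(N_LAGS, np.nan)
    idx = i0 + np.arange(N_LAGS)
    valid = (idx >= 0) & (idx < len(v))
    out[valid] = v[idx[valid]]
    if tap is not None:
        out[idx >= tap.sample_index] = np.nan
    return out


def response_curve(
    trials: Sequence[Trajectory],
    geom: Geometry | None = None,
    participant: str = "p0",
) -> ResponseCurve:
    """Build the direction-difference curve for one participant x condition.

    ``trials`` must all share one square kind and size and contain at least
    one trial per motion direction.  Each trial is aligned to its own
    recorded square-motion onset (nearest sample); velocities are averaged
    per lag within direction, ignoring unavailable intervals, and the
    leftward mean is subtracted from the rightward mean.
    """
    geom = geom or Geometry()
    if not trials:
        raise ValueError("no trials supplied")
    kinds = {t.trial.condition.square_kind for t in trials}
    sides = {t.trial.condition.square_side for t in trials}
    if len(kinds) > 1 or len(sides) > 1:
        raise ValueError(f"trials span multiple conditions: kinds={kinds}, sides={sides}")
    by_dir: dict[str, list[np.ndarray]] = {"left": [], "right": []}
    for traj in trials:
        tap = detect_tap(traj, geom)
        by_dir[traj.trial.condition.motion_direction].append(
            _trial_lag_velocities(traj, tap)
        )
    for direction, rows in by_dir.items():
        if not rows:
            raise ValueError(
                f"no {direction}ward trials for kind={kinds.pop()} side={sides.pop()}; "
                "cannot form a direction difference"
            )
    # lags where no trial has data (e.g. all taps landed earlier) stay NaN
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_right = np.nanmean(np.vstack(by_dir["right"]), axis=0)
        mean_left = np.nanmean(np.vstack(by_dir["left"]), axis=0)
    return ResponseCurve(
        lag_times=lag_grid(),
        values=mean_right - mean_left,
        participant=participant,
        square_kind=kinds.pop(),
        square_side=sides.pop(),
        n_trials_right=len(by_dir["right"]),
        n_trials_left=len(by_dir["left"]),
    )


def response_magnitude(
    curve: ResponseCurve, window: tuple[float, float] = MAGNITUDE_WINDOW
) -> ResponseMagnitude:
    """Mean of the curve over the (inclusive) lag window, default 150-200 ms."""
    lo, hi = window
    eps = DT / 4
    sel = (curve.lag_times >= lo - eps) & (curve.lag_times <= hi + eps)
    if not sel.any() or curve.lag_times[sel][-1] < hi - eps:
        raise ValueError(f"curve does not cover the window [{lo}, {hi}] s")
    vals = curve.values[sel]
    if np.isnan(vals).any():
        raise ValueError("curve has undefined values inside the magnitude window")
    return ResponseMagnitude(
        participant=curve.participant,
        square_kind=curve.square_kind,
        square_side=curve.square_side,
        value=float(vals.mean()),
    )


def analyze_participant(
    session: Sequence[Trajectory],
    geom: Geometry | None = None,
    participant: str = "p0",
    timing_tolerance: float = TIMING_TOLERANCE,
    window: tuple[float, float] = MAGNITUDE_WINDOW,
) -> tuple[list[ResponseCurve], list[ResponseMagnitude], ExclusionReport]:
    """Exclusion + curves + magnitudes for every condition of one session."""
    kept, report = exclude_trials(session, timing_tolerance, geom)
    groups: dict[tuple[str, float], list[Trajectory]] = {}
    for traj in kept:
        cond = traj.trial.condition
        groups.setdefault((cond.square_kind, cond.square_side), []).append(traj)
    curves, magnitudes = [], []
    for key in sorted(groups):
        curve = response_curve(groups[key], geom, participant)
        curves.append(curve)
        magnitudes.append(response_magnitude(curve, window))
    return curves, magnitudes, report


@dataclass
class GroupSummary:
    """Across-participant means and standard errors per condition."""

    curve_summary: pd.DataFrame      # kind, side_cm, lag_s, mean_cm_s, sem_cm_s
    magnitude_summary: pd.DataFrame  # kind, side_cm, mean_cm_s, sem_cm_s, n_participants
    pairing: pd.DataFrame            # participant, side_cm, frame_cm_s, tile_cm_s
    n_participants: int


def group_summary(
    curves: Iterable[ResponseCurve], magnitudes: Iterable[ResponseMagnitude]
) -> GroupSummary:
    """Aggregate per-participant results across participants.

    The standard error is the across-participant standard deviation (ddof 1)
    divided by sqrt(n); at least two participants are required.  Also emits
    the per-participant tile-vs-frame magnitude pairing per square size.
    """
    curve_rows = [
        pd.DataFrame(
            {
                "participant": c.participant,
                "kind": c.square_kind,
                "side_cm": c.square_side,
                "lag_s": c.lag_times,
                "response_cm_s": c.values,
            }
        )
        for c in curves
    ]
    mag_rows = pd.DataFrame(
        [
            {
                "participant": m.participant,
                "kind": m.square_kind,
                "side_cm": m.square_side,
                "magnitude_cm_s": m.value,
            }
            for m in magnitudes
        ]
    )
    n_participants = mag_rows["participant"].nunique() if len(mag_rows) else 0
    if n_participants < 2:
        raise ValueError("group summary needs at least 2 participants (SEM undefined)")

    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(x.count()))

    curve_df = pd.concat(curve_rows, ignore_index=True)
    curve_summary = (
        curve_df.groupby(["kind", "side_cm", "lag_s"], as_index=False)["response_cm_s"]
        .agg(mean_cm_s="mean", sem_cm_s=_sem)
    )
    magnitude_summary = (
        mag_rows.groupby(["kind", "side_cm"], as_index=False)["magnitude_cm_s"]
        .agg(mean_cm_s="mean", sem_cm_s=_sem, n_participants="count")
    )
    pairing = (
        mag_rows.pivot_table(
            index=["participant", "side_cm"], columns="kind", values="magnitude_cm_s"
        )
        .reset_index()
        .rename(columns={"frame": "frame_cm_s", "tile": "tile_cm_s"})
    )
    pairing.columns.name = None
    return GroupSummary(
        curve_summary=curve_summary,
        magnitude_summary=magnitude_summary,
        pairing=pairing,
        n_participants=int(n_participants),
    )


# ---------------------------------------------------------------------------
# plots (group time courses and magnitude summaries)

def plot_time_courses(summary: GroupSummary, path: str | None = None):
    """Mean response curves with SEM bands, one panel per square size."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sides = sorted(summary.curve_summary["side_cm"].unique())
    fig, axes = plt.subplots(1, len(sides), figsize=(4 * len(sides), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    colors = {"frame": "#2aa7a0", "tile": "#c8a021"}
    for ax, side in zip(axes, sides):
        for kind in ("frame", "tile"):
            sub = summary.curve_summary.query("kind == @kind and side_cm == @side")
            lag_ms = sub["lag_s"] * 1000
            ax.plot(lag_ms, sub["mean_cm_s"], color=colors[kind], label=kind)
            ax.fill_between(
                lag_ms,
                sub["mean_cm_s"] - sub["sem_cm_s"],
                sub["mean_cm_s"] + sub["sem_cm_s"],
                color=colors[kind],
                alpha=0.3,
                lw=0,
            )
        ax.axvspan(150, 200, color="0.85", zorder=0)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(f"{side:g}-cm square")
        ax.set_xlabel("time after motion onset (ms)")
    axes[0].set_ylabel("response (cm/s)")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_magnitudes(summary: GroupSummary, path: str | None = None):
    """Magnitude vs size with participant lines, and tile-vs-frame scatter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_a, ax_b) = plt.subplots(1, 2, figsize=(9, 3.6))
    colors = {"frame": "#2aa7a0", "tile": "#c8a021"}
    pairing = summary.pairing
    for kind, col in (("frame", "frame_cm_s"), ("tile", "tile_cm_s")):
        for _, sub in pairing.groupby("participant"):
            ax_a.plot(sub["side_cm"], sub[col], color=colors[kind], alpha=0.3, lw=0.8)
        g = summary.magnitude_summary.query("kind == @kind")
        ax_a.errorbar(
            g["side_cm"], g["mean_cm_s"], yerr=g["sem_cm_s"],
            color=colors[kind], marker="o", capsize=3, label=kind,
        )
    ax_a.set_xlabel("square size (cm)")
    ax_a.set_ylabel("response magnitude (cm/s)")
    ax_a.legend(frameon=False)
    ax_b.scatter(pairing["frame_cm_s"], pairing["tile_cm_s"], s=14, color="0.3")
    lims = np.array(
        [
            min(pairing["frame_cm_s"].min(), pairing["tile_cm_s"].min()),
            max(pairing["frame_cm_s"].max(), pairing["tile_cm_s"].max()),
        ]
    )
    ax_b.plot(lims, lims, "k--", lw=0.8)
    ax_b.set_xlabel("frame response (cm/s)")
    ax_b.set_ylabel("tile response (cm/s)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
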