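"""Configuration, delimited-text I/O, logging, and the end-to-end pipeline.

A run configuration is a flat key-value text file with dotted namespaces
(``response.latency_s = 0.12``); unknown keys are errors so that typos never
silently alter a simulation.  Trajectories, schedules and result tables are
plain delimited text with units in the column names.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import analysis, kinematics, paradigm, synthetic
from .paradigm import Condition, Geometry, Schedule, TrialSpec
from .synthetic import NoiseModel, ReachModel, ResponseModel, Trajectory

__all__ = [
    "RunConfig",
    "RunResult",
    "PipelineError",
    "parse_config",
    "format_config",
    "read_config",
    "write_config",
    "schedule_to_frame",
    "schedule_from_frame",
    "write_schedule",
    "read_schedule",
    "write_trajectory",
    "read_trajectory",
    "write_session",
    "read_session",
    "run_end_to_end",
]

log = logging.getLogger("endpointmotion")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _key(name: str) -> dict:
    return {"metadata": {"key": name}}


@dataclass
class RunConfig:
    """Everything needed to reproduce a full simulated study.

    Defaults reproduce the paradigm: 2 blocks of 25 repetitions per
    condition x direction cell (600 trials), 12 participants, the default
    geometry, response, noise and reach models.
    """

    reps_per_cell: int = dataclasses.field(default=25, **_key("schedule.reps_per_cell"))
    n_blocks: int = dataclasses.field(default=2, **_key("schedule.n_blocks"))
    n_participants: int = dataclasses.field(default=12, **_key("participants"))
    seed: int = dataclasses.field(default=0, **_key("seed"))
    # geometry
    target_speed: float = dataclasses.field(default=30.0, **_key("geometry.target_speed_cm_s"))
    target_start_offset: float = dataclasses.field(default=20.0, **_key("geometry.target_start_offset_cm"))
    square_speed: float = dataclasses.field(default=20.0, **_key("geometry.square_speed_cm_s"))
    square_motion_duration: float = dataclasses.field(default=0.1, **_key("geometry.square_motion_duration_s"))
    # response model
    latency: float = dataclasses.field(default=0.12, **_key("response.latency_s"))
    kernel_width: float = dataclasses.field(default=0.15, **_key("response.kernel_width_s"))
    gain_size_7: float = dataclasses.field(default=0.10, **_key("response.gain.size_7"))
    gain_size_37: float = dataclasses.field(default=0.075, **_key("response.gain.size_37"))
    gain_size_67: float = dataclasses.field(default=0.04, **_key("response.gain.size_67"))
    gain_frame: float = dataclasses.field(default=1.0, **_key("response.gain.frame_multiplier"))
    gain_tile: float = dataclasses.field(default=1.0, **_key("response.gain.tile_multiplier"))
    # noise model
    position_sd: float = dataclasses.field(default=0.005, **_key("noise.position_sd_cm"))
    endpoint_sd: float = dataclasses.field(default=0.65, **_key("noise.endpoint_sd_cm"))
    missing_rate: float = dataclasses.field(default=0.01, **_key("noise.missing_rate"))
    timing_issue_rate: float = dataclasses.field(default=0.005, **_key("noise.timing_issue_rate"))
    # reach model
    reaction_time: float = dataclasses.field(default=0.2, **_key("reach.reaction_time_s"))
    contact_mean: float = dataclasses.field(default=0.662, **_key("reach.contact_mean_s"))
    contact_sd: float = dataclasses.field(default=0.027, **_key("reach.contact_sd_s"))
    lift_height: float = dataclasses.field(default=4.0, **_key("reach.lift_height_cm"))
    approach_speed: float = dataclasses.field(default=100.0, **_key("reach.approach_speed_cm_s"))
    # analysis
    window_lo: float = dataclasses.field(default=0.15, **_key("analysis.window_lo_s"))
    window_hi: float = dataclasses.field(default=0.20, **_key("analysis.window_hi_s"))
    timing_tolerance: float = dataclasses.field(default=1.0 / 120.0, **_key("analysis.timing_tolerance_s"))
    tap_threshold: float = dataclasses.field(default=0.1, **_key("tap.threshold_cm"))
    tap_height: float = dataclasses.field(default=2.0, **_key("tap.height_cm"))
    # marker miscalibration (exercises the four-point calibration end to end)
    calibrate: bool = dataclasses.field(default=False, **_key("calibration.enabled"))
    cal_max_angle: float = dataclasses.field(default=3.0, **_key("calibration.max_angle_deg"))
    cal_max_offset: float = dataclasses.field(default=2.0, **_key("calibration.max_offset_cm"))

    def geometry(self) -> Geometry:
        return Geometry(
            target_speed=self.target_speed,
            target_start_offset=self.target_start_offset,
            square_speed=self.square_speed,
            square_motion_duration=self.square_motion_duration,
        )

    def response_model(self) -> ResponseModel:
        return ResponseModel(
            latency=self.latency,
            kernel_width=self.kernel_width,
            gain_by_size={7.0: self.gain_size_7, 37.0: self.gain_size_37, 67.0: self.gain_size_67},
            gain_by_kind={"frame": self.gain_frame, "tile": self.gain_tile},
        )

    def noise_model(self) -> NoiseModel:
        return NoiseModel(
            position_sd=self.position_sd,
            endpoint_sd=self.endpoint_sd,
            missing_rate=self.missing_rate,
            timing_issue_rate=self.timing_issue_rate,
        )

    def reach_model(self) -> ReachModel:
        return ReachModel(
            reaction_time=self.reaction_time,
            contact_mean=self.contact_mean,
            contact_sd=self.contact_sd,
            lift_height=self.lift_height,
            approach_speed=self.approach_speed,
        )

    @property
    def window(self) -> tuple[float, float]:
        return (self.window_lo, self.window_hi)


_KEY_TO_FIELD = {f.metadata["key"]: f for f in fields(RunConfig)}


def _parse_value(f: dataclasses.Field, text: str):
    if f.type in ("bool", bool):
        if text.lower() in ("true", "1", "yes"):
            return True
        if text.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"invalid boolean {text!r} for {f.metadata['key']}")
    if f.type in ("int", int):
        return int(text)
    return float(text)


def parse_config(text: str) -> RunConfig:
    """Parse a flat key-value config; unknown keys raise ``ValueError``."""
    values = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in _KEY_TO_FIELD:
            raise ValueError(f"line {lineno}: unknown config key {key!r}")
        f = _KEY_TO_FIELD[key]
        values[f.name] = _parse_value(f, val)
    return RunConfig(**values)


def format_config(config: RunConfig) -> str:
    lines = []
    for f in fields(RunConfig):
        val = getattr(config, f.name)
        if isinstance(val, bool):
            val = "true" if val else "false"
        elif isinstance(val, float):
            val = repr(val)
        lines.append(f"{f.metadata['key']} = {val}")
    return "\n".join(lines) + "\n"


def read_config(path: str | Path) -> RunConfig:
    return parse_config(Path(path).read_text())


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(format_config(config))


# ---------------------------------------------------------------------------
# schedules

def schedule_to_frame(schedule: Schedule) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trial_index": s.trial_index,
                "block": s.block_index,
                "kind": s.condition.square_kind,
                "side_cm": s.condition.square_side,
                "direction": s.condition.motion_direction,
                "start_delay_s": s.start_delay,
                "square_onset_s": s.square_onset,
            }
            for s in schedule
        ]
    )


def schedule_from_frame(df: pd.DataFrame, seed: int = -1) -> Schedule:
    trials = tuple(
        TrialSpec(
            trial_index=int(r.trial_index),
            block_index=int(r.block),
            condition=Condition(str(r.kind), float(r.side_cm), str(r.direction)),
            start_delay=float(r.start_delay_s),
            square_onset=float(r.square_onset_s),
        )
        for r in df.itertuples()
    )
    n_blocks = len({t.block_index for t in trials})
    reps = len(trials) // (12 * n_blocks) if trials else 0
    return Schedule(trials, seed=seed, reps_per_cell=reps, n_blocks=n_blocks)


def write_schedule(schedule: Schedule, path: str | Path) -> None:
    schedule_to_frame(schedule).to_csv(path, sep="\t", index=False)


def read_schedule(path: str | Path) -> Schedule:
    return schedule_from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# trajectories

_TRAJ_META_FLOAT = ("recorded_square_onset", "recorded_square_offset", "contact_time")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """One trial as delimited text: a key-value header block, then samples."""
    spec = traj.trial
    header = {
        "trial_index": spec.trial_index,
        "block": spec.block_index,
        "kind": spec.condition.square_kind,
        "side_cm": spec.condition.square_side,
        "direction": spec.condition.motion_direction,
        "start_delay_s": spec.start_delay,
        "square_onset_s": spec.square_onset,
        "recorded_square_onset": traj.recorded_square_onset,
        "recorded_square_offset": traj.recorded_square_offset,
        "contact_time": traj.contact_time,
    }
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"# {key}: {val!r}\n" if isinstance(val, str) else f"# {key}: {val}\n")
        fh.write("t_s\tx_cm\ty_cm\tz_cm\tmissing\n")
        for t, (x, y, z), m in zip(traj.sample_times, traj.positions, traj.missing_mask):
            fh.write(f"{t:.3f}\t{x:.6f}\t{y:.6f}\t{z:.6f}\t{int(m)}\n")


def read_trajectory(path: str | Path) -> Trajectory:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip().strip("'")
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    spec = TrialSpec(
        trial_index=int(meta["trial_index"]),
        block_index=int(meta["block"]),
        condition=Condition(meta["kind"], float(meta["side_cm"]), meta["direction"]),
        start_delay=float(meta["start_delay_s"]),
        square_onset=float(meta["square_onset_s"]),
    )
    missing = df["missing"].to_numpy().astype(bool)
    positions = df[["x_cm", "y_cm", "z_cm"]].to_numpy()
    positions[missing] = np.nan
    n0 = int(round(df["t_s"].iloc[0] / synthetic.DT))
    times = (n0 + np.arange(len(df))) * synthetic.DT  # re-snap to the exact grid
    return Trajectory(
        sample_times=times,
        positions=positions,
        missing_mask=missing,
        trial=spec,
        recorded_square_onset=float(meta["recorded_square_onset"]),
        recorded_square_offset=float(meta["recorded_square_offset"]),
        contact_time=float(meta["contact_time"]),
    )


def write_session(session: Sequence[Trajectory], out_dir: str | Path, participant: str = "p0") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for traj in session:
        name = f"{participant}_trial{traj.trial.trial_index:04d}.tsv"
        write_trajectory(traj, out / name)
        names.append(name)
    (out / f"{participant}_manifest.json").write_text(
        json.dumps({"participant": participant, "trials": names}, indent=1)
    )


def read_session(data_dir: str | Path, participant: str = "p0") -> list[Trajectory]:
    data = Path(data_dir)
    manifest = json.loads((data / f"{participant}_manifest.json").read_text())
    return [read_trajectory(data / name) for name in manifest["trials"]]


# ---------------------------------------------------------------------------
# end-to-end pipeline

@dataclass
class RunResult:
    schedule: Schedule
    curves: pd.DataFrame        # participant, kind, side_cm, lag_s, response_cm_s
    magnitudes: pd.DataFrame    # participant, kind, side_cm, magnitude_cm_s
    group: analysis.GroupSummary
    exclusions: dict[str, analysis.ExclusionReport]
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_end_to_end(config: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Schedule -> simulate -> (calibrate) -> analyze -> group summary.

    Every participant gets a deterministic seed derived from ``config.seed``.
    If ``out_dir`` is given, all result tables plus a manifest (seed, config
    hash, exclusion counts) are written there as delimited text.
    """
    geom = config.geometry()
    resp = config.response_model()
    noise = config.noise_model()
    reach = config.reach_model()

    schedule = _stage("schedule")(paradigm.build_schedule)(
        config.reps_per_cell, config.n_blocks, config.seed
    )
    log.info("schedule: %d trials (%d blocks)", len(schedule), config.n_blocks)

    ss = np.random.SeedSequence(config.seed)
    part_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_participants)]

    all_curves: list[analysis.ResponseCurve] = []
    all_mags: list[analysis.ResponseMagnitude] = []
    exclusions: dict[str, analysis.ExclusionReport] = {}
    for p_idx, p_seed in enumerate(part_seeds):
        pid = f"p{p_idx:02d}"
        session = _stage("simulate")(synthetic.simulate_session)(
            schedule, resp, noise, geom, seed=p_seed, reach=reach
        )
        if config.calibrate:
            session = _stage("calibrate")(_miscalibrate_and_recover)(
                session, p_seed, config, geom
            )
        curves, mags, report = _stage("analyze")(analysis.analyze_participant)(
            session, geom, pid, config.timing_tolerance, config.window
        )
        log.info(
            "%s: %d trials, excluded %d (timing %d, missing %d)",
            pid, report.n_total, len(report.excluded_indices),
            report.n_timing, report.n_missing,
        )
        all_curves.extend(curves)
        all_mags.extend(mags)
        exclusions[pid] = report

    group = _stage("group")(analysis.group_summary)(all_curves, all_mags)

    curves_df = pd.concat(
        [
            pd.DataFrame(
                {
                    "participant": c.participant,
                    "kind": c.square_kind,
                    "side_cm": c.square_side,
                    "lag_s": c.lag_times,
                    "response_cm_s": c.values,
                }
            )
            for c in all_curves
        ],
        ignore_index=True,
    )
    mags_df = pd.DataFrame(
        [
            {
                "participant": m.participant,
                "kind": m.square_kind,
                "side_cm": m.square_side,
                "magnitude_cm_s": m.value,
            }
            for m in all_mags
        ]
    )
    manifest = {
        "seed": config.seed,
        "participant_seeds": part_seeds,
        "config_sha256": hashlib.sha256(format_config(config).encode()).hexdigest(),
        "n_trials": len(schedule),
        "exclusions": {
            pid: {
                "n_total": r.n_total,
                "n_timing": r.n_timing,
                "n_missing": r.n_missing,
                "n_kept": r.n_kept,
            }
            for pid, r in exclusions.items()
        },
    }
    result = RunResult(schedule, curves_df, mags_df, group, exclusions, manifest)
    if out_dir is not None:
        _write_result(result, config, Path(out_dir))
    return result


def _miscalibrate_and_recover(
    session: list[Trajectory], seed: int, config: RunConfig, geom: Geometry
) -> list[Trajectory]:
    """Push trajectories into a miscalibrated marker frame, then calibrate back."""
    transform = synthetic.make_miscalibration(seed, config.cal_max_angle, config.cal_max_offset)
    raw_pts, screen_pts = synthetic.calibration_correspondences(transform, geom)
    cal = kinematics.fit_calibration(raw_pts, screen_pts)
    out = []
    for traj in session:
        raw = dataclasses.replace(traj, positions=transform.apply(traj.positions))
        out.append(kinematics.apply_calibration(raw, cal))
    return out


def _write_result(result: RunResult, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_schedule(result.schedule, out / "schedule.tsv")
    result.curves.to_csv(out / "curves.tsv", sep="\t", index=False)
    result.magnitudes.to_csv(out / "magnitudes.tsv", sep="\t", index=False)
    result.group.curve_summary.to_csv(out / "group_curves.tsv", sep="\t", index=False)
    result.group.magnitude_summary.to_csv(out / "group_magnitudes.tsv", sep="\t", index=False)
    result.group.pairing.to_csv(out / "pairing.tsv", sep="\t", index=False)
    write_config(config, out / "config.txt")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
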