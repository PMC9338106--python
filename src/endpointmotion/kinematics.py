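"""Low-level trajectory processing: calibration, differentiation, tap detection.

These are the operators applied to raw marker data before any averaging:
a four-point plane-projective calibration relating marker coordinates to
screen coordinates, per-interval forward differencing of lateral position
(no smoothing), and detection of screen taps from the abrupt deceleration of
the approach at impact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .paradigm import Geometry, target_position
from .synthetic import DT, Trajectory

__all__ = [
    "TAP_THRESHOLD_CM",
    "TAP_HEIGHT_CM",
    "CalibrationMap",
    "TapEvent",
    "fit_calibration",
    "lateral_velocity",
    "detect_tap",
    "apply_calibration",
]

#: Tap criterion: the per-sample approach to the screen must shrink by more
#: than this between consecutive sample pairs (1 mm per 2-ms interval) ...
TAP_THRESHOLD_CM = 0.1
#: ... while the finger is closer to the screen than this (cm).
TAP_HEIGHT_CM = 2.0


@dataclass(frozen=True)
class CalibrationMap:
    """Maps raw 3-D marker coordinates to screen coordinates plus distance.

    The four calibration points define the screen plane; in-plane coordinates
    are sent through an exact homography (a four-point correspondence
    determines a plane projectivity uniquely), and the third output is the
    perpendicular distance to the fitted plane, signed positive on the
    viewer's side.
    """

    plane_origin: np.ndarray   # (3,) a point on the screen plane
    basis: np.ndarray          # (2, 3) orthonormal in-plane axes
    normal: np.ndarray         # (3,) unit normal, viewer side positive
    homography: np.ndarray     # (3, 3) in-plane (u, v) -> screen (x, y)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(n, 3)`` (or ``(3,)``) raw points to (screen_x, screen_y, distance)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = pts - self.plane_origin
        uv = rel @ self.basis.T
        dist = rel @ self.normal
        uvh = np.column_stack([uv, np.ones(len(uv))])
        mapped = uvh @ self.homography.T
        screen = mapped[:, :2] / mapped[:, 2:3]
        out = np.column_stack([screen, dist])
        return out[0] if np.asarray(points).ndim == 1 else out


def _any_three_collinear(points_2d: np.ndarray, tol: float = 1e-9) -> bool:
    scale = np.ptp(points_2d, axis=0).max() or 1.0
    for i in range(4):
        for j in range(i + 1, 4):
            for k in range(j + 1, 4):
                a, b, c = points_2d[i], points_2d[j], points_2d[k]
                area = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
                if abs(area) < tol * scale**2:
                    return True
    return False


def fit_calibration(raw_points: np.ndarray, screen_points: np.ndarray) -> CalibrationMap:
    """Fit the four-point calibration exactly.

    ``raw_points`` are four marker positions recorded with the fingertip on
    four known screen targets ``screen_points``.  The raw points fix the
    screen plane; the homography between their in-plane coordinates and the
    screen targets is solved exactly (8 equations, 8 unknowns).  Degenerate
    configurations (three collinear points on either side) are rejected.
    """
    raw = np.asarray(raw_points, dtype=float)
    screen = np.asarray(screen_points, dtype=float)
    if raw.shape != (4, 3) or screen.shape != (4, 2):
        raise ValueError("need four 3-D raw points and four 2-D screen points")
    if _any_three_collinear(screen):
        raise ValueError("degenerate calibration: three screen points are collinear")

    # orthonormal frame of the plane through the raw points
    e1 = raw[1] - raw[0]
    norm_e1 = np.linalg.norm(e1)
    if norm_e1 == 0:
        raise ValueError("degenerate calibration: coincident raw points")
    e1 = e1 / norm_e1
    n = np.cross(raw[1] - raw[0], raw[2] - raw[0])
    norm_n = np.linalg.norm(n)
    if norm_n < 1e-9 * norm_e1**2:
        raise ValueError("degenerate calibration: raw points are collinear")
    n = n / norm_n
    e2 = np.cross(n, e1)

    rel = raw - raw[0]
    uv = rel @ np.vstack([e1, e2]).T
    if _any_three_collinear(uv):
        raise ValueError("degenerate calibration: three raw points are collinear in-plane")

    # exact homography uv -> screen with h33 = 1
    rows, rhs = [], []
    for (u, v), (x, y) in zip(uv, screen):
        rows.append([u, v, 1, 0, 0, 0, -u * x, -v * x])
        rhs.append(x)
        rows.append([0, 0, 0, u, v, 1, -u * y, -v * y])
        rhs.append(y)
    try:
        h = np.linalg.solve(np.asarray(rows), np.asarray(rhs))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate calibration: {exc}") from exc
    H = np.append(h, 1.0).reshape(3, 3)

    # orient the normal so distances are positive on the viewer's side: if the
    # uv -> screen map is orientation-reversing the plane frame is left-handed
    # relative to the screen, so flip
    centroid = np.append(uv.mean(axis=0), 1.0)
    w = H[2] @ centroid
    jac = (H[:2, :2] * w - np.outer((H[:2] @ centroid), H[2, :2])) / w**2
    if np.linalg.det(jac) < 0:
        n = -n
        e2 = -e2  # keep (e1, e2, n) right-handed; refit homography in flipped frame
        uv = rel @ np.vstack([e1, e2]).T
        rows, rhs = [], []
        for (u, v), (x, y) in zip(uv, screen):
            rows.append([u, v, 1, 0, 0, 0, -u * x, -v * x])
            rhs.append(x)
            rows.append([0, 0, 0, u, v, 1, -u * y, -v * y])
            rhs.append(y)
        h = np.linalg.solve(np.asarray(rows), np.asarray(rhs))
        H = np.append(h, 1.0).reshape(3, 3)

    cal = CalibrationMap(
        plane_origin=raw[0].copy(),
        basis=np.vstack([e1, e2]),
        normal=n,
        homography=H,
    )
    residual = np.abs(cal.apply(raw)[:, :2] - screen).max()
    if residual > 1e-6:
        raise ValueError(f"calibration residual {residual:.2e} cm exceeds 1e-6")
    return cal


def apply_calibration(traj: Trajectory, cal: CalibrationMap) -> Trajectory:
    """Return a trajectory with positions mapped through a calibration."""
    mapped = np.full_like(traj.positions, np.nan)
    ok = ~traj.missing_mask
    if ok.any():
        mapped[ok] = cal.apply(traj.positions[ok])
    return replace(traj, positions=mapped)


def lateral_velocity(traj: Trajectory) -> np.ndarray:
    """Per-interval lateral velocity by direct forward differencing.

    ``v[i] = (x[i+1] - x[i]) / 0.002`` for every consecutive 2-ms sample
    pair, indexed to the interval start; intervals touching a missing sample
    are NaN.  No smoothing is applied.
    """
    if traj.n_samples < 2:
        raise ValueError("need at least 2 samples to differentiate")
    x = traj.positions[:, 0]
    v = np.diff(x) / DT
    bad = traj.missing_mask[:-1] | traj.missing_mask[1:]
    v[bad] = np.nan
    return v


def detect_tap(
    traj: Trajectory,
    geom: Geometry | None = None,
    threshold_cm: float = TAP_THRESHOLD_CM,
    height_cm: float = TAP_HEIGHT_CM,
) -> "TapEvent | None":
    """Detect the screen tap from the deceleration of the approach.

    With the per-sample approach ``delta[i] = z[i-1] - z[i]``, a tap is the
    first sample ``i`` where the approach shrinks by more than
    ``threshold_cm`` between consecutive sample pairs
    (``delta[i-1] - delta[i] > threshold_cm``) while the finger is within
    ``height_cm`` of the screen.  Returns ``None`` if no sample qualifies.
    Hit flags compare the tap position against the target's outline (at its
    position at tap time) and the interception zone; a touch exactly on the
    outline counts as a hit.
    """
    geom = geom or Geometry()
    z = traj.positions[:, 2]
    if len(z) < 3:
        return None
    delta = z[:-1] - z[1:]               # delta[i] is approach into sample i+1
    jerk = delta[:-1] - delta[1:]        # shrinkage of the approach at sample i+2
    with np.errstate(invalid="ignore"):
        qualifies = (jerk > threshold_cm) & (z[2:] < height_cm)
    idx = np.flatnonzero(qualifies)
    if len(idx) == 0:
        return None
    i = int(idx[0]) + 2
    tap_time = float(traj.sample_times[i])
    tap_position = traj.positions[i, :2].copy()
    if tap_time >= 0:
        target_xy = target_position(tap_time, geom)
        hit_target = float(np.hypot(*(tap_position - target_xy))) <= geom.target_diameter / 2
    else:
        hit_target = False
    zone_xy = np.asarray(geom.zone_center)
    hit_zone = float(np.hypot(*(tap_position - zone_xy))) <= geom.zone_diameter / 2
    return TapEvent(
        tap_time=tap_time,
        tap_position=tap_position,
        hit_target=bool(hit_target),
        hit_zone=bool(hit_zone),
        sample_index=i,
    )


@dataclass(frozen=True)
class TapEvent:
    """A detected screen contact."""

    tap_time: float            # s after target appearance
    tap_position: np.ndarray   # (2,) calibrated screen cm
    hit_target: bool
    hit_zone: bool
    sample_index: int
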