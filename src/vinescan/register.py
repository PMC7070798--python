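"""Georeferencing: raw 2D scans + GNSS fixes -> one 3D point cloud.

Each beam is converted from polar to Cartesian coordinates in the sensor
plane, then moved into the local frame by the platform pose at the scan
timestamp.  Pose position is linearly interpolated between the bracketing
GNSS fixes (the RTK stream acts as the travel-axis encoder); yaw comes from
the smoothed local travel direction or is held at zero, roll/pitch from
config.  An optional X-shear term models the residual along-track skew of a
tilted sensor; it defaults to identity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io import PointCloud
from .nmea import GnssFix
from .simulate import PlatformPose, ScanFrame, SensorConfig, rotation_matrix

__all__ = [
    "PlatformPose",
    "rotation_matrix",
    "polar_to_plane",
    "interpolate_pose",
    "apply_pose",
    "georeference",
    "PoseInterpolator",
]

log = logging.getLogger(__name__)


def polar_to_plane(ranges, angles_deg, sensor: SensorConfig):
    """Beam (range, angle) -> (y, z) in the sensor plane.

    theta = 0 points horizontally toward the row (+Y); positive angles tilt
    toward +Z.  The mount height is added so z is height above the platform
    reference (ground contact).
    """
    th = np.radians(np.asarray(angles_deg, dtype=float))
    r = np.asarray(ranges, dtype=float)
    return r * np.cos(th), sensor.mount_height + r * np.sin(th)


class PoseInterpolator:
    """Pose lookup over a fix sequence; built once, queried per frame.

    ``encoder_axes`` controls how much of the fix position is trusted:
    ``"x"`` (default) uses the GNSS stream only as the travel-axis encoder --
    the platform is assumed to follow the nominal straight line at y = z = 0,
    with the scanner as the origin of the local frame; ``"xyz"`` interpolates
    the full fix position.
    """

    def __init__(self, fixes: list[GnssFix], attitude: str = "travel",
                 heading_window: int = 21, roll: float = 0.0, pitch: float = 0.0,
                 encoder_axes: str = "x"):
        if len(fixes) < 2:
            raise ValueError("need at least two GNSS fixes")
        self.t = np.array([f.timestamp for f in fixes])
        if np.any(np.diff(self.t) <= 0.0):
            raise ValueError("fix timestamps must be strictly increasing")
        self.pos = np.array([[f.east, f.north, f.up] for f in fixes])
        if encoder_axes == "x":
            self.pos = self.pos.copy()
            self.pos[:, 1] = 0.0
            self.pos[:, 2] = 0.0
        elif encoder_axes != "xyz":
            raise ValueError(f"unknown encoder_axes {encoder_axes!r}")
        self.roll, self.pitch = roll, pitch
        if attitude == "zero":
            self.yaw = np.zeros(len(fixes))
        elif attitude == "travel":
            # heading of the secant over +/- half a window: robust to cm noise
            w = max(1, heading_window // 2)
            n = len(fixes)
            i0 = np.maximum(np.arange(n) - w, 0)
            i1 = np.minimum(np.arange(n) + w, n - 1)
            d = self.pos[i1] - self.pos[i0]
            self.yaw = np.arctan2(d[:, 1], d[:, 0])
        else:
            raise ValueError(f"unknown attitude source {attitude!r}")

    @property
    def t_range(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    def __call__(self, t: float) -> PlatformPose:
        if not (self.t[0] <= t <= self.t[-1]):
            raise ValueError(f"t={t} outside fix coverage "
                             f"[{self.t[0]}, {self.t[-1]}]; no extrapolation")
        p = np.array([np.interp(t, self.t, self.pos[:, k]) for k in range(3)])
        yaw = float(np.interp(t, self.t, np.unwrap(self.yaw)))
        yaw = math.atan2(math.sin(yaw), math.cos(yaw))  # wrap to (-pi, pi]
        return PlatformPose(t, p, self.roll, self.pitch, yaw)


def interpolate_pose(fixes: list[GnssFix], t: float, attitude: str = "travel",
                     heading_window: int = 21,
                     encoder_axes: str = "xyz") -> PlatformPose:
    """Interpolate one pose; full-position interpolation by default."""
    return PoseInterpolator(fixes, attitude, heading_window,
                            encoder_axes=encoder_axes)(t)


def apply_pose(points: np.ndarray, pose: PlatformPose,
               shear: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Sensor-frame points -> local frame: rotate (Z.Y.X), translate, X-shear.

    The shear adds ``s_y*y + s_z*z`` to x after the rigid move; (0, 0) is the
    identity and the default.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    R = rotation_matrix(pose.roll, pose.pitch, pose.yaw)
    out = pts @ R.T + pose.position
    sy, sz = shear
    if sy or sz:
        out = out.copy()
        out[:, 0] += sy * out[:, 1] + sz * out[:, 2]
    return out


def georeference(frames: list[ScanFrame], fixes: list[GnssFix],
                 sensor: SensorConfig, *, attitude: str = "travel",
                 heading_window: int = 21, shear: tuple[float, float] = (0.0, 0.0),
                 encoder_axes: str = "x",
                 frame_labels: list[np.ndarray] | None = None) -> PointCloud:
    """Fuse scans and fixes into one cloud with per-point provenance.

    Frames whose timestamps fall outside fix coverage are dropped (and
    counted in the log) rather than extrapolated; raises if nothing remains.
    ``frame_labels`` (per-beam tag arrays from the simulator) propagate to
    per-point labels for provenance-based oracles.
    """
    interp = PoseInterpolator(fixes, attitude, heading_window,
                              encoder_axes=encoder_axes)
    t0, t1 = interp.t_range
    pts, sidx, bidx, labs = [], [], [], []
    dropped = 0
    for i, frame in enumerate(frames):
        if not (t0 <= frame.timestamp <= t1):
            dropped += 1
            continue
        m = frame.valid
        if not np.any(m):
            continue
        y, z = polar_to_plane(frame.ranges[m], frame.angles[m], sensor)
        sensor_pts = np.stack([np.zeros_like(y), y, z], axis=1)
        world = apply_pose(sensor_pts, interp(frame.timestamp), shear)
        pts.append(world)
        sidx.append(np.full(len(world), frame.scan_index, dtype=np.int32))
        bidx.append(np.flatnonzero(m).astype(np.int32))
        if frame_labels is not None:
            labs.append(np.asarray(frame_labels[i])[m])
    if dropped:
        log.info("georeference: dropped %d frames outside fix coverage", dropped)
    if not pts:
        raise ValueError("no frames usable: empty fix coverage or all-invalid scans")
    return PointCloud(np.concatenate(pts), np.concatenate(sidx),
                      np.concatenate(bidx),
                      np.concatenate(labs) if labs else None)
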