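"""Acquisition-rig emulator: sideways 2D time-of-flight scanner + RTK-GNSS.

The scanner sweeps a vertical plane perpendicular to travel while the platform
moves along +X at walking pace; each sweep (a :class:`ScanFrame`) carries one
beam per angular step across the field of view.  Ranging is exact ray/primitive
geometry plus Gaussian noise (12 mm sd by default), an optional per-run
systematic bias, and 1 mm range quantization; returns outside the
[range_min, range_max] window are flagged invalid.  A parallel GGA stream
with seeded position noise acts as the travel-axis encoder.

Beam-angle convention: theta = 0 along +Y (horizontal, toward the row),
positive toward +Z, field of view symmetric about 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nmea
from .scene import VineScene

__all__ = [
    "SensorConfig",
    "TrajectorySpec",
    "ScanFrame",
    "PlatformPose",
    "SimulationRun",
    "simulate_trajectory",
    "cast_beam",
    "cast_scan",
    "generate_nmea",
    "simulate_run",
]


@dataclass(frozen=True)
class SensorConfig:
    """2D scanner geometry and error model (defaults: the operational settings)."""

    fov_deg: float = 270.0
    angular_step_deg: float = 0.5  # 0.25 or 0.5 selectable
    scan_rate_hz: float = 50.0  # 25 Hz also printed by the datasheet mode
    range_min: float = 0.5
    range_max: float = 20.0
    range_noise_sd: float = 0.012
    systematic_error_bound: float = 0.030  # one constant in-run bias drawn within this
    mount_height: float = 1.20
    lateral_standoff: float = 1.0  # nominal sensor-to-row distance (informational)
    quantization: float = 0.001  # m, device range resolution

    def __post_init__(self) -> None:
        if not (0.0 < self.angular_step_deg <= self.fov_deg):
            raise ValueError("need 0 < angular_step <= fov")
        if self.range_min >= self.range_max:
            raise ValueError("range_min must be below range_max")
        if self.range_noise_sd < 0.0:
            raise ValueError("noise sd must be >= 0")

    @property
    def n_beams(self) -> int:
        return int(math.floor(self.fov_deg / self.angular_step_deg)) + 1

    @property
    def beam_angles_deg(self) -> np.ndarray:
        """Symmetric about theta = 0; ascending."""
        half = self.fov_deg / 2.0
        return -half + self.angular_step_deg * np.arange(self.n_beams)


@dataclass(frozen=True)
class TrajectorySpec:
    """Straight pass along +X through the inter-row area, with perturbations."""

    speed: float = 0.5  # m/s; 50 Hz x 0.5 m/s -> 10 mm slice spacing
    row_length: float = 12.0
    start_x: float = 0.0
    start_t: float = 36000.0  # seconds of day (10:00:00)
    # residual sensor attitude after the stabilizing gimbal (~0.2 deg of the
    # vehicle's ~1 deg sway leaks through) plus white servo/boom jitter
    attitude_amp_rad: tuple[float, float, float] = (0.004, 0.004, 0.004)
    attitude_jitter_rad: float = 0.003
    # lateral drift of the platform over the uneven alley (not stabilized)
    lateral_wobble_amp: float = 0.02  # m
    gnss_rate_hz: float = 10.0  # 20 Hz also selectable
    gnss_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed <= 0.0:
            raise ValueError("speed must be positive")
        if self.speed > 0.84:
            raise ValueError("platform speed is limited to < 3 km/h")
        if self.gnss_rate_hz <= 0.0:
            raise ValueError("gnss rate must be positive")


@dataclass
class ScanFrame:
    """One 2D sweep: parallel angle/range arrays plus a validity mask."""

    scan_index: int
    timestamp: float
    angles: np.ndarray  # degrees, beam order
    ranges: np.ndarray  # m; nan for no-return
    valid: np.ndarray  # bool per beam

    def __post_init__(self) -> None:
        if not (len(self.angles) == len(self.ranges) == len(self.valid)):
            raise ValueError("angle/range/valid arrays must align")


@dataclass(frozen=True)
class PlatformPose:
    timestamp: float
    position: np.ndarray  # (x, y, z) m
    roll: float = 0.0
    pitch: float = 0.0
    yaw: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


def _smooth_perturbation(t: np.ndarray, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Sum of two low-frequency sinusoids with seeded phase/frequency."""
    if amp == 0.0:
        return np.zeros_like(t)
    out = np.zeros_like(t)
    for _ in range(2):
        f = rng.uniform(0.1, 0.6)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        out += 0.5 * amp * np.sin(2.0 * math.pi * f * (t - t[0]) + phase)
    return out


def simulate_trajectory(traj: TrajectorySpec, scan_rate_hz: float) -> list[PlatformPose]:
    """Platform poses sampled at the scan rate; deterministic per seed."""
    rng = np.random.default_rng(traj.seed)
    duration = traj.row_length / traj.speed
    n = int(math.floor(duration * scan_rate_hz)) + 1
    t = traj.start_t + np.arange(n) / scan_rate_hz
    x = traj.start_x + traj.speed * (t - traj.start_t)
    y = _smooth_perturbation(t, traj.lateral_wobble_amp, rng)
    roll = _smooth_perturbation(t, traj.attitude_amp_rad[0], rng)
    pitch = _smooth_perturbation(t, traj.attitude_amp_rad[1], rng)
    yaw = _smooth_perturbation(t, traj.attitude_amp_rad[2], rng)
    if traj.attitude_jitter_rad > 0.0:
        roll = roll + rng.normal(0.0, traj.attitude_jitter_rad, n)
        pitch = pitch + rng.normal(0.0, traj.attitude_jitter_rad, n)
        yaw = yaw + rng.normal(0.0, traj.attitude_jitter_rad, n)
    return [PlatformPose(float(t[i]), np.array([x[i], y[i], 0.0]),
                         float(roll[i]), float(pitch[i]), float(yaw[i]))
            for i in range(n)]


# ---------------------------------------------------------------------------
# ray casting

class _Primitives:
    """Flat arrays of scene primitives with per-segment x-extents for culling."""

    def __init__(self, scene: VineScene):
        segs = scene.segments
        self.p0 = np.array([s.p0 for s in segs]).reshape(-1, 3)
        self.axis = np.array([s.axis for s in segs]).reshape(-1, 3)
        self.h = np.array([s.length for s in segs])
        self.r0 = np.array([s.r0 for s in segs])
        self.k = np.array([(s.r1 - s.r0) / s.length for s in segs])
        self.tag = np.array([s.tag for s in segs], dtype="<U8")
        rmax = np.array([max(s.r0, s.r1) for s in segs])
        p1 = np.array([s.p1 for s in segs]).reshape(-1, 3)
        self.xmin = np.minimum(self.p0[:, 0], p1[:, 0]) - rmax
        self.xmax = np.maximum(self.p0[:, 0], p1[:, 0]) + rmax
        self.sph_c = np.array([m.center for m in scene.markers]).reshape(-1, 3)
        self.sph_r = np.array([m.radius for m in scene.markers])
        self.ground_z = scene.ground_z


def _primitives(scene: VineScene) -> _Primitives:
    prims = getattr(scene, "_prims_cache", None)
    if prims is None:
        prims = _Primitives(scene)
        scene._prims_cache = prims
    return prims


def _ray_frustum(origin, dirs, p0, a, h, r0, k):
    """Smallest positive hit of unit rays with one frustum's lateral surface.

    Solves the quadratic |w + t d - ((w + t d).a) a|^2 = (r0 + k s)^2 with
    s = (w + t d).a clamped to the axis extent.  Returns +inf where no hit.
    """
    w = origin - p0
    sw = float(w @ a)
    sd = dirs @ a
    wd = dirs @ w
    A = 1.0 - (1.0 + k * k) * sd * sd
    B = 2.0 * (wd - sw * sd - k * sd * (r0 + k * sw))
    C = float(w @ w) - sw * sw - (r0 + k * sw) ** 2
    t_hit = np.full(len(dirs), np.inf)
    quad = np.abs(A) > 1e-12
    disc = B * B - 4.0 * A * C
    ok = quad & (disc >= 0.0)
    if np.any(ok):
        sq = np.sqrt(disc[ok])
        for sign in (-1.0, 1.0):
            t = (-B[ok] + sign * sq) / (2.0 * A[ok])
            s = sw + t * sd[ok]
            good = (t > 1e-9) & (s >= 0.0) & (s <= h)
            cand = np.where(good, t, np.inf)
            idx = np.flatnonzero(ok)
            t_hit[idx] = np.minimum(t_hit[idx], cand)
    lin = (~quad) & (np.abs(B) > 1e-12)
    if np.any(lin):
        t = -C / B[lin]
        s = sw + t * sd[lin]
        good = (t > 1e-9) & (s >= 0.0) & (s <= h)
        idx = np.flatnonzero(lin)
        t_hit[idx] = np.where(good, t, np.inf)
    return t_hit


def _trace(origin: np.ndarray, dirs: np.ndarray, prims: _Primitives,
           x_margin: float) -> tuple[np.ndarray, np.ndarray]:
    """Nearest hit distance and tag for each unit ray; inf/'' for no hit."""
    B = len(dirs)
    best = np.full(B, np.inf)
    tag = np.full(B, "", dtype="<U8")
    lo, hi = origin[0] - x_margin, origin[0] + x_margin
    for i in np.flatnonzero((prims.xmax >= lo) & (prims.xmin <= hi)):
        t = _ray_frustum(origin, dirs, prims.p0[i], prims.axis[i],
                         prims.h[i], prims.r0[i], prims.k[i])
        closer = t < best
        best[closer] = t[closer]
        tag[closer] = prims.tag[i]
    for c, r in zip(prims.sph_c, prims.sph_r):
        if not (lo - r <= c[0] <= hi + r):
            continue
        w = origin - c
        b = dirs @ w
        disc = b * b - (w @ w - r * r)
        ok = disc >= 0.0
        t = np.where(ok, -b - np.sqrt(np.maximum(disc, 0.0)), np.inf)
        t = np.where(t > 1e-9, t, np.inf)
        closer = t < best
        best[closer] = t[closer]
        tag[closer] = "marker"
    dz = dirs[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        tg = (prims.ground_z - origin[2]) / dz
    tg = np.where((dz < -1e-12) & (tg > 1e-9), tg, np.inf)
    closer = tg < best
    best[closer] = tg[closer]
    tag[closer] = "ground"
    return best, tag


def rotation_matrix(roll: float, pitch: float, yaw: float) -> np.ndarray:
    """Intrinsic Z(yaw) . Y(pitch) . X(roll)."""
    cr, sr = math.cos(roll), math.sin(roll)
    cp, sp = math.cos(pitch), math.sin(pitch)
    cy, sy = math.cos(yaw), math.sin(yaw)
    rx = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
    ry = np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]])
    rz = np.array([[cy, -sy, 0], [sy, cy, 0], [0, 0, 1]])
    return rz @ ry @ rx


def cast_beam(origin: np.ndarray, direction: np.ndarray, scene: VineScene,
              sensor: SensorConfig | None = None) -> float:
    """Exact geometric range of one ray, or ``nan`` for no return.

    Applies the sensor's range window if ``sensor`` is given; no noise.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    t, _ = _trace(np.asarray(origin, dtype=float), d[None, :], _primitives(scene),
                  x_margin=abs(d[0]) * 25.0 + 1.0)
    r = float(t[0])
    if not np.isfinite(r):
        return float("nan")
    if sensor is not None and not (sensor.range_min <= r <= sensor.range_max):
        return float("nan")
    return r


def cast_scan(pose: PlatformPose, sensor: SensorConfig, scene: VineScene,
              rng: np.random.Generator | None = None, scan_index: int = 0,
              bias: float = 0.0) -> tuple[ScanFrame, np.ndarray]:
    """One sweep from ``pose``; returns the frame and per-beam hit tags."""
    R = rotation_matrix(pose.roll, pose.pitch, pose.yaw)
    origin = pose.position + R @ np.array([0.0, 0.0, sensor.mount_height])
    th = np.radians(sensor.beam_angles_deg)
    dirs = np.stack([np.zeros_like(th), np.cos(th), np.sin(th)], axis=1) @ R.T
    margin = 0.45 + sensor.range_max * float(np.max(np.abs(dirs[:, 0])))
    t, tags = _trace(origin, dirs, _primitives(scene), margin)
    ranges = t.copy()
    hit = np.isfinite(ranges)
    if rng is not None and sensor.range_noise_sd > 0.0:
        ranges[hit] += rng.normal(0.0, sensor.range_noise_sd, size=int(hit.sum()))
    ranges[hit] += bias
    if sensor.quantization > 0.0:
        ranges[hit] = np.round(ranges[hit] / sensor.quantization) * sensor.quantization
    valid = hit & (ranges >= sensor.range_min) & (ranges <= sensor.range_max)
    ranges[~hit] = np.nan
    frame = ScanFrame(scan_index, pose.timestamp, sensor.beam_angles_deg.copy(),
                      ranges, valid)
    return frame, tags


def generate_nmea(poses: list[PlatformPose], gnss_rate_hz: float, noise_sd: float,
                  rng: np.random.Generator,
                  origin_lla: tuple[float, float, float] = (40.1333, -3.3667, 750.0),
                  ) -> tuple[list[str], list[nmea.GnssFix]]:
    """GGA sentences + noisy ENU fixes along the pose track.

    Fixes are sampled at ``gnss_rate_hz`` over the pose time span; the local
    frame is anchored at ``origin_lla`` <-> world (0, 0, 0).  The receiver is
    assumed aligned with the sensor column (zero lever arm).
    """
    ts = np.array([p.timestamp for p in poses])
    pos = np.array([p.position for p in poses])
    n = int(math.floor((ts[-1] - ts[0]) * gnss_rate_hz)) + 1
    tf = ts[0] + np.arange(n) / gnss_rate_hz
    e = np.interp(tf, ts, pos[:, 0])
    nn = np.interp(tf, ts, pos[:, 1])
    u = np.interp(tf, ts, pos[:, 2])
    if noise_sd > 0.0:
        e = e + rng.normal(0.0, noise_sd, n)
        nn = nn + rng.normal(0.0, noise_sd, n)
        u = u + rng.normal(0.0, noise_sd, n)
    lat, lon, alt = nmea.enu_to_lla(e, nn, u, origin_lla)
    sentences = [nmea.format_gga(float(tf[i]) % 86400.0, float(lat[i]),
                                 float(lon[i]), float(alt[i])) for i in range(n)]
    fixes = nmea.gga_to_fixes(sentences, origin_lla)
    return sentences, fixes


@dataclass
class SimulationRun:
    """Everything one acquisition pass produces."""

    frames: list[ScanFrame]
    poses: list[PlatformPose]
    sentences: list[str]
    fixes: list[nmea.GnssFix]
    hit_tags: list[np.ndarray] = field(repr=False, default_factory=list)
    origin_lla: tuple[float, float, float] = (40.1333, -3.3667, 750.0)
    range_bias: float = 0.0


def simulate_run(scene: VineScene, sensor: SensorConfig, traj: TrajectorySpec,
                 origin_lla: tuple[float, float, float] = (40.1333, -3.3667, 750.0),
                 ) -> SimulationRun:
    """Full pass over the scene: trajectory -> scans -> NMEA, one seed."""
    rng = np.random.default_rng(traj.seed)
    noise_rng, gnss_rng = rng.spawn(2)
    bias = (float(rng.uniform(-sensor.systematic_error_bound,
                              sensor.systematic_error_bound))
            if sensor.systematic_error_bound > 0.0 else 0.0)
    poses = simulate_trajectory(traj, sensor.scan_rate_hz)
    frames, tags = [], []
    for i, pose in enumerate(poses):
        frame, tag = cast_scan(pose, sensor, scene, noise_rng, scan_index=i, bias=bias)
        frames.append(frame)
        tags.append(tag)
    sentences, fixes = generate_nmea(poses, traj.gnss_rate_hz, traj.gnss_noise_sd,
                                     gnss_rng, origin_lla)
    return SimulationRun(frames, poses, sentences, fixes, tags, origin_lla, bias)
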