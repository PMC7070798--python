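"""Parametric synthetic vineyards with analytically known shoot volume and biomass.

A :class:`VineScene` is a single trellised row of defoliated vines laid out
along the +X axis (the travel axis): per vine a vertical trunk, a horizontal
cordon at training height, and a handful of one-year canes ("shoots") modelled
as chains of thin tapered cylinders (conical frusta, diameter < 1 cm).  The
trellis adds posts, two horizontal wires and spherical row markers at batch
boundaries.  The row is divided into disjoint 10-vine *batches* (treatment x
plot), each with an exact analytic shoot volume and dry biomass
(``biomass = wood_density * volume``) serving as ground truth for the
reconstruction pipeline.

Coordinates are metric, double precision: X along the row, Y across the row
(crop depth, the scanner looks toward +Y), Z up.  The ground is the plane
``z = ground_z``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Segment",
    "Sphere",
    "Batch",
    "BatchTruth",
    "SceneSpec",
    "VineScene",
    "frustum_volume",
    "build_scene",
    "batch_truth",
    "sample_surface",
    "scene_to_mesh",
]

#: Segment tags understood by the simulator and the filtering stage.
TAGS = ("shoot", "trunk", "cordon", "post", "wire", "marker", "ground")


@dataclass(frozen=True)
class Segment:
    """A tapered cylinder (conical frustum) between ``p0`` and ``p1``.

    Radii ``r0``/``r1`` apply at the respective endpoints and interpolate
    linearly along the axis.  ``tag`` identifies the structural role.
    """

    p0: np.ndarray
    p1: np.ndarray
    r0: float
    r1: float
    tag: str = "shoot"

    def __post_init__(self) -> None:
        object.__setattr__(self, "p0", np.asarray(self.p0, dtype=float))
        object.__setattr__(self, "p1", np.asarray(self.p1, dtype=float))
        if self.r0 <= 0.0 or self.r1 <= 0.0:
            raise ValueError("segment radii must be positive")
        if not np.all(np.isfinite(self.p0)) or not np.all(np.isfinite(self.p1)):
            raise ValueError("segment endpoints must be finite")
        if np.allclose(self.p0, self.p1):
            raise ValueError("zero-length segment")
        if self.tag not in TAGS:
            raise ValueError(f"unknown tag {self.tag!r}")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from p0 to p1."""
        d = self.p1 - self.p0
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class Sphere:
    """A sphere; used for the white row markers placed at batch boundaries."""

    center: np.ndarray
    radius: float
    tag: str = "marker"

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0.0:
            raise ValueError("sphere radius must be positive")


@dataclass(frozen=True)
class Batch:
    """One treatment x plot unit: a half-open x-interval ``[x0, x1)`` of the row."""

    treatment: str
    plot: int
    x0: float
    x1: float


@dataclass(frozen=True)
class BatchTruth:
    treatment: str
    plot: int
    true_shoot_volume: float  # m^3
    true_biomass: float  # kg


@dataclass(frozen=True)
class SceneSpec:
    """Layout and vine-template parameters for :func:`build_scene`.

    Defaults emulate the study conditions: 5 treatments x 3 plots x 10 vines
    (150 vines), vertically trellised canes thinner than 1 cm attached to a
    cordon at 1.0 m, two trellis wires, posts and markers at batch bounds.
    """

    n_treatments: int = 5
    n_plots_per_treatment: int = 3
    n_vines_per_plot: int = 10
    treatment_labels: tuple[str, ...] = ("S1", "S2", "S3_1", "S3_2", "S4_1")

    vine_spacing: float = 1.1  # m between vine trunks along the row
    end_margin: float = 0.45  # m of clear row at each end of a batch
    row_y: float = 1.0  # crop-depth offset of the row plane from the sensor path

    trunk_height: float = 1.0  # m, cordon/training height
    trunk_radius: float = 0.025
    cordon_radius: float = 0.015

    shoots_per_vine: tuple[int, int] = (10, 16)  # inclusive; ~2 buds on each
    # of 6-8 spurs leave 10-20 canes and a few tenths of kg of pruning wood
    # per vine, the realistic range for a spur-pruned cordon
    vine_span: float = 1.05  # m of cordon over which cane bases spread;
    # spurs sit along the whole (continuous) cordon, so adjacent vines' canes
    # interleave rather than leaving bare cordon at vine boundaries
    shoot_length: tuple[float, float] = (0.7, 1.2)
    shoot_base_radius: tuple[float, float] = (0.0032, 0.0050)  # diameter < 1 cm
    shoot_tip_radius: tuple[float, float] = (0.0012, 0.0020)
    shoot_segments: tuple[int, int] = (2, 4)  # chained frusta per cane
    shoot_tilt_sd_deg: float = 8.0  # polar tilt from vertical
    shoot_tilt_max_deg: float = 20.0
    shoot_lateral_frac: float = 0.3  # damping of the cross-row tilt component

    # secondary (lateral) shoots on each cane: short, thin (down to <2 mm)
    # side branches that make real pruning wood a tangle rather than a comb
    laterals_per_shoot: tuple[int, int] = (0, 3)
    lateral_length: tuple[float, float] = (0.10, 0.35)
    lateral_angle_deg: tuple[float, float] = (25.0, 60.0)
    lateral_radius_frac: float = 0.55  # of the cane radius at the attachment

    wire_heights: tuple[float, ...] = (1.35, 1.65)
    wire_radius: float = 0.0015
    post_radius: float = 0.04
    post_height: float = 1.9
    marker_radius: float = 0.05

    wood_density: float = 450.0  # kg/m^3, configuration default
    ground_z: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_treatments, self.n_plots_per_treatment, self.n_vines_per_plot) <= 0:
            raise ValueError("treatment/plot/vine counts must be positive")
        if self.shoots_per_vine[0] < 0 or self.shoots_per_vine[1] < self.shoots_per_vine[0]:
            raise ValueError("invalid shoots_per_vine range")
        if self.shoot_base_radius[1] > 0.005:
            raise ValueError("shoot radii above 5 mm violate the <1 cm diameter premise")
        max_reach = (self.shoot_length[1] * math.sin(math.radians(self.shoot_tilt_max_deg))
                     + self.lateral_length[1])
        if self.batch_length < 2.0 * max_reach:
            raise ValueError("batch too short for the cane reach; canes could not "
                             "be kept inside their batch interval")

    @property
    def batch_length(self) -> float:
        return 2.0 * self.end_margin + self.n_vines_per_plot * self.vine_spacing

    @property
    def n_batches(self) -> int:
        return self.n_treatments * self.n_plots_per_treatment


@dataclass
class VineScene:
    """A generated vineyard row: frustum segments, marker spheres, batches."""

    segments: list[Segment]
    markers: list[Sphere]
    batches: list[Batch]
    wood_density: float
    seed: int
    row_y: float = 1.0
    ground_z: float = 0.0
    spec: SceneSpec | None = field(default=None, repr=False)

    @property
    def x_extent(self) -> tuple[float, float]:
        return self.batches[0].x0, self.batches[-1].x1

    def segments_by_tag(self, tag: str) -> list[Segment]:
        return [s for s in self.segments if s.tag == tag]


def frustum_volume(segment: Segment) -> float:
    """Exact volume of a conical frustum: ``pi*h/3 * (r0^2 + r0*r1 + r1^2)``."""
    h = segment.length
    if h <= 0.0:
        raise ValueError("zero-length segment has no volume")
    r0, r1 = segment.r0, segment.r1
    return math.pi * h / 3.0 * (r0 * r0 + r0 * r1 + r1 * r1)


def _tilted_direction(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    """Unit growth direction: vertical plus a capped random tilt.

    The cross-row (Y) component is damped because canes are trained into the
    row plane by the vertical trellis.
    """
    tilt = min(abs(rng.normal(0.0, math.radians(spec.shoot_tilt_sd_deg))),
               math.radians(spec.shoot_tilt_max_deg))
    azim = rng.uniform(0.0, 2.0 * math.pi)
    d = np.array([
        math.sin(tilt) * math.cos(azim),
        math.sin(tilt) * math.sin(azim) * spec.shoot_lateral_frac,
        math.cos(tilt),
    ])
    return d / np.linalg.norm(d)


def _jitter_direction(d: np.ndarray, rng: np.random.Generator, sd_deg: float = 3.0) -> np.ndarray:
    d = d + rng.normal(0.0, math.radians(sd_deg), size=3)
    return d / np.linalg.norm(d)


def _rotate_toward(d: np.ndarray, angle: float, azim: float,
                   lateral_frac: float) -> np.ndarray:
    """Tilt direction ``d`` by ``angle`` toward a damped random azimuth."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    side = math.cos(azim) * u + math.sin(azim) * v
    side[1] *= lateral_frac
    side /= np.linalg.norm(side)
    out = math.cos(angle) * d + math.sin(angle) * side
    return out / np.linalg.norm(out)


def _build_shoot(base: np.ndarray, rng: np.random.Generator, spec: SceneSpec,
                 xlim: tuple[float, float]) -> list[Segment]:
    """One cane: a chain of tapered frusta plus a few thin lateral shoots.

    A cane (or lateral) that would cross its batch boundary is mirrored in x
    about its base -- end-of-row canes are tucked inward by the trellis.
    """
    length = rng.uniform(*spec.shoot_length)
    r_base = rng.uniform(*spec.shoot_base_radius)
    r_tip = rng.uniform(*spec.shoot_tip_radius)
    n_seg = int(rng.integers(spec.shoot_segments[0], spec.shoot_segments[1] + 1))
    d = _tilted_direction(rng, spec)
    chain: list[tuple[np.ndarray, np.ndarray, float, float]] = []
    p = base
    for i in range(n_seg):
        frac0, frac1 = i / n_seg, (i + 1) / n_seg
        q = p + d * (length / n_seg)
        chain.append((p, q, r_base + (r_tip - r_base) * frac0,
                      r_base + (r_tip - r_base) * frac1))
        p = q
        d = _jitter_direction(d, rng)
    n_lat = int(rng.integers(spec.laterals_per_shoot[0],
                             spec.laterals_per_shoot[1] + 1))
    for _ in range(n_lat):
        i = int(rng.integers(0, n_seg))
        p0, p1, r0, r1 = chain[i]
        u = rng.uniform(0.2, 0.9)
        attach = p0 + u * (p1 - p0)
        r_att = max(0.0008, spec.lateral_radius_frac * (r0 + u * (r1 - r0)))
        axis = (p1 - p0) / np.linalg.norm(p1 - p0)
        ld = _rotate_toward(axis, math.radians(rng.uniform(*spec.lateral_angle_deg)),
                            rng.uniform(0.0, 2.0 * math.pi), spec.shoot_lateral_frac)
        llen = rng.uniform(*spec.lateral_length)
        chain.append((attach, attach + ld * llen, r_att, max(0.0006, 0.4 * r_att)))
    lo, hi = xlim[0] + 0.02, xlim[1] - 0.02
    xs = [x for p0, p1, _, _ in chain for x in (p0[0], p1[0])]
    if min(xs) < lo or max(xs) > hi:
        chain = [(np.array([2 * base[0] - p0[0], p0[1], p0[2]]),
                  np.array([2 * base[0] - p1[0], p1[1], p1[2]]), r0, r1)
                 for p0, p1, r0, r1 in chain]
    return [Segment(p0, p1, r0, r1, tag="shoot") for p0, p1, r0, r1 in chain]


def build_scene(spec: SceneSpec, seed: int) -> VineScene:
    """Generate a deterministic vineyard row for ``spec`` and ``seed``."""
    rng = np.random.default_rng(seed)
    labels = list(spec.treatment_labels)
    while len(labels) < spec.n_treatments:  # pad if config gives fewer labels
        labels.append(f"T{len(labels) + 1}")
    labels = labels[: spec.n_treatments]

    segments: list[Segment] = []
    markers: list[Sphere] = []
    batches: list[Batch] = []
    y = spec.row_y
    z0 = spec.ground_z
    L = spec.batch_length

    b = 0
    for treatment in labels:
        for plot in range(1, spec.n_plots_per_treatment + 1):
            x0, x1 = b * L, (b + 1) * L
            batches.append(Batch(treatment, plot, x0, x1))
            # one continuous cordon per batch at training height
            segments.append(Segment(
                np.array([x0 + 0.05, y, z0 + spec.trunk_height]),
                np.array([x1 - 0.05, y, z0 + spec.trunk_height]),
                spec.cordon_radius, spec.cordon_radius, tag="cordon"))
            for v in range(spec.n_vines_per_plot):
                xv = x0 + spec.end_margin + (v + 0.5) * spec.vine_spacing
                segments.append(Segment(
                    np.array([xv, y, z0]),
                    np.array([xv, y, z0 + spec.trunk_height]),
                    spec.trunk_radius, 0.8 * spec.trunk_radius, tag="trunk"))
                n_shoots = int(rng.integers(spec.shoots_per_vine[0],
                                            spec.shoots_per_vine[1] + 1))
                if n_shoots == 0:
                    continue
                offsets = (np.linspace(-0.5, 0.5, n_shoots) * spec.vine_span
                           + rng.uniform(-0.015, 0.015, size=n_shoots))
                for dx in offsets:
                    base = np.array([
                        xv + dx,
                        y + rng.uniform(-0.01, 0.01),
                        z0 + spec.trunk_height + spec.cordon_radius,
                    ])
                    shoot = _build_shoot(base, rng, spec, (x0, x1))
                    for s in shoot:
                        if not (x0 <= s.p0[0] < x1 and x0 <= s.p1[0] < x1):
                            raise AssertionError("cane escaped its batch interval")
                    segments.extend(shoot)
            b += 1

    total_len = spec.n_batches * L
    for zw in spec.wire_heights:
        segments.append(Segment(np.array([0.0, y, z0 + zw]),
                                np.array([total_len, y, z0 + zw]),
                                spec.wire_radius, spec.wire_radius, tag="wire"))
    for k in range(spec.n_batches + 1):
        xp = min(k * L, total_len - 1e-6)
        segments.append(Segment(np.array([xp, y, z0]),
                                np.array([xp, y, z0 + spec.post_height]),
                                spec.post_radius, spec.post_radius, tag="post"))
        markers.append(Sphere(np.array([xp, y, z0 + spec.post_height + spec.marker_radius]),
                              spec.marker_radius))

    return VineScene(segments=segments, markers=markers, batches=batches,
                     wood_density=spec.wood_density, seed=int(seed),
                     row_y=y, ground_z=z0, spec=spec)


def batch_truth(scene: VineScene) -> list[BatchTruth]:
    """Analytic per-batch shoot volume and biomass.

    A shoot segment belongs to the batch containing its base (``p0``); the
    generator guarantees whole canes stay inside one interval.  Wires, posts,
    trunks and cordons are excluded from the truth (training structures and
    negligible-volume wires are not pruning biomass).
    """
    out = []
    for batch in scene.batches:
        vol = sum(frustum_volume(s) for s in scene.segments
                  if s.tag == "shoot" and batch.x0 <= s.p0[0] < batch.x1)
        out.append(BatchTruth(batch.treatment, batch.plot, vol,
                              scene.wood_density * vol))
    return out


def n_vines(scene: VineScene) -> int:
    """Number of vines (trunk segments) in the scene."""
    return len(scene.segments_by_tag("trunk"))


# ---------------------------------------------------------------------------
# dense surface sampling (used for resolution-limited volume recovery checks)

def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(axis, u)


def sample_surface(scene: VineScene, spacing: float,
                   rng: np.random.Generator | None = None,
                   include_tags: tuple[str, ...] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sample points on primitive surfaces at roughly ``spacing`` metres.

    Rings are placed along each frustum axis with azimuthal phase jitter
    (breaking the cospherical degeneracies exact rings would hand to the
    Delaunay tetrahedralization); markers get a Fibonacci covering.  Returns
    ``(points, tags)``.
    """
    if spacing <= 0.0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(0) if rng is None else rng
    pts: list[np.ndarray] = []
    tags: list[np.ndarray] = []
    for seg in scene.segments:
        if include_tags is not None and seg.tag not in include_tags:
            continue
        h = seg.length
        a = seg.axis
        u, v = _orthonormal_frame(a)
        n_rings = max(2, int(math.ceil(h / spacing)) + 1)
        s = np.linspace(0.0, h, n_rings)
        s[1:-1] += rng.uniform(-0.25, 0.25, size=n_rings - 2) * (h / (n_rings - 1))
        for si in s:
            r = seg.r0 + (seg.r1 - seg.r0) * (si / h)
            n_az = max(3, int(math.ceil(2.0 * math.pi * r / spacing)))
            phase = rng.uniform(0.0, 2.0 * math.pi)
            az = phase + np.linspace(0.0, 2.0 * math.pi, n_az, endpoint=False)
            ring = (seg.p0 + a * si
                    + r * (np.cos(az)[:, None] * u + np.sin(az)[:, None] * v))
            pts.append(ring)
            tags.append(np.full(n_az, seg.tag, dtype="<U8"))
    if include_tags is None or "marker" in include_tags:
        for sph in scene.markers:
            n = max(8, int(4.0 * math.pi * sph.radius ** 2 / spacing ** 2))
            i = np.arange(n)
            phi = math.pi * (3.0 - math.sqrt(5.0)) * i
            zz = 1.0 - 2.0 * (i + 0.5) / n
            rr = np.sqrt(1.0 - zz * zz)
            pts.append(sph.center + sph.radius
                       * np.stack([rr * np.cos(phi), rr * np.sin(phi), zz], axis=1))
            tags.append(np.full(n, sph.tag, dtype="<U8"))
    if not pts:
        return np.empty((0, 3)), np.empty(0, dtype="<U8")
    return np.concatenate(pts), np.concatenate(tags)


def scene_to_mesh(scene: VineScene, sections: int = 12):
    """Tessellate the scene as a watertight-ish triangle soup for inspection.

    Returns a :class:`trimesh.Trimesh`; export with ``mesh.export(path)``.
    """
    import trimesh

    meshes = []
    for seg in scene.segments:
        a = seg.axis
        u, v = _orthonormal_frame(a)
        az = np.linspace(0.0, 2.0 * math.pi, sections, endpoint=False)
        ring = np.cos(az)[:, None] * u + np.sin(az)[:, None] * v
        v0 = seg.p0 + seg.r0 * ring
        v1 = seg.p1 + seg.r1 * ring
        verts = np.vstack([v0, v1, seg.p0[None, :], seg.p1[None, :]])
        faces = []
        for i in range(sections):
            j = (i + 1) % sections
            faces += [[i, j, sections + i], [j, sections + j, sections + i]]
            faces += [[2 * sections, j, i], [2 * sections + 1, sections + i, sections + j]]
        meshes.append(trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False))
    for sph in scene.markers:
        m = trimesh.creation.icosphere(subdivisions=2, radius=sph.radius)
        m.apply_translation(sph.center)
        meshes.append(m)
    return trimesh.util.concatenate(meshes)
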