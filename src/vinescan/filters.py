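"""Reduce a georeferenced cloud to vine-shoot points.

Stages (default pipeline order, all strict subset operations): crop to the
batch x-interval, cut below the bud-height plane, split out training
structures (posts + markers) by cylinder masks, and statistical outlier
removal against the 64-neighbour mean-distance distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import PointCloud

__all__ = [
    "CylinderMask",
    "FilterConfig",
    "crop_batch",
    "cut_below_height",
    "sor_filter",
    "sor_outlier_mask",
    "mask_training_structures",
    "structure_masks",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CylinderMask:
    """Finite cylinder around a known structure axis (post, wire, marker column)."""

    p0: np.ndarray
    p1: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "p0", np.asarray(self.p0, dtype=float))
        object.__setattr__(self, "p1", np.asarray(self.p1, dtype=float))
        if self.radius <= 0.0:
            raise ValueError("mask radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = self.p1 - self.p0
        h2 = float(d @ d)
        w = np.asarray(points) - self.p0
        s = np.clip((w @ d) / h2, 0.0, 1.0)
        closest = self.p0 + s[:, None] * d
        return np.linalg.norm(points - closest, axis=1) <= self.radius


@dataclass
class FilterConfig:
    """Shoot-extraction parameters.

    ``nsigma`` scales the SOR threshold (mean + nsigma*sd of the neighbour
    distances); ``literal_sigma`` switches to the threshold = sd reading.
    """

    k_neighbors: int = 64
    nsigma: float = 1.0
    bud_height: float = 1.0  # m; bud plane at the training (cordon) height
    masks: list[CylinderMask] = field(default_factory=list)
    literal_sigma: bool = False

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.nsigma <= 0.0:
            raise ValueError("nsigma must be positive")
        if self.bud_height < 0.0:
            raise ValueError("bud height must be >= 0")


def crop_batch(cloud: PointCloud, x_interval: tuple[float, float]) -> PointCloud:
    """Keep points with x in the half-open interval ``[x0, x1)``."""
    x0, x1 = x_interval
    if not x1 > x0:
        raise ValueError("empty batch interval")
    return cloud.select((cloud.points[:, 0] >= x0) & (cloud.points[:, 0] < x1))


def cut_below_height(cloud: PointCloud, z0: float) -> PointCloud:
    """Keep points at or above the bud plane (drops stump/cordon/soil returns)."""
    if not np.isfinite(z0):
        raise ValueError("bud height must be finite")
    return cloud.select(cloud.points[:, 2] >= z0)


def sor_outlier_mask(points: np.ndarray, k: int = 64, nsigma: float = 1.0,
                     literal_sigma: bool = False) -> np.ndarray:
    """True where a point is an outlier under the k-NN mean-distance rule.

    d_i = mean distance to the k nearest neighbours; outliers have
    d_i > mean(d) + nsigma*sd(d) (or d_i > sd(d) under the literal rule).
    k is clamped to N-1 for small clouds.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("SOR needs at least two points")
    k_eff = min(k, n - 1)
    if k_eff < k:
        log.info("sor_filter: clamped k from %d to %d for N=%d", k, k_eff, n)
    dist, _ = cKDTree(pts).query(pts, k=k_eff + 1)
    d = dist[:, 1:].mean(axis=1)  # exclude self (distance 0)
    threshold = d.std() if literal_sigma else d.mean() + nsigma * d.std()
    return d > threshold


def sor_filter(cloud: PointCloud, k: int = 64, nsigma: float = 1.0,
               literal_sigma: bool = False) -> tuple[PointCloud, int]:
    """Single-pass statistical outlier removal; returns (kept, removed count)."""
    out = sor_outlier_mask(cloud.points, k, nsigma, literal_sigma)
    return cloud.select(~out), int(out.sum())


def mask_training_structures(cloud: PointCloud, masks: list[CylinderMask],
                             ) -> tuple[PointCloud, PointCloud]:
    """Split the cloud into (shoot cloud, structure cloud) by the cylinder masks."""
    if not masks or len(cloud) == 0:
        return cloud, cloud.select(np.zeros(len(cloud), dtype=bool))
    inside = np.zeros(len(cloud), dtype=bool)
    for m in masks:
        inside |= m.contains(cloud.points)
    return cloud.select(~inside), cloud.select(inside)


def structure_masks(scene, margin: float = 0.05,
                    include_wires: bool = False) -> list[CylinderMask]:
    """Masks for a synthetic scene's posts (+ their markers) and optionally wires.

    Post masks extend above the post to swallow the boundary marker sphere;
    wire masks are off by default because wire returns are negligible-volume
    and are normally left in the cloud.
    """
    masks = []
    marker_r = max((m.radius for m in scene.markers), default=0.0)
    for seg in scene.segments:
        if seg.tag == "post":
            top = seg.p1 + np.array([0.0, 0.0, 2.0 * marker_r + margin])
            masks.append(CylinderMask(seg.p0, top, max(seg.r0, marker_r) + margin))
        elif include_wires and seg.tag == "wire":
            masks.append(CylinderMask(seg.p0, seg.p1, seg.r0 + margin))
    return masks
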