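"""3D alpha-shapes over a Delaunay tetrahedralization: the volume estimator.

The alpha-complex of a point set retains every Delaunay tetrahedron whose
circumsphere radius is at most alpha; the enclosed volume is the exact sum of
retained tetrahedron volumes (their interiors are disjoint).  Alpha is a
LENGTH in metres (circumradius threshold): alpha = 0.1 means 0.1 m.  Because
the retained set is nested in alpha, the volume is monotone and reaches the
convex-hull volume once alpha exceeds the largest circumradius.

The working alpha is chosen by the smallest-solid rule: the smallest candidate
whose complex is a single face-connected component covering (almost) all
points -- an operational reading of "the smallest volume whilst maintaining a
solid surface free from voids".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "AlphaShapeResult",
    "tetrahedron_circumradius",
    "alpha_complex",
    "select_alpha",
    "volume_without_structures",
]

log = logging.getLogger(__name__)

#: relative determinant threshold below which a tetrahedron is degenerate
DEGENERATE_REL_DET = 1e-12


@dataclass
class AlphaShapeResult:
    """An alpha-complex: retained tetrahedra, boundary surface, volume."""

    alpha: float
    tetrahedra: np.ndarray  # (M, 4) vertex indices into the point array
    boundary_triangles: np.ndarray  # (B, 3) vertex indices
    volume: float  # m^3
    n_components: int
    n_points_covered: int
    n_points: int
    n_points_main_component: int = 0

    @property
    def coverage(self) -> float:
        return self.n_points_covered / self.n_points if self.n_points else 0.0

    @property
    def main_component_coverage(self) -> float:
        """Fraction of all points covered by the largest connected component."""
        return self.n_points_main_component / self.n_points if self.n_points else 0.0


def tetrahedron_circumradius(vertices: np.ndarray) -> float:
    """Radius of the circumscribing sphere of one tetrahedron.

    Returns ``inf`` for a degenerate (coplanar) tetrahedron.
    """
    r, _, deg = _circumradii(np.asarray(vertices, dtype=float)[None, :, :],
                             np.zeros((1, 4), dtype=int))
    return float("inf") if deg[0] else float(r[0])


def _circumradii(verts: np.ndarray, simplices: np.ndarray):
    """Vectorized circumradius + volume for (M, 4, 3) tetra vertex arrays.

    The circumcenter c solves 2 (a_i - a_0) . c = |a_i|^2 - |a_0|^2; the
    system matrix determinant is 6 x the signed tetra volume, so it doubles
    as volume and degeneracy test.
    """
    a0 = verts[:, 0, :]
    E = verts[:, 1:, :] - a0[:, None, :]  # (M, 3, 3) edge matrix
    det = np.linalg.det(E)
    vol = np.abs(det) / 6.0
    scale = np.max(np.abs(E), axis=(1, 2))
    scale = np.where(scale > 0.0, scale, 1.0)
    degenerate = np.abs(det) <= DEGENERATE_REL_DET * scale ** 3
    rhs = 0.5 * (np.einsum("mij,mij->mi", verts[:, 1:, :], verts[:, 1:, :])
                 - np.einsum("mj,mj->m", a0, a0)[:, None])
    R = np.full(len(verts), np.inf)
    ok = ~degenerate
    if np.any(ok):
        center = np.linalg.solve(E[ok], rhs[ok][..., None])[..., 0]
        R[ok] = np.linalg.norm(center - a0[ok], axis=1)
    return R, vol, degenerate


def _components(kept_idx: np.ndarray, neighbors: np.ndarray,
                simplices: np.ndarray) -> tuple[int, int]:
    """Face-adjacency components of the retained tetrahedra.

    Returns ``(n_components, n_points_in_largest_component)``.
    """
    if len(kept_idx) == 0:
        return 0, 0
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    m = len(kept_idx)
    pos = -np.ones(neighbors.shape[0], dtype=np.int64)
    pos[kept_idx] = np.arange(m)
    nb = neighbors[kept_idx]  # (m, 4), -1 at hull facets
    src = np.repeat(np.arange(m), 4)
    dst_global = nb.ravel()
    ok = dst_global >= 0
    src, dst_global = src[ok], dst_global[ok]
    dst = pos[dst_global]
    ok = dst >= 0
    src, dst = src[ok], dst[ok]
    g = coo_matrix((np.ones(len(src), dtype=np.int8), (src, dst)), shape=(m, m))
    n_comp, labels = connected_components(g, directed=False)
    kept = simplices[kept_idx]
    pairs = np.unique(np.stack([np.repeat(labels, 4), kept.ravel()], axis=1), axis=0)
    per_comp = np.bincount(pairs[:, 0], minlength=n_comp)
    return int(n_comp), int(per_comp.max())


def _boundary_faces(kept: np.ndarray) -> np.ndarray:
    """Triangles belonging to exactly one retained tetrahedron."""
    if len(kept) == 0:
        return np.empty((0, 3), dtype=int)
    faces = np.concatenate([kept[:, [1, 2, 3]], kept[:, [0, 2, 3]],
                            kept[:, [0, 1, 3]], kept[:, [0, 1, 2]]])
    faces = np.sort(faces, axis=1)
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    return uniq[counts == 1]


def _empty_result(alpha: float, n_points: int) -> AlphaShapeResult:
    return AlphaShapeResult(alpha, np.empty((0, 4), dtype=int),
                            np.empty((0, 3), dtype=int), 0.0, 0, 0, n_points)


def _tetrahedralize(points: np.ndarray, jitter_seed: int = 0) -> Delaunay | None:
    try:
        return Delaunay(points)
    except QhullError:
        # e.g. all points coplanar up to rounding: retry with a 1 nm jitter
        rng = np.random.default_rng(jitter_seed)
        try:
            return Delaunay(points + rng.normal(0.0, 1e-9, points.shape))
        except QhullError:
            return None


def alpha_complex(points: np.ndarray, alpha: float,
                  jitter_seed: int = 0) -> AlphaShapeResult:
    """Alpha-complex of ``points`` at circumradius threshold ``alpha`` (m)."""
    if alpha <= 0.0:
        raise ValueError("alpha must be positive")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 4:
        warnings.warn("fewer than 4 points: empty alpha-complex", stacklevel=2)
        return _empty_result(alpha, len(points))
    tri = _tetrahedralize(points)
    if tri is None:
        warnings.warn("degenerate point set: empty alpha-complex", stacklevel=2)
        return _empty_result(alpha, len(points))
    return _complex_from_triangulation(tri, alpha, len(points))


def _complex_from_triangulation(tri: Delaunay, alpha: float,
                                n_points: int) -> AlphaShapeResult:
    R, vol, degenerate = _circumradii(tri.points[tri.simplices], tri.simplices)
    keep = (~degenerate) & (R <= alpha)
    kept_idx = np.flatnonzero(keep)
    kept = tri.simplices[kept_idx]
    n_comp, n_main = _components(kept_idx, tri.neighbors, tri.simplices)
    return AlphaShapeResult(
        alpha=float(alpha),
        tetrahedra=kept,
        boundary_triangles=_boundary_faces(kept),
        volume=float(vol[kept_idx].sum()),
        n_components=n_comp,
        n_points_covered=len(np.unique(kept)) if len(kept) else 0,
        n_points=n_points,
        n_points_main_component=n_main,
    )


def select_alpha(points: np.ndarray, candidates, coverage_frac: float = 0.99,
                 jitter_seed: int = 0) -> tuple[float, dict[float, AlphaShapeResult]]:
    """Pick the working alpha by the smallest-solid rule.

    Evaluates the complex for every candidate (ascending) on one shared
    tetrahedralization and returns the smallest alpha whose largest
    face-connected component covers at least ``coverage_frac`` of the points
    -- i.e. the complex is one solid up to the same stray-point tolerance
    that ``coverage_frac`` grants to uncovered points.  If no candidate
    qualifies, the largest candidate is returned with a warning.  The
    per-candidate results are returned for the alpha sweep report.
    """
    cands = sorted(float(a) for a in candidates)
    if not cands:
        raise ValueError("need at least one candidate alpha")
    if len(set(cands)) != len(cands):
        raise ValueError("candidate alphas must be distinct")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    results: dict[float, AlphaShapeResult] = {}
    tri = _tetrahedralize(points, jitter_seed) if len(points) >= 4 else None
    for a in cands:
        results[a] = (_complex_from_triangulation(tri, a, len(points))
                      if tri is not None else _empty_result(a, len(points)))
    for a in cands:
        if results[a].main_component_coverage >= coverage_frac:
            return a, results
    warnings.warn("no candidate alpha gives a single covering component; "
                  "falling back to the largest", stacklevel=2)
    return cands[-1], results


def volume_without_structures(result_total: AlphaShapeResult | float,
                              result_structures: AlphaShapeResult | float) -> float:
    """Total minus training-structure volume, clamped at zero."""
    vt = result_total.volume if isinstance(result_total, AlphaShapeResult) else float(result_total)
    vs = (result_structures.volume
          if isinstance(result_structures, AlphaShapeResult) else float(result_structures))
    if vs > vt:
        warnings.warn("structure volume exceeds total; clamping to zero", stacklevel=2)
    return max(0.0, vt - vs)
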