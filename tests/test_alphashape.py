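"""Alpha-shape volume estimator: circumradii, complexes, alpha selection."""

import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull, Delaunay

import vinescan as vs
from vinescan.alphashape import (alpha_complex, select_alpha,
                                 tetrahedron_circumradius,
                                 volume_without_structures)

CUBE = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                 [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=float)


def _cylinder_surface(r=0.005, length=1.0, spacing=0.004, seed=0):
    rng = np.random.default_rng(seed)
    rings = int(length / spacing) + 1
    pts = []
    for z in np.linspace(0, length, rings):
        n = max(3, int(math.ceil(2 * math.pi * r / spacing)))
        az = rng.uniform(0, 2 * math.pi) + np.linspace(0, 2 * math.pi, n,
                                                       endpoint=False)
        pts.append(np.column_stack([r * np.cos(az), r * np.sin(az),
                                    np.full(n, z)]))
    return np.concatenate(pts)


class TestCircumradius:
    def test_regular_tetrahedron(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0.5, math.sqrt(3) / 2, 0],
                          [0.5, math.sqrt(3) / 6, math.sqrt(2.0 / 3.0)]])
        assert tetrahedron_circumradius(verts) == pytest.approx(0.612372, abs=1e-6)

    def test_unit_cube_corner(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        assert tetrahedron_circumradius(verts) == pytest.approx(0.866025, abs=1e-6)

    def test_coplanar_is_degenerate(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        assert tetrahedron_circumradius(verts) == math.inf


class TestAlphaComplex:
    def test_cube_at_large_alpha_recovers_unit_volume(self):
        res = alpha_complex(CUBE, alpha=10.0)
        assert res.volume == pytest.approx(1.0, abs=1e-12)
        assert res.n_components == 1
        assert res.coverage == 1.0

    def test_cube_below_min_circumradius_is_empty(self):
        res = alpha_complex(CUBE, alpha=0.1)  # min circumradius ~ 0.866
        assert res.volume == 0.0 and len(res.tetrahedra) == 0

    def test_cylinder_volume_within_sampling_tolerance(self):
        pts = _cylinder_surface()
        res = alpha_complex(pts, alpha=0.1)
        truth = math.pi * 0.005**2 * 1.0
        assert abs(res.volume - truth) / truth < 0.25
        assert res.coverage > 0.99

    def test_volume_monotone_in_alpha(self, rng):
        alphas = [0.05, 0.1, 0.2, 0.4, 0.8, 1.6]
        for _ in range(100):
            pts = rng.uniform(0, 1, size=(40, 3))
            vols = [alpha_complex(pts, a).volume for a in alphas]
            assert all(v1 <= v2 + 1e-12 for v1, v2 in zip(vols, vols[1:]))

    def test_hull_limit(self, rng):
        for seed in range(5):
            pts = np.random.default_rng(seed).normal(size=(60, 3))
            tri = Delaunay(pts)
            big = max(tetrahedron_circumradius(pts[s]) for s in tri.simplices
                      if tetrahedron_circumradius(pts[s]) < math.inf)
            res = alpha_complex(pts, alpha=big * (1 + 1e-9))
            hull = ConvexHull(pts).volume
            assert abs(res.volume - hull) / hull < 1e-9

    def test_monte_carlo_volume_oracle(self):
        """Summed tetra volume agrees with point-in-complex MC integration."""
        rng = np.random.default_rng(12)
        pts = rng.uniform(0, 1, size=(200, 3))
        res = alpha_complex(pts, alpha=0.35)
        assert res.volume > 0
        retained = {tuple(sorted(t)) for t in res.tetrahedra}
        tri = Delaunay(pts)
        m = 40000
        samples = rng.uniform(0, 1, size=(m, 3))
        idx = tri.find_simplex(samples)
        inside = np.array([i >= 0 and tuple(sorted(tri.simplices[i])) in retained
                           for i in idx])
        p = inside.mean()
        mc_vol = p  # bounding box volume is 1
        se = math.sqrt(p * (1 - p) / m)
        assert abs(res.volume - mc_vol) <= 3 * se

    def test_fewer_than_four_points_warns_empty(self):
        with pytest.warns(UserWarning):
            res = alpha_complex(np.zeros((3, 3)), alpha=0.5)
        assert res.volume == 0.0 and res.n_points == 3

    def test_coplanar_cloud_handled_via_jitter(self):
        g = np.stack(np.meshgrid(np.linspace(0, 1, 6), np.linspace(0, 1, 6)),
                     axis=-1).reshape(-1, 2)
        pts = np.column_stack([g, np.zeros(len(g))])
        res = alpha_complex(pts, alpha=1.0)
        assert res.volume == pytest.approx(0.0, abs=1e-6)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            alpha_complex(CUBE, alpha=0.0)

    def test_boundary_faces_belong_to_exactly_one_tetra(self):
        pts = np.random.default_rng(3).normal(size=(50, 3))
        res = alpha_complex(pts, alpha=1.0)
        faces = np.sort(np.concatenate([
            res.tetrahedra[:, [1, 2, 3]], res.tetrahedra[:, [0, 2, 3]],
            res.tetrahedra[:, [0, 1, 3]], res.tetrahedra[:, [0, 1, 2]]]), axis=1)
        uniq, counts = np.unique(faces, axis=0, return_counts=True)
        expected = uniq[counts == 1]
        got = np.unique(np.sort(res.boundary_triangles, axis=1), axis=0)
        np.testing.assert_array_equal(got, expected)


def _blob(center, n, radius, seed):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return center + v * (radius * rng.uniform(0, 1, size=(n, 1)) ** (1 / 3))


def _bfs_component_count(tetrahedra):
    """Independent union-find over shared triangular faces."""
    parent = list(range(len(tetrahedra)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    owners = {}
    for i, tet in enumerate(tetrahedra):
        for face in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
            key = tuple(sorted(tet[list(face)]))
            if key in owners:
                parent[find(i)] = find(owners[key])
            else:
                owners[key] = i
    return len({find(i) for i in range(len(tetrahedra))})


class TestSelectAlpha:
    def test_two_blobs_need_the_large_alpha(self):
        pts = np.vstack([_blob(np.zeros(3), 150, 0.05, 1),
                         _blob(np.array([1.0, 0, 0]), 150, 0.05, 2)])
        chosen, results = select_alpha(pts, [0.1, 0.9])
        assert chosen == 0.9
        r = results[0.1]
        assert r.n_components == 2
        assert _bfs_component_count(r.tetrahedra) == 2
        assert _bfs_component_count(results[0.9].tetrahedra) == 1

    def test_dense_blob_takes_smallest_candidate(self):
        pts = _blob(np.zeros(3), 400, 0.05, 3)
        chosen, _ = select_alpha(pts, [0.1, 0.3, 0.5, 0.7, 0.9])
        assert chosen == 0.1

    def test_single_tetrahedron_takes_smallest(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        chosen, _ = select_alpha(verts, [0.9, 1.5, 2.0])
        assert chosen == 0.9

    def test_no_qualifying_candidate_falls_back_to_largest(self):
        pts = np.vstack([_blob(np.zeros(3), 100, 0.05, 4),
                         _blob(np.array([50.0, 0, 0]), 100, 0.05, 5)])
        with pytest.warns(UserWarning, match="falling back"):
            chosen, _ = select_alpha(pts, [0.1, 0.2])
        assert chosen == 0.2

    def test_duplicate_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_alpha(CUBE, [0.5, 0.5])


class TestVolumeWithoutStructures:
    def test_subtraction(self):
        assert volume_without_structures(5e-4, 1e-4) == pytest.approx(4e-4)

    def test_no_structures_keeps_total(self):
        assert volume_without_structures(5e-4, 0.0) == 5e-4

    def test_pathological_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert volume_without_structures(1e-4, 5e-4) == 0.0
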