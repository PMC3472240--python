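"""Tetrahedron primitives, connectivity, quality metrics, box-mesh generator."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import fit_circumsphere, fit_insphere
from rdvox.geometry import (DegenerateTetError, NonManifoldMeshError,
                            REGULAR_RADIUS_EDGE, Tetmesh, WellMixedCompartment,
                            WellMixedGeometry, WellMixedPatch,
                            build_connectivity, generate_box_tetmesh,
                            quality_metrics, tet_geometry)

UNIT_TET = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)


class TestTetGeometry:
    def test_unit_tet_closed_form(self):
        geo = tet_geometry(UNIT_TET)
        assert geo["volume"] == pytest.approx(1.0 / 6.0)
        assert geo["barycenter"] == pytest.approx([0.25, 0.25, 0.25])
        # three axis-aligned right-triangle faces of area 1/2 and the
        # diagonal face of area sqrt(3)/2
        assert sorted(geo["face_areas"]) == pytest.approx(
            [0.5, 0.5, 0.5, np.sqrt(3) / 2])

    def test_regular_tet_volume(self, regular_tet):
        geo = tet_geometry(regular_tet)
        assert geo["volume"] == pytest.approx(np.sqrt(2.0) / 12.0, rel=1e-12)

    def test_coplanar_points_rejected(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(DegenerateTetError):
            tet_geometry(flat)


class TestQualityMetrics:
    def test_regular_tet_values(self, regular_tet):
        q = quality_metrics(regular_tet)
        assert q["radius_edge_ratio"] == pytest.approx(np.sqrt(6) / 4, rel=1e-12)
        assert q["radius_edge_ratio"] == pytest.approx(REGULAR_RADIUS_EDGE)
        assert q["aspect_ratio_beta"] == pytest.approx(1.0, rel=1e-12)

    def test_sliver_matches_sphere_fit_oracle(self):
        sliver = np.array([[0, 0, 0], [1, 0, 0], [0.5, 1.0, 0], [0.5, 0.45, 0.08]])
        q = quality_metrics(sliver)
        _, circ_r = fit_circumsphere(sliver)
        _, in_r = fit_insphere(sliver)
        edges = min(np.linalg.norm(sliver[i] - sliver[j])
                    for i, j in itertools.combinations(range(4), 2))
        assert q["radius_edge_ratio"] == pytest.approx(circ_r / edges, rel=1e-6)
        assert q["aspect_ratio_beta"] == pytest.approx(circ_r / (3 * in_r), rel=1e-6)
        # a flattened tet is worse than the regular one on both metrics
        assert q["radius_edge_ratio"] > REGULAR_RADIUS_EDGE
        assert q["aspect_ratio_beta"] > 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariance_under_rigid_motion_and_scaling(self, regular_tet, seed):
        rng = np.random.default_rng(seed)
        rot = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
        shift = rng.normal(size=3)
        scale = float(rng.uniform(0.1, 10.0))
        base = np.array([[0, 0, 0], [1, 0, 0], [0.2, 1.2, 0], [0.4, 0.3, 0.9]],
                        dtype=float)
        q0 = quality_metrics(base)
        q1 = quality_metrics(scale * base @ rot.T + shift)
        assert q1["radius_edge_ratio"] == pytest.approx(q0["radius_edge_ratio"],
                                                        rel=1e-9)
        assert q1["aspect_ratio_beta"] == pytest.approx(q0["aspect_ratio_beta"],
                                                        rel=1e-9)

    def test_regular_tet_minimizes_radius_edge(self, regular_tet):
        rng = np.random.default_rng(42)
        q0 = quality_metrics(regular_tet)["radius_edge_ratio"]
        for _ in range(50):
            q = quality_metrics(regular_tet + rng.normal(scale=0.05, size=(4, 3)))
            assert q["radius_edge_ratio"] >= q0 - 1e-9


class TestConnectivity:
    def test_two_tets_sharing_a_face(self):
        tets = [[0, 1, 2, 3], [0, 1, 2, 4]]
        conn = build_connectivity(tets)
        assert list(conn["neighbors"][0]).count(1) == 1
        assert list(conn["neighbors"][0]).count(-1) == 3
        assert list(conn["neighbors"][1]).count(0) == 1
        assert conn["boundary"].sum() == 6  # 7 faces, 1 internal

    def test_isolated_tet(self):
        conn = build_connectivity([[0, 1, 2, 3]])
        assert (conn["neighbors"] == -1).all()
        assert conn["boundary"].all() and len(conn["faces"]) == 4

    def test_cube_decomposition_vs_face_enumeration(self):
        mesh = generate_box_tetmesh(1.0, 1)
        # exhaustive oracle: count every face of every tet
        from collections import Counter
        counter = Counter()
        for tet in mesh.tets:
            for j in range(4):
                counter[tuple(sorted(np.delete(tet, j)))] += 1
        assert set(counter.values()) <= {1, 2}
        internal = sum(1 for v in counter.values() if v == 2)
        # 6-tet Kuhn cube: every internal face appears exactly twice and the
        # neighbor relation is symmetric
        for k in range(mesh.n_tets):
            for l in mesh.tet_neighbors[k]:
                if l >= 0:
                    assert k in mesh.tet_neighbors[l]
        assert internal == (~mesh.tri_boundary).sum()

    def test_non_manifold_rejected(self):
        tets = [[0, 1, 2, 3], [0, 1, 2, 4], [0, 1, 2, 5]]
        with pytest.raises(NonManifoldMeshError):
            build_connectivity(tets)


class TestBoxMesh:
    def test_unit_cube_single_division(self):
        mesh = generate_box_tetmesh(1.0, 1)
        assert mesh.n_tets == 6
        assert mesh.total_volume == pytest.approx(1.0, rel=1e-12)

    def test_three_divisions_count(self):
        mesh = generate_box_tetmesh(1.0, 3)
        assert mesh.n_tets == 27 * 6

    def test_volume_sums_exact_anisotropic(self):
        mesh = generate_box_tetmesh((2.0, 1.0, 0.5), (3, 2, 1))
        assert mesh.total_volume == pytest.approx(1.0, rel=1e-12)

    def test_all_tets_pass_quality(self):
        mesh = generate_box_tetmesh(1e-6, 2)
        rep = mesh.quality_report()
        assert (rep.radius_edge_ratio >= REGULAR_RADIUS_EDGE - 1e-9).all()
        assert (rep.aspect_ratio_beta >= 1.0 - 1e-9).all()

    def test_barycenter_distance_symmetric(self):
        mesh = generate_box_tetmesh(1e-6, 2)
        for k in range(mesh.n_tets):
            for l in mesh.tet_neighbors[k]:
                if l >= 0:
                    assert mesh.barycenter_distance(k, int(l)) == pytest.approx(
                        mesh.barycenter_distance(int(l), k), rel=1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_box_tetmesh(-1.0, 2)
        with pytest.raises(ValueError):
            generate_box_tetmesh(1.0, 0)


class TestAnnotation:
    def test_compartments_must_be_disjoint(self):
        mesh = generate_box_tetmesh(1.0, 1)
        mesh.add_compartment("a", [0, 1, 2], ("v",))
        with pytest.raises(ValueError, match="overlaps"):
            mesh.add_compartment("b", [2, 3])

    def test_patch_triangle_must_bound_inner_compartment(self):
        mesh = generate_box_tetmesh(1.0, (2, 1, 1))
        left = np.flatnonzero(mesh.tet_barycenters[:, 0] < 0.5)
        right = np.flatnonzero(mesh.tet_barycenters[:, 0] >= 0.5)
        mesh.add_compartment("L", left)
        mesh.add_compartment("R", right)
        # interface faces: shared by one L-tet and one R-tet
        iface = [fi for fi in range(len(mesh.tris))
                 if not mesh.tri_boundary[fi]
                 and {mesh.tet_compartment[t] for t in mesh.tri_tets[fi]} == {0, 1}]
        assert iface
        patch = mesh.add_patch("m", iface, inner="L", outer="R")
        inner, outer = mesh.patch_tri_tets("m")
        assert set(inner) <= set(int(t) for t in left)
        assert set(outer) <= set(int(t) for t in right)
        boundary_tri = int(np.flatnonzero(mesh.tri_boundary)[0])
        with pytest.raises(ValueError):
            mesh.add_patch("bad", [boundary_tri], inner="L", outer="R")

    def test_well_mixed_geometry_checks(self):
        geom = WellMixedGeometry()
        geom.add_compartment(WellMixedCompartment("c", 1e-18))
        with pytest.raises(ValueError):
            geom.add_patch(WellMixedPatch("p", 1e-12, inner="missing"))
        with pytest.raises(ValueError):
            WellMixedCompartment("bad", -1.0)
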