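"""Mesh data model, I/O round trips, quality metrics, refinement, surfaces."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioem.mesh_core import (
    DEFAULT_FIBRE,
    DEFAULT_SHEET,
    UVC_SENTINEL,
    LabelSchema,
    MeshFormatError,
    TetMesh,
    boundary_faces,
    edge_length_stats,
    extract_surfaces,
    read_mesh,
    scaled_jacobian,
    tet_volumes,
    triangle_areas,
    triangle_normals,
    uniform_refine,
    unique_edges,
    write_mesh,
)


def regular_tet(edge: float = 1.0) -> np.ndarray:
    return edge * np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.5, np.sqrt(3) / 2, 0.0],
            [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)],
        ]
    )


@pytest.fixture
def two_tet_mesh():
    nodes = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], dtype=float
    )
    mesh = TetMesh(
        nodes=nodes,
        tets=np.array([[0, 1, 2, 3], [1, 2, 3, 4]]),
        elem_tags=np.array([1, 14]),
    )
    mesh.default_frames()
    mesh.node_fields["uvc_z"] = np.array([0.0, 0.5, 0.5, 1.0, UVC_SENTINEL])
    mesh.node_fields["electrode_endo_rv"] = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    mesh.elem_fields["fast_layer"] = np.array([1.0, 0.0])
    return mesh


class TestCarpIO:
    def test_round_trip_identity(self, two_tet_mesh, tmp_path):
        write_mesh(two_tet_mesh, tmp_path / "m")
        back = read_mesh(tmp_path / "m")
        np.testing.assert_allclose(back.nodes, two_tet_mesh.nodes, atol=1e-9)
        np.testing.assert_array_equal(back.tets, two_tet_mesh.tets)
        np.testing.assert_array_equal(back.elem_tags, two_tet_mesh.elem_tags)
        np.testing.assert_allclose(back.fibres, two_tet_mesh.fibres, atol=1e-9)
        np.testing.assert_allclose(back.sheets, two_tet_mesh.sheets, atol=1e-9)
        # the -100 sentinel and the electrode label survive the round trip
        np.testing.assert_allclose(
            back.node_fields["uvc_z"], two_tet_mesh.node_fields["uvc_z"]
        )
        np.testing.assert_allclose(
            back.node_fields["electrode_endo_rv"],
            two_tet_mesh.node_fields["electrode_endo_rv"],
        )
        np.testing.assert_allclose(
            back.elem_fields["fast_layer"], two_tet_mesh.elem_fields["fast_layer"]
        )

    def test_elem_record_format(self, tmp_path):
        mesh = TetMesh(regular_tet(), np.array([[0, 1, 2, 3]]), np.array([1]))
        write_mesh(mesh, tmp_path / "one", write_lon=False)
        lines = (tmp_path / "one.elem").read_text().splitlines()
        assert lines[0] == "1"
        assert lines[1].split() == ["Tt", "0", "1", "2", "3", "1"]

    def test_default_vectors_for_non_ventricular(self, tmp_path):
        """A mesh without ventricular elements writes an all-default .lon."""
        mesh = TetMesh(regular_tet(), np.array([[0, 1, 2, 3]]), np.array([14]))
        mesh.default_frames()
        write_mesh(mesh, tmp_path / "cap")
        back = read_mesh(tmp_path / "cap")
        np.testing.assert_array_equal(back.fibres[0], DEFAULT_FIBRE)
        np.testing.assert_array_equal(back.sheets[0], DEFAULT_SHEET)

    def test_missing_fibres_lon_error(self, tmp_path):
        mesh = TetMesh(regular_tet(), np.array([[0, 1, 2, 3]]), np.array([1]))
        with pytest.raises(MeshFormatError, match="no fibre"):
            write_mesh(mesh, tmp_path / "x", write_lon=True)

    def test_header_count_mismatch(self, tmp_path):
        (tmp_path / "bad.pts").write_text("3\n0 0 0\n1 0 0\n")
        (tmp_path / "bad.elem").write_text("0\n")
        with pytest.raises(MeshFormatError, match="3 records"):
            read_mesh(tmp_path / "bad")

    def test_unsupported_element_type(self, tmp_path):
        (tmp_path / "hex.pts").write_text("4\n0 0 0\n1 0 0\n0 1 0\n0 0 1\n")
        (tmp_path / "hex.elem").write_text("1\nHx 0 1 2 3 0 0 0 0 1\n")
        with pytest.raises(MeshFormatError, match="unsupported element type"):
            read_mesh(tmp_path / "hex")


class TestVtkIO:
    def test_round_trip(self, two_tet_mesh, tmp_path):
        write_mesh(two_tet_mesh, tmp_path / "m.vtk", format="vtk")
        back = read_mesh(tmp_path / "m.vtk", format="vtk")
        np.testing.assert_allclose(back.nodes, two_tet_mesh.nodes, atol=1e-9)
        np.testing.assert_array_equal(back.tets, two_tet_mesh.tets)
        np.testing.assert_array_equal(back.elem_tags, two_tet_mesh.elem_tags)
        np.testing.assert_allclose(back.fibres, two_tet_mesh.fibres, atol=1e-9)
        np.testing.assert_allclose(
            back.node_fields["uvc_z"], two_tet_mesh.node_fields["uvc_z"]
        )

    def test_round_trip_edge_stats(self, tmp_path):
        """Writing then re-reading a slab leaves the edge statistics intact."""
        from cardioem.synthetic_anatomy import SlabSpec, generate_slab

        slab = generate_slab(SlabSpec(extents=(6, 4, 4), edge_length=1.0))
        write_mesh(slab, tmp_path / "slab.vtk", format="vtk")
        back = read_mesh(tmp_path / "slab.vtk", format="vtk")
        m1, s1, _ = edge_length_stats(slab)
        m2, s2, _ = edge_length_stats(back)
        assert m1 == pytest.approx(m2, rel=1e-12)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_binary_read(self, tmp_path):
        """Big-endian binary legacy files parse to the same mesh."""
        import struct

        nodes = regular_tet()
        tets = np.array([[0, 1, 2, 3]])
        buf = b"# vtk DataFile Version 3.0\nbinary fixture\nBINARY\nDATASET UNSTRUCTURED_GRID\n"
        buf += b"POINTS 4 double\n" + nodes.astype(">f8").tobytes() + b"\n"
        cells = np.array([[4, 0, 1, 2, 3]], dtype=">i4")
        buf += b"CELLS 1 5\n" + cells.tobytes() + b"\n"
        buf += b"CELL_TYPES 1\n" + np.array([10], dtype=">i4").tobytes() + b"\n"
        path = tmp_path / "bin.vtk"
        path.write_bytes(buf)
        mesh = read_mesh(path, format="vtk")
        np.testing.assert_allclose(mesh.nodes, nodes, atol=1e-12)
        np.testing.assert_array_equal(mesh.tets, tets)

    def test_non_tet_cells_rejected(self, tmp_path):
        txt = (
            "# vtk DataFile Version 3.0\nx\nASCII\nDATASET UNSTRUCTURED_GRID\n"
            "POINTS 3 double\n0 0 0\n1 0 0\n0 1 0\n"
            "CELLS 1 4\n3 0 1 2\nCELL_TYPES 1\n5\n"
        )
        (tmp_path / "tri.vtk").write_text(txt)
        with pytest.raises(MeshFormatError, match="non-tetrahedral"):
            read_mesh(tmp_path / "tri.vtk", format="vtk")


class TestScaledJacobian:
    def test_regular_tet_scores_one(self):
        mesh = TetMesh(regular_tet(2.3), np.array([[0, 1, 2, 3]]), np.array([1]))
        sj, summary = scaled_jacobian(mesh)
        assert sj[0] == pytest.approx(1.0, abs=1e-12)
        assert summary["mean"] == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_tet_scores_zero(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 1e-9]], dtype=float)
        mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([1]))
        sj, _ = scaled_jacobian(mesh)
        assert abs(sj[0]) < 1e-6

    def test_matches_direct_formula(self):
        """Independent brute-force evaluation of the normalised Jacobian."""
        rng = np.random.default_rng(7)
        nodes = regular_tet()
        nodes[3, 2] *= 0.5  # squash the apex to half height
        mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([1]))
        sj, _ = scaled_jacobian(mesh)

        def oracle(p):
            best = np.inf
            for v in range(4):
                e = [p[o] - p[v] for o in range(4) if o != v]
                det = abs(np.linalg.det(np.array(e)))
                best = min(best, det / np.prod([np.linalg.norm(x) for x in e]))
            return np.sqrt(2.0) * best

        assert sj[0] == pytest.approx(oracle(nodes), rel=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        angle=st.floats(-np.pi, np.pi),
        scale=st.floats(0.1, 10.0),
        axis_seed=st.integers(0, 10_000),
    )
    def test_rigid_motion_and_scaling_invariance(self, angle, scale, axis_seed):
        rng = np.random.default_rng(axis_seed)
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
        nodes = regular_tet()
        nodes[3] += [0.1, -0.05, 0.2]  # make it irregular
        mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([1]))
        moved = TetMesh(scale * nodes @ R.T + 5.0, mesh.tets.copy(), mesh.elem_tags.copy())
        sj0, _ = scaled_jacobian(mesh)
        sj1, _ = scaled_jacobian(moved)
        assert sj1[0] == pytest.approx(sj0[0], rel=1e-9)


class TestEdgeStats:
    def test_unit_regular_tet(self):
        mesh = TetMesh(regular_tet(), np.array([[0, 1, 2, 3]]), np.array([1]))
        mean, sd, _ = edge_length_stats(mesh)
        assert mean == pytest.approx(1.0, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_hand_enumerated_edges(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([1]))
        mean, _, _ = edge_length_stats(mesh)
        hand = (3 * 1.0 + 3 * np.sqrt(2.0)) / 6.0
        assert mean == pytest.approx(hand, rel=1e-12)

    def test_refinement_halves_mean_edge(self, slab_small):
        m0, _, _ = edge_length_stats(slab_small)
        m1, _, _ = edge_length_stats(uniform_refine(slab_small, 1))
        assert m1 == pytest.approx(m0 / 2, rel=0.01)


class TestUniformRefine:
    def test_single_tet_counts(self):
        mesh = TetMesh(regular_tet(), np.array([[0, 1, 2, 3]]), np.array([3]))
        fine = uniform_refine(mesh, 1)
        assert fine.n_elems == 8
        assert fine.n_nodes == 10
        assert (fine.elem_tags == 3).all()

    def test_volume_preserved_exactly(self, lv_coarse):
        _, mesh, _ = lv_coarse
        fine = uniform_refine(mesh, 1)
        v0 = mesh.volumes().sum()
        v1 = fine.volumes().sum()
        assert v1 == pytest.approx(v0, rel=1e-10)

    def test_two_rounds_quarter_edge(self, slab_small):
        m0, _, _ = edge_length_stats(slab_small)
        m2, _, _ = edge_length_stats(uniform_refine(slab_small, 2))
        assert m2 == pytest.approx(m0 / 4, rel=0.02)

    def test_fields_and_frames_inherited(self, two_tet_mesh):
        fine = uniform_refine(two_tet_mesh, 1)
        assert fine.n_elems == 16
        np.testing.assert_array_equal(fine.elem_tags[:8], np.ones(8))
        np.testing.assert_allclose(fine.fibres, np.tile(DEFAULT_FIBRE, (16, 1)))
        # linear interpolation: midpoint values are endpoint averages
        z = fine.node_fields["uvc_z"]
        edges = unique_edges(two_tet_mesh.tets)
        z0 = two_tet_mesh.node_fields["uvc_z"]
        np.testing.assert_allclose(z[5:], 0.5 * (z0[edges[:, 0]] + z0[edges[:, 1]]))

    def test_negative_rounds_rejected(self, two_tet_mesh):
        with pytest.raises(ValueError):
            uniform_refine(two_tet_mesh, -1)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_volume_preserved_on_random_tets(self, seed):
        rng = np.random.default_rng(seed)
        nodes = rng.uniform(-1, 1, (4, 3))
        vol = np.linalg.det(nodes[1:] - nodes[0]) / 6.0
        if abs(vol) < 1e-3:
            return
        mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([1]))
        fine = uniform_refine(mesh, 1)
        assert fine.volumes().sum() == pytest.approx(abs(vol), rel=1e-12)


class TestBoundaryFaces:
    def test_against_hashing_oracle(self, slab_small):
        faces, owners = boundary_faces(slab_small)
        # oracle: count each sorted face over all tets; boundary = count 1
        from collections import Counter

        counter = Counter()
        for tet in slab_small.tets:
            for f in ([0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]):
                counter[tuple(sorted(tet[f]))] += 1
        oracle = {k for k, v in counter.items() if v == 1}
        ours = {tuple(sorted(f)) for f in faces}
        assert ours == oracle
        assert len(faces) == len(owners)

    def test_outward_orientation(self, slab_small):
        faces, _ = boundary_faces(slab_small)
        n = triangle_normals(slab_small.nodes, faces)
        ctr = slab_small.nodes.mean(axis=0)
        fc = slab_small.nodes[faces].mean(axis=1)
        # a convex box: every outward normal points away from the centroid
        assert (np.einsum("ij,ij->i", n, fc - ctr) > 0).all()


class TestExtractSurfaces:
    def test_single_endo_and_epi_component(self, lv_coarse):
        _, mesh, surfaces = lv_coarse
        assert "lv_endo" in surfaces.surfaces
        assert "epicardium" in surfaces.surfaces
        assert "rv_endo" not in surfaces.surfaces

    def test_base_is_shared_node_set(self, lv_coarse):
        """Base nodes equal the direct intersection of ventricular boundary
        nodes and mitral-plane element nodes."""
        _, mesh, surfaces = lv_coarse
        vent = mesh.elem_tags == 1
        vfaces, _ = boundary_faces(mesh, vent)
        plane_nodes = np.unique(mesh.tets[mesh.elem_tags == 14])
        oracle = np.intersect1d(np.unique(vfaces), plane_nodes)
        np.testing.assert_array_equal(np.sort(surfaces.node_sets["base"]), oracle)
        # base and endocardium are disjoint by construction
        assert np.intersect1d(surfaces.node_sets["base"], surfaces.nodes_of("lv_endo")).size == 0

    def test_endo_normals_face_the_cavity(self, lv_coarse):
        _, mesh, surfaces = lv_coarse
        tri = surfaces.surfaces["lv_endo"]
        n = triangle_normals(mesh.nodes, tri)
        a = triangle_areas(mesh.nodes, tri)
        fc = mesh.nodes[tri].mean(axis=1)
        vols = mesh.volumes()
        vent = mesh.elem_tags == 1
        ctr = (mesh.elem_centroids()[vent] * vols[vent, None]).sum(0) / vols[vent].sum()
        sense = (a * np.einsum("ij,ij->i", n, fc - ctr)).sum() / a.sum()
        assert sense < 0  # outward-of-solid normals point into the cavity

    def test_unknown_tags_rejected(self, two_tet_mesh):
        from cardioem.mesh_core import MeshValidationError

        bad = TetMesh(
            two_tet_mesh.nodes.copy(),
            two_tet_mesh.tets.copy(),
            np.array([1, 99]),
        )
        with pytest.raises(MeshValidationError, match=r"\[99\]"):
            extract_surfaces(bad, LabelSchema.lv_only())


class TestTetMeshInvariants:
    def test_inverted_elements_reoriented_with_warning(self):
        nodes = regular_tet()
        with pytest.warns(UserWarning, match="reoriented"):
            mesh = TetMesh(nodes, np.array([[0, 2, 1, 3]]), np.array([1]))
        assert (tet_volumes(mesh.nodes, mesh.tets) > 0).all()

    def test_out_of_range_indices_rejected(self):
        from cardioem.mesh_core import MeshValidationError

        with pytest.raises(MeshValidationError, match="out of range"):
            TetMesh(regular_tet(), np.array([[0, 1, 2, 9]]), np.array([1]))

    def test_validate_checks_frame_orthonormality(self, two_tet_mesh):
        from cardioem.mesh_core import MeshValidationError

        two_tet_mesh.fibres[0] = [1.0, 0.5, 0.0]  # not unit norm
        with pytest.raises(MeshValidationError, match="unit norm"):
            two_tet_mesh.validate(LabelSchema.lv_only())

    def test_22_tag_meshes_validate_against_24_tag_schema(self):
        schema = LabelSchema.four_chamber()
        present = np.array([1, 2, 3, 4, 14, 15])  # no left pulmonary veins
        schema.validate_tags(present)  # must not raise
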