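"""Mesh data model, I/O, alignment and surface-distance measures."""

import numpy as np
import pytest

from surfwave.icosphere import icosphere
from surfwave.mesh import (MeshFormatError, MeshTopologyError, SurfaceField,
                           TriangleMesh, read_mesh, rigid_align,
                           signed_distance_field, thickness_field,
                           vertex_normals, write_mesh)


def scaled(mesh, factor):
    return TriangleMesh(mesh.vertices * factor, mesh.faces, mesh.name)


class TestIO:
    @pytest.mark.parametrize("fmt", ["off", "ply", "obj"])
    def test_round_trip_preserves_geometry(self, ico2, tmp_path, fmt):
        path = tmp_path / f"mesh.{fmt}"
        write_mesh(scaled(ico2, 80.0), path)
        back = read_mesh(path)
        assert np.abs(back.vertices - ico2.vertices * 80).max() < 1e-9
        assert np.array_equal(back.faces, ico2.faces)

    def test_reads_regular_icosahedron(self, tmp_path):
        mesh = icosphere(0).mesh
        path = write_mesh(mesh, tmp_path / "ico.off")
        back = read_mesh(path)
        assert back.n_vertices == 12
        assert back.n_faces == 20
        assert back.euler_characteristic() == 2

    def test_icosphere2_ply_has_162_vertex_records(self, tmp_path):
        path = write_mesh(icosphere(2).mesh, tmp_path / "s.ply")
        assert "element vertex 162" in path.read_text()

    def test_torus_rejected_as_genus_1(self, torus_mesh, tmp_path):
        v, f = torus_mesh
        # bypass construction-time checks by writing the file directly
        lines = ["OFF", f"{len(v)} {len(f)} 0"]
        lines += [f"{x} {y} {z}" for x, y, z in v]
        lines += [f"3 {a} {b} {c}" for a, b, c in f]
        path = tmp_path / "torus.off"
        path.write_text("\n".join(lines))
        with pytest.raises(MeshTopologyError, match="V-E\\+F=0"):
            read_mesh(path)

    def test_open_surface_rejected(self, ico2, tmp_path):
        lines = ["OFF", f"{ico2.n_vertices} {ico2.n_faces - 1} 0"]
        lines += [f"{x} {y} {z}" for x, y, z in ico2.vertices]
        lines += [f"3 {a} {b} {c}" for a, b, c in ico2.faces[:-1]]
        path = tmp_path / "open.off"
        path.write_text("\n".join(lines))
        with pytest.raises(MeshTopologyError, match="not closed"):
            read_mesh(path)

    def test_degenerate_face_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.5]])
        f = np.array([[0, 1, 2], [0, 1, 2], [1, 0, 3]])
        with pytest.raises(MeshTopologyError):
            TriangleMesh(v, f).validate()

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(MeshFormatError):
            read_mesh(tmp_path / "mesh.stl", fmt="auto")

    def test_empty_mesh_rejected(self):
        with pytest.raises(MeshTopologyError):
            TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))

    def test_field_csv_round_trip(self, ico2, tmp_path):
        rng = np.random.default_rng(0)
        fld = SurfaceField(ico2, rng.normal(size=ico2.n_vertices))
        path = tmp_path / "field.csv"
        fld.to_csv(path)
        back = SurfaceField.from_csv(path, ico2)
        assert np.abs(back.values - fld.values).max() < 1e-12


class TestRigidAlign:
    def test_recovers_rigid_motion_exactly(self, ico2):
        from scipy.spatial.transform import Rotation

        template = scaled(ico2, 80.0)
        rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        subject = TriangleMesh(template.vertices @ rot.T + [5.0, -3.0, 2.0],
                               template.faces)
        aligned = rigid_align(subject, template)
        assert np.abs(aligned.vertices - template.vertices).max() < 1e-6

    def test_identity_when_already_aligned(self, ico2):
        aligned = rigid_align(ico2, ico2)
        assert np.abs(aligned.vertices - ico2.vertices).max() < 1e-12

    def test_topology_mismatch_rejected(self, ico2):
        other = icosphere(1).mesh
        with pytest.raises(MeshTopologyError):
            rigid_align(other, ico2)

    def test_residual_localizes_at_deformation(self):
        from surfwave.synthetic import (DeformationSpec, add_deformation,
                                        make_template, rigid_place)

        template = make_template(level=3, radius=80, bumpiness=0, seed=0)
        spec = DeformationSpec(site="A", amplitude=7.5)
        subject = rigid_place(add_deformation(template, spec), seed=3)
        aligned = rigid_align(subject, template)
        resid = np.linalg.norm(aligned.vertices - template.vertices, axis=1)
        u = template.vertices / np.linalg.norm(template.vertices, axis=1,
                                               keepdims=True)
        angle = np.arccos(np.clip(u @ spec.direction, -1, 1))
        far = angle > np.deg2rad(20)
        near = angle < np.deg2rad(4)
        assert resid[near].max() > 10 * resid[far].max()


class TestSignedDistance:
    def test_zero_for_identical_meshes(self, ico2):
        fld = signed_distance_field(ico2, ico2)
        assert np.abs(fld.values).max() < 1e-12

    def test_concentric_spheres_give_plus_one_mm(self):
        base = icosphere(1).mesh  # symmetric 1-rings -> exactly radial normals
        outer = scaled(base, 100.0)
        fld = signed_distance_field(outer, scaled(base, 101.0))
        assert np.abs(fld.values - 1.0).max() < 1e-6

    def test_indentation_is_negative_and_local(self):
        from surfwave.synthetic import (DeformationSpec, add_deformation,
                                        make_template)

        template = make_template(level=4, radius=80, bumpiness=0, seed=0)
        spec = DeformationSpec(site="A", polarity="indentation", amplitude=7.5)
        fld = signed_distance_field(template, add_deformation(template, spec))
        assert fld.values.min() < -5.0
        assert fld.values.max() < 1e-9
        u = template.vertices / 80.0
        far = np.arccos(np.clip(u @ spec.direction, -1, 1)) > np.deg2rad(15)
        assert np.abs(fld.values[far]).max() < 1e-9

    def test_protrusion_indentation_antisymmetry(self):
        from surfwave.synthetic import (DeformationSpec, add_deformation,
                                        make_template)

        template = make_template(level=3, radius=80, bumpiness=2, seed=1)
        pro = signed_distance_field(template, add_deformation(
            template, DeformationSpec(site="B", polarity="protrusion")))
        ind = signed_distance_field(template, add_deformation(
            template, DeformationSpec(site="B", polarity="indentation")))
        assert np.abs(pro.values + ind.values).max() < 1e-9

    def test_nearest_point_agrees_with_shared_topology(self):
        """On a smooth low-amplitude deformation the two modes agree to
        within 10% of the amplitude."""
        from surfwave.synthetic import (DeformationSpec, add_deformation,
                                        make_template)

        template = make_template(level=3, radius=80, bumpiness=0, seed=0)
        subject = add_deformation(template, DeformationSpec(
            site="A", width=40.0, amplitude=2.0))
        shared = signed_distance_field(template, subject, "shared_topology")
        nearest = signed_distance_field(template, subject, "nearest_point")
        assert np.abs(shared.values - nearest.values).max() < 0.2


class TestThickness:
    def test_concentric_spheres(self, ico2):
        outer = scaled(ico2, 100.0)
        inner = scaled(ico2, 97.0)
        fld = thickness_field(outer, inner)
        assert np.abs(fld.values - 3.0).max() < 1e-3

    def test_zero_for_identical_meshes(self, ico2):
        assert thickness_field(ico2, ico2).values.max() < 1e-12

    def test_shifted_inner_brackets_nominal_gap(self):
        base = icosphere(3).mesh
        outer = TriangleMesh(base.vertices * 100.0, base.faces)
        inner = TriangleMesh(base.vertices * 97.0 + [1.0, 0, 0], base.faces)
        fld = thickness_field(outer, inner)
        assert 1.9 < fld.values.min() < 2.1
        assert 3.9 < fld.values.max() < 4.1

    def test_matches_brute_force_distances(self):
        base = icosphere(1).mesh
        outer = TriangleMesh(base.vertices * 10.0, base.faces)
        inner = TriangleMesh(base.vertices * 9.0 + [0.5, -0.2, 0.1],
                             base.faces)
        fld = thickness_field(outer, inner)
        # brute force: exact distance to every triangle
        from surfwave.mesh import _point_triangle_distance
        tri = inner.vertices[inner.faces]
        brute = _point_triangle_distance(outer.vertices, tri).min(axis=1)
        assert np.abs(fld.values - brute).max() < 1e-12

    def test_invariant_under_common_rigid_motion(self, ico2):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        t = np.array([3.0, -1.0, 7.0])
        outer = scaled(ico2, 100.0)
        inner = TriangleMesh(ico2.vertices * 97.0 + [1, 0, 0], ico2.faces)
        ref = thickness_field(outer, inner).values
        moved = thickness_field(
            TriangleMesh(outer.vertices @ rot.T + t, outer.faces),
            TriangleMesh(inner.vertices @ rot.T + t, inner.faces)).values
        assert np.abs(ref - moved).max() < 1e-6

    def test_empty_inner_rejected(self, ico2):
        with pytest.raises(MeshTopologyError):
            TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))


class TestNormalsAndFields:
    def test_normals_point_outward(self, ico3):
        n = vertex_normals(ico3)
        assert np.all(np.einsum("ij,ij->i", n, ico3.vertices) > 0.9)

    def test_field_length_mismatch_rejected(self, ico2):
        with pytest.raises(ValueError):
            SurfaceField(ico2, np.zeros(7))

    def test_non_finite_field_rejected(self, ico2):
        vals = np.zeros(ico2.n_vertices)
        vals[0] = np.nan
        with pytest.raises(ValueError):
            SurfaceField(ico2, vals)
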