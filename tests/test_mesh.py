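"""Geometric primitives: areas, volumes, loops, repair, segmentation."""

import math

import numpy as np
import pytest

from coralmorph.mesh import (
    LIVING,
    NONLIVING_CONTACT,
    BACKGROUND,
    DegenerateFaceWarning,
    EmptySelectionError,
    FaceLabelMask,
    Mesh,
    MeshStructureError,
    NotWatertightError,
    ObjParseError,
    boundary_loops,
    enclosed_volume,
    fill_holes_flat,
    read_obj,
    segment,
    surface_area,
    write_obj,
)
from conftest import CUBE_FACES, CUBE_VERTS, icosphere, uv_hemisphere_shell


class TestObjIO:
    def test_cube_roundtrip_counts(self, cube, tmp_path):
        p = tmp_path / "cube.obj"
        write_obj(cube, p)
        m = read_obj(p)
        assert m.n_vertices == 8
        assert m.n_faces == 12
        np.testing.assert_allclose(m.vertices, cube.vertices, atol=1e-9)
        assert np.array_equal(m.faces, cube.faces)

    def test_quad_fan_triangulated(self, tmp_path):
        p = tmp_path / "quad.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n")
        m = read_obj(p)
        assert m.n_faces == 2
        # both triangles share the quad's diagonal (vertices 0 and 2)
        shared = set(m.faces[0]) & set(m.faces[1])
        assert shared == {0, 2}

    def test_negative_indices(self, tmp_path):
        p = tmp_path / "neg.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf -3 -2 -1\n")
        m = read_obj(p)
        assert np.array_equal(m.faces, [[0, 1, 2]])

    def test_materials_ignored(self, tmp_path):
        p = tmp_path / "mtl.obj"
        p.write_text("mtllib x.mtl\nusemtl skin\nv 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        assert read_obj(p).n_faces == 1

    def test_malformed_face_names_line(self, tmp_path):
        p = tmp_path / "bad.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 oops\n")
        with pytest.raises(ObjParseError, match=":4"):
            read_obj(p)

    def test_face_index_out_of_range(self, tmp_path):
        p = tmp_path / "oob.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 9\n")
        with pytest.raises(MeshStructureError):
            read_obj(p)

    def test_write_is_byte_stable(self, cube, tmp_path):
        a, b = tmp_path / "a.obj", tmp_path / "b.obj"
        write_obj(cube, a)
        write_obj(cube, b)
        assert a.read_bytes() == b.read_bytes()


class TestSurfaceArea:
    def test_unit_cube(self, cube):
        assert surface_area(cube) == pytest.approx(6.0)

    def test_masked_cube_excludes_nonliving(self, cube):
        labels = np.full(12, LIVING, object)
        labels[[2, 3]] = NONLIVING_CONTACT  # one full side
        mask = FaceLabelMask(labels)
        assert surface_area(cube, mask, {LIVING}) == pytest.approx(5.0)
        assert surface_area(cube, mask, {LIVING, NONLIVING_CONTACT}) == pytest.approx(6.0)

    def test_icosphere_approaches_sphere_area(self):
        sph = icosphere(radius=1.0, subdivisions=5)
        assert surface_area(sph) == pytest.approx(4 * math.pi, rel=1e-3)

    def test_degenerate_faces_warn_and_contribute_zero(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [2, 0, 0]], float)
        f = np.array([[0, 1, 2], [0, 1, 3]])  # second face is collinear
        with pytest.warns(DegenerateFaceWarning):
            a = surface_area(Mesh(v, f, units="cm"))
        assert a == pytest.approx(0.5)

    @pytest.mark.parametrize("s", [0.1, 2.5, 23.0])
    def test_area_scales_quadratically(self, cube, s):
        assert surface_area(cube.scaled(s)) == pytest.approx(
            s**2 * surface_area(cube), rel=1e-9
        )

    def test_esa_never_exceeds_tsa(self):
        rng = np.random.default_rng(11)
        sph = icosphere(1.0, 3)
        labels = rng.choice([LIVING, NONLIVING_CONTACT, BACKGROUND], sph.n_faces)
        mask = FaceLabelMask(labels.astype(object))
        esa = surface_area(sph, mask, {LIVING})
        assert esa <= surface_area(sph)
        all_living = FaceLabelMask.uniform(sph.n_faces, LIVING)
        assert surface_area(sph, all_living, {LIVING}) == surface_area(sph)


class TestEnclosedVolume:
    def test_unit_cube(self, cube):
        assert enclosed_volume(cube) == pytest.approx(1.0)

    def test_translation_invariance(self, cube):
        moved = cube.translated([1000.0, -500.0, 3.0])
        assert enclosed_volume(moved) == pytest.approx(1.0, rel=1e-9)

    def test_rotation_invariance(self, cube):
        th = 0.7
        R = np.array(
            [[math.cos(th), -math.sin(th), 0], [math.sin(th), math.cos(th), 0], [0, 0, 1]]
        )
        assert enclosed_volume(cube.transformed(R, [3, -2, 11])) == pytest.approx(
            1.0, rel=1e-9
        )

    @pytest.mark.parametrize("s", [0.1, 2.5, 23.0])
    def test_volume_scales_cubically(self, cube, s):
        assert enclosed_volume(cube.scaled(s)) == pytest.approx(s**3, rel=1e-9)

    def test_icosphere_volume(self):
        sph = icosphere(radius=2.0, subdivisions=5)
        assert enclosed_volume(sph) == pytest.approx(4 / 3 * math.pi * 8, rel=2e-3)

    def test_open_mesh_refused(self, open_cube):
        with pytest.raises(NotWatertightError):
            enclosed_volume(open_cube)

    def test_inconsistent_winding_repaired(self, cube):
        f = cube.faces.copy()
        f[5] = f[5, ::-1]
        f[9] = f[9, ::-1]
        scrambled = Mesh(cube.vertices, f, units="cm")
        assert enclosed_volume(scrambled) == pytest.approx(1.0)

    def test_matches_trimesh_on_synthetic_colony(self):
        """Dual route: our divergence-theorem volume and area against an
        independent mesh library on the same colony."""
        import trimesh

        from coralmorph.synthetic import SyntheticColonySpec, make_colony
        from coralmorph.mesh import segment as seg

        col = make_colony(SyntheticColonySpec("massive", 4.0, 3, 0))
        sub, _ = seg(col.mesh, col.mask, {LIVING, NONLIVING_CONTACT})
        tm = trimesh.Trimesh(vertices=sub.vertices, faces=sub.faces, process=False)
        assert surface_area(sub) == pytest.approx(tm.area, rel=1e-9)
        assert enclosed_volume(sub) == pytest.approx(abs(tm.volume), rel=1e-9)

    def test_icosphere_convergence_monotone(self):
        sa_err, v_err = [], []
        for sub in range(2, 6):
            sph = icosphere(1.0, sub)
            sa_err.append(abs(surface_area(sph) - 4 * math.pi))
            v_err.append(abs(enclosed_volume(sph) - 4 / 3 * math.pi))
        assert all(a > b for a, b in zip(sa_err, sa_err[1:]))
        assert all(a > b for a, b in zip(v_err, v_err[1:]))


class TestBoundaryLoopsAndFill:
    def test_closed_cube_has_no_loops(self, cube):
        assert boundary_loops(cube) == []

    def test_single_square_hole(self, open_cube):
        loops = boundary_loops(open_cube)
        assert len(loops) == 1
        assert sorted(loops[0]) == [4, 5, 6, 7]

    def test_nonmanifold_edge_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0]], float)
        f = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])  # edge (0,1) x3
        with pytest.raises(MeshStructureError, match="non-manifold"):
            boundary_loops(Mesh(v, f, units="cm"))

    def test_three_punched_holes(self):
        sph = icosphere(1.0, 3)
        # remove three well-separated faces
        drop = [0, sph.n_faces // 2, sph.n_faces - 1]
        keep = np.ones(sph.n_faces, bool)
        keep[drop] = False
        holed = Mesh(sph.vertices, sph.faces[keep], units="cm")
        assert len(boundary_loops(holed)) == 3

    def test_fill_watertight_cube_noop(self, cube):
        filled, added = fill_holes_flat(cube)
        assert added == []
        assert filled is cube

    def test_fill_open_cube_restores_volume(self, open_cube):
        filled, added = fill_holes_flat(open_cube)
        assert len(added) > 0
        assert boundary_loops(filled) == []
        assert enclosed_volume(filled) == pytest.approx(1.0)

    def test_fill_hemisphere_shell(self):
        shell = uv_hemisphere_shell(radius=1.0)
        with pytest.raises(NotWatertightError):
            enclosed_volume(shell)
        filled, added = fill_holes_flat(shell)
        assert enclosed_volume(filled) == pytest.approx(2 / 3 * math.pi, rel=5e-3)

    def test_fill_idempotent(self, open_cube):
        once, _ = fill_holes_flat(open_cube)
        twice, added = fill_holes_flat(once)
        assert added == []
        assert np.array_equal(once.faces, twice.faces)
        np.testing.assert_array_equal(once.vertices, twice.vertices)


class TestSegment:
    @pytest.fixture
    def labelled_sphere(self):
        sph = icosphere(1.0, 3)
        labels = np.full(sph.n_faces, LIVING, object)
        labels[: sph.n_faces // 4] = BACKGROUND
        labels[sph.n_faces // 4 : sph.n_faces // 3] = NONLIVING_CONTACT
        return sph, FaceLabelMask(labels)

    def test_colony_extraction_drops_background(self, labelled_sphere):
        sph, mask = labelled_sphere
        sub, fmap = segment(sph, mask, {LIVING, NONLIVING_CONTACT})
        n_bg = int((mask.labels == BACKGROUND).sum())
        assert sub.n_faces == sph.n_faces - n_bg
        assert len(fmap) == sub.n_faces

    def test_identity_when_all_classes(self, labelled_sphere):
        sph, mask = labelled_sphere
        sub, _ = segment(sph, mask, {LIVING, NONLIVING_CONTACT, BACKGROUND})
        assert sub.n_faces == sph.n_faces
        assert surface_area(sub) == pytest.approx(surface_area(sph), rel=1e-12)

    def test_segment_area_equals_masked_area(self, labelled_sphere):
        sph, mask = labelled_sphere
        sub, _ = segment(sph, mask, {LIVING})
        assert surface_area(sub) == pytest.approx(
            surface_area(sph, mask, {LIVING}), rel=1e-12
        )

    def test_empty_selection_raises(self, cube):
        mask = FaceLabelMask.uniform(cube.n_faces, LIVING)
        with pytest.raises(EmptySelectionError):
            segment(cube, mask, {BACKGROUND})

    def test_mask_csv_roundtrip(self, cube, tmp_path):
        labels = np.full(12, LIVING, object)
        labels[[0, 1]] = BACKGROUND
        mask = FaceLabelMask(labels)
        p = tmp_path / "mask.csv"
        mask.to_csv(p)
        back = FaceLabelMask.from_csv(p, n_faces=12)
        assert list(back.labels) == list(mask.labels)
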