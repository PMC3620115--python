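"""Mesh generators, scene validation and ray-query tests."""

import numpy as np
import pytest

from photonmc.geometry import (
    FACE_LABELS,
    Region,
    Scene,
    SurfaceMesh,
    brute_force_intersection,
    face_grid_index,
    first_intersection,
    locate_region,
    make_cube_phantom,
    make_ellipsoid_mesh,
    make_sphere_mesh,
)
from photonmc.optics import OpticalProperties

PROPS = OpticalProperties(0.01, 1.0, 0.5, 1.37)


class TestCubePhantom:
    def test_basic_counts_and_volume(self):
        m = make_cube_phantom(10.0, 1)
        assert len(m.vertices) == 8
        assert len(m.faces) == 12
        assert m.signed_volume() == pytest.approx(1000.0)

    def test_unit_cube_outward_orientation(self):
        assert make_cube_phantom(1.0, 1).signed_volume() == pytest.approx(1.0)

    def test_subdivision_preserves_volume(self):
        m = make_cube_phantom(10.0, 3)
        assert len(m.faces) == 12 * 9
        assert m.signed_volume() == pytest.approx(1000.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            make_cube_phantom(-1.0)
        with pytest.raises(ValueError):
            make_cube_phantom(1.0, 0)


class TestEllipsoid:
    def test_sphere_volume_converges(self):
        m = make_ellipsoid_mesh((1, 1, 1), refinement=4)
        assert m.signed_volume() == pytest.approx(4 / 3 * np.pi, rel=0.01)

    def test_bounding_box_matches_semi_axes(self):
        m = make_ellipsoid_mesh((1, 2, 3), refinement=2)
        lo, hi = m.aabb
        np.testing.assert_allclose(lo, [-1, -2, -3], atol=1e-9)
        np.testing.assert_allclose(hi, [1, 2, 3], atol=1e-9)

    def test_translation(self):
        m = make_sphere_mesh(1.0, center=(5, 0, 0), refinement=2)
        np.testing.assert_allclose(m.vertices.mean(axis=0), [5, 0, 0], atol=1e-9)

    def test_invalid_axis(self):
        with pytest.raises(ValueError):
            make_ellipsoid_mesh((1, -1, 1))


class TestMeshValidation:
    def test_open_mesh_rejected(self):
        cube = make_cube_phantom(1.0)
        with pytest.raises(ValueError, match="closed"):
            SurfaceMesh(cube.vertices, cube.faces[:-1])

    def test_inward_orientation_rejected(self):
        cube = make_cube_phantom(1.0)
        with pytest.raises(ValueError):
            SurfaceMesh(cube.vertices, cube.faces[:, ::-1])

    def test_degenerate_triangle_rejected(self):
        cube = make_cube_phantom(1.0)
        faces = cube.faces.copy()
        faces[0, 1] = faces[0, 0]
        with pytest.raises(ValueError, match="degenerate"):
            SurfaceMesh(cube.vertices, faces)

    @pytest.mark.parametrize("suffix", [".stl", ".ply", ".off"])
    def test_file_roundtrip(self, tmp_path, suffix):
        m = make_sphere_mesh(2.0, refinement=1)
        path = str(tmp_path / ("mesh" + suffix))
        m.save(path)
        loaded = SurfaceMesh.load(path)
        assert loaded.signed_volume() == pytest.approx(m.signed_volume(), rel=1e-6)


class TestWatertightness:
    def test_crossing_parity(self, rng):
        """Rays from interior points cross a closed surface an odd number of
        times; from exterior points an even number."""
        mesh = make_ellipsoid_mesh((2, 1.5, 1), refinement=2)
        tri = mesh.vertices[mesh.faces]
        from photonmc.geometry import _moller_trumbore

        for _ in range(100):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            inside_pt = rng.uniform(-0.3, 0.3, size=3)
            outside_pt = rng.uniform(3.0, 5.0, size=3)
            _, hits_in = _moller_trumbore(inside_pt, d, tri)
            _, hits_out = _moller_trumbore(outside_pt, d, tri)
            assert int(hits_in.sum()) % 2 == 1
            assert int(hits_out.sum()) % 2 == 0


class TestSceneValidation:
    def test_child_outside_parent_rejected(self):
        cube = make_cube_phantom(4.0)
        ball = make_sphere_mesh(1.0, center=(10, 0, 0), refinement=1)
        with pytest.raises(ValueError, match="contained"):
            Scene([Region("cube", cube, PROPS), Region("ball", ball, PROPS, parent="cube")])

    def test_two_roots_rejected(self):
        a = make_sphere_mesh(1.0, center=(0, 0, 0), refinement=1)
        b = make_sphere_mesh(1.0, center=(5, 0, 0), refinement=1)
        with pytest.raises(ValueError, match="outermost"):
            Scene([Region("a", a, PROPS), Region("b", b, PROPS)])

    def test_overlapping_siblings_rejected(self):
        cube = make_cube_phantom(10.0)
        a = make_sphere_mesh(1.5, center=(-0.5, 0, 0), refinement=1)
        b = make_sphere_mesh(1.5, center=(0.5, 0, 0), refinement=1)
        with pytest.raises(ValueError, match="intersect"):
            Scene(
                [
                    Region("cube", cube, PROPS),
                    Region("a", a, PROPS, parent="cube"),
                    Region("b", b, PROPS, parent="cube"),
                ]
            )


class TestFirstIntersection:
    def test_inside_cube_to_ambient(self, cube_scene):
        hit = first_intersection((0, 0, 0), (1, 0, 0), cube_scene)
        assert hit.distance == pytest.approx(5.0, abs=1e-12)
        assert hit.region_from == "cube"
        assert hit.region_to is None

    def test_max_dist_cap(self, cube_scene):
        assert first_intersection((0, 0, 0), (1, 0, 0), cube_scene, max_dist=2.0) is None

    def test_nested_sphere_entry(self, nested_scene):
        hit = first_intersection((-5 + 1e-6, 0, 0), (1, 0, 0), nested_scene)
        assert hit.region_from == "cube"
        assert hit.region_to == "core"
        # icosphere chord: slightly under the analytic radius 1
        assert hit.distance == pytest.approx(4.0, abs=0.05)

    def test_zero_direction_rejected(self, cube_scene):
        with pytest.raises(ValueError):
            first_intersection((0, 0, 0), (0, 0, 0), cube_scene)

    def test_matches_brute_force_oracle(self, nested_scene, rng):
        """Culled intersection equals the all-triangle scan: same triangle,
        distance to 1e-9 mm, over randomized rays inside and around the scene."""
        compiled = nested_scene.compile()
        for _ in range(2000):
            origin = rng.uniform(-8, 8, size=3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            expected = brute_force_intersection(origin, d, compiled)
            got = first_intersection(origin, d, compiled)
            if expected is None:
                assert got is None
            else:
                assert got.triangle_id == expected[0]
                assert got.distance == pytest.approx(expected[1], abs=1e-9)

    def test_kernel_intersection_matches_python(self, nested_scene, rng):
        """The compiled kernel's nearest-hit agrees with the python query."""
        from photonmc import _kernel

        c = nested_scene.compile()
        for _ in range(300):
            origin = rng.uniform(-6, 6, size=3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            tri_k, t_k = _kernel._nearest_hit(
                origin[0], origin[1], origin[2], d[0], d[1], d[2], 1e30,
                c.v0, c.v1, c.v2, c.reg_bb_min, c.reg_bb_max,
                c.reg_tri_start, c.reg_tri_end,
            )
            hit = first_intersection(origin, d, c)
            if hit is None:
                assert tri_k == -1
            else:
                assert tri_k == hit.triangle_id
                assert t_k == pytest.approx(hit.distance, abs=1e-12)


class TestLocateRegion:
    def test_inside_outside(self, cube_scene):
        assert locate_region((0, 0, 0), cube_scene) == "cube"
        assert locate_region((20, 0, 0), cube_scene) is None

    def test_nested_innermost_wins(self, nested_scene):
        assert locate_region((0, 0, 0), nested_scene) == "core"
        assert locate_region((3, 0, 0), nested_scene) == "cube"


class TestFaceGridIndex:
    BOX = (np.array([-5.0, -5.0, -5.0]), np.array([5.0, 5.0, 5.0]))

    def test_face_center(self):
        row, col = face_grid_index((0, 0, 5.0), "+z", (300, 300), *self.BOX)
        assert (row, col) == (150, 150)

    def test_minimal_corner(self):
        assert face_grid_index((-5, -5, 5.0), "+z", (300, 300), *self.BOX) == (0, 0)

    def test_opposite_extremes(self):
        row, col = face_grid_index((5 - 1e-9, -5 + 1e-9, 5.0), "+z", (300, 300), *self.BOX)
        assert (row, col) == (299, 0)

    def test_off_face_rejected(self):
        with pytest.raises(ValueError):
            face_grid_index((0, 0, 4.0), "+z", (300, 300), *self.BOX)

    def test_matches_kernel_binning(self, rng):
        from photonmc import _kernel

        lo, hi = self.BOX
        for _ in range(200):
            face = int(rng.integers(0, 6))
            axis, positive = divmod(face, 2)
            p = rng.uniform(-5, 5, size=3)
            p[axis] = hi[axis] if positive else lo[axis]
            normal = np.zeros(3)
            normal[axis] = 1.0 if positive else -1.0
            f_k, r_k, c_k = _kernel._face_bins(
                p[0], p[1], p[2], normal[0], normal[1], normal[2], lo, hi, 300, 300
            )
            r_p, c_p = face_grid_index(p, FACE_LABELS[face], (300, 300), lo, hi)
            assert (f_k, r_k, c_k) == (face, r_p, c_p)
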