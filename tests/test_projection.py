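"""Virtual scene construction, silhouette extraction, rasterization, cost."""

import numpy as np
import pytest
from scipy import ndimage

from kneedea.geometry import TriangleSurface, ValidationError
from kneedea.phantom import icosphere, uv_sphere
from kneedea.projection import (
    EdgeImage,
    build_scene,
    contour_cost,
    extract_silhouette_edges,
    project_to_detector,
    rasterize_contour,
    render_silhouette,
)

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


class TestSceneConstruction:
    def test_source_sits_at_sdd_from_detector(self):
        scene = build_scene()
        assert np.linalg.norm(scene.source_point - scene.detector_center) == pytest.approx(
            1828.8, abs=1e-9
        )

    @pytest.mark.parametrize("angle", [5.0, 10.0, 15.0])
    def test_central_ray_makes_caudal_angle_with_normal(self, angle):
        scene = build_scene(caudal_angle=angle)
        cosang = abs(scene.central_ray @ scene.detector_normal)
        assert np.degrees(np.arccos(cosang)) == pytest.approx(angle, abs=1e-9)

    def test_zero_angle_override_gives_perpendicular_beam(self):
        scene = build_scene(caudal_angle=0, allow_nonstandard_angle=True)
        np.testing.assert_allclose(scene.central_ray, [0, 0, -1], atol=1e-12)

    def test_nonstandard_angle_rejected_without_override(self):
        with pytest.raises(ValidationError):
            build_scene(caudal_angle=7.0)

    @pytest.mark.parametrize(
        "kw",
        [
            {"source_detector_distance": -1.0},
            {"pixel_spacing": 0.0},
            {"image_size": (0, 100)},
            {"object_detector_distance": -5.0},
        ],
    )
    def test_nonpositive_dimensions_rejected(self, kw):
        with pytest.raises(ValidationError):
            build_scene(**kw)

    def test_detector_is_two_adjacent_coplanar_polygons(self):
        scene = build_scene()
        polys = scene.detector_polygons
        assert len(polys) == 2
        for p in polys:
            assert np.allclose(p[:, 2], 0.0)


class TestProjection:
    def test_similar_triangles_hand_calculation(self):
        scene = build_scene(caudal_angle=0, allow_nonstandard_angle=True)
        uv = project_to_detector([[10.0, 0.0, 100.0]], scene)
        assert uv[0, 0] == pytest.approx(10 * 1828.8 / 1728.8, abs=1e-9)
        assert uv[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_point_on_detector_plane_projects_to_itself(self):
        scene = build_scene()
        uv = project_to_detector([[13.0, -4.0, 0.0]], scene)
        np.testing.assert_allclose(uv[0], [13.0, -4.0], atol=1e-9)

    def test_points_on_central_ray_share_one_image_point(self):
        scene = build_scene(caudal_angle=10)
        src, ctr = scene.source_point, scene.detector_center
        pts = [src + t * (ctr - src) for t in (0.3, 0.6, 0.9)]
        uv = project_to_detector(pts, scene)
        np.testing.assert_allclose(uv, np.zeros((3, 2)), atol=1e-9)

    def test_point_at_source_rejected(self):
        scene = build_scene()
        with pytest.raises(ValidationError):
            project_to_detector([scene.source_point], scene)

    def test_ray_parallel_to_detector_excluded_with_warning(self):
        scene = build_scene(caudal_angle=0, allow_nonstandard_angle=True)
        with pytest.warns(UserWarning, match="parallel"):
            uv = project_to_detector(
                [[5.0, 0.0, scene.source_point[2]], [1.0, 1.0, 100.0]], scene
            )
        assert len(uv) == 1

    def test_magnification_follows_similar_triangles(self):
        # ruler at object-detector distance d magnified by SDD/(SDD-d)
        scene = build_scene(caudal_angle=0, allow_nonstandard_angle=True)
        d = 250.0
        ticks = np.column_stack(
            [np.linspace(-30, 30, 7), np.zeros(7), np.full(7, d)]
        )
        uv = project_to_detector(ticks, scene)
        mag = 1828.8 / (1828.8 - d)
        np.testing.assert_allclose(uv[:, 0], ticks[:, 0] * mag, rtol=1e-12)


class TestSilhouette:
    def test_isolated_triangle_returns_all_boundary_edges(self):
        s = TriangleSurface(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float), np.array([[0, 1, 2]])
        )
        edges = extract_silhouette_edges(s, [0, 0, 100.0])
        assert len(edges) == 3

    def test_sphere_silhouette_is_one_closed_loop(self):
        sphere = icosphere(10.0, subdivisions=3)
        edges = extract_silhouette_edges(sphere, [0, 0, 1000.0])
        # every vertex on the loop has degree 2 and the loop is connected
        verts, counts = np.unique(edges, return_counts=True)
        assert np.all(counts == 2)
        import networkx as nx  # available in the test environment

        g = nx.Graph(edges.tolist())
        assert nx.is_connected(g)

    def test_cube_silhouette_matches_brute_force_sign_oracle(self):
        v = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
        )
        faces = []
        for axis in range(3):
            for side in (0, 1):
                ids = [i for i in range(8) if v[i, axis] == side]
                a, b, c, d = ids
                quads = [[a, b, d], [a, d, c]] if side else [[a, d, b], [a, c, d]]
                faces += quads
        cube = TriangleSurface(v, np.array(faces))
        if cube.signed_volume < 0:
            cube = TriangleSurface(v, np.array(faces)[:, ::-1])
        src = np.array([0.5, 0.5, 500.0])
        edges = extract_silhouette_edges(cube, src)

        # brute-force per-edge sign test
        expected = set()
        facing = np.einsum(
            "ij,ij->i", cube.face_normals, cube.face_centroids - src
        )
        from collections import defaultdict

        incident = defaultdict(list)
        for fi, f in enumerate(cube.faces):
            for e in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                incident[tuple(sorted(e))].append(fi)
        for e, fs in incident.items():
            if len(fs) == 1 or np.sign(facing[fs[0]]) != np.sign(facing[fs[1]]):
                expected.add(e)
        got = {tuple(sorted(e)) for e in edges.tolist()}
        assert got == expected
        # and the silhouette projects onto the outline square z in {0,1}
        for a, b in got:
            assert v[a, 0] == v[b, 0] or v[a, 1] == v[b, 1]

    def test_empty_surface_rejected(self):
        s = TriangleSurface(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValidationError):
            extract_silhouette_edges(s, [0, 0, 100.0])

    def test_convex_body_silhouette_is_convex_outline(self):
        # at zero caudal angle a sphere projects to a circle: foreground
        # pixels deviate from their convex hull by less than one pixel
        from scipy.spatial import ConvexHull, Delaunay

        scene = build_scene(
            caudal_angle=0, allow_nonstandard_angle=True, image_size=(256, 256),
            pixel_spacing=0.4,
        )
        sphere = icosphere(15.0, center=(0, 0, 100.0), subdivisions=3)
        img = render_silhouette(sphere, scene)
        px = img.foreground_pixels.astype(float)
        hull = Delaunay(px[ConvexHull(px).vertices])
        # every foreground pixel lies within the hull grown by 1 px
        dil = hull.find_simplex(px) >= 0
        assert np.mean(dil) > 0.99


class TestRasterization:
    def test_horizontal_run_pixel_count(self):
        scene = build_scene(image_size=(64, 64), pixel_spacing=1.0)
        img = rasterize_contour(np.array([[-5.0, 0.0], [5.0, 0.0]]), scene)
        assert img.n_foreground in (10, 11)
        rows = np.unique(img.foreground_pixels[:, 0])
        assert len(rows) == 1

    def test_square_outline_is_single_connected_component(self):
        scene = build_scene(image_size=(128, 128), pixel_spacing=0.5)
        square = np.array([[-10, -10], [10, -10], [10, 10], [-10, 10]], float)
        img = rasterize_contour(square, scene, close=True)
        _, n = ndimage.label(img.pixels, structure=EIGHT_CONNECTED)
        assert n == 1

    def test_degenerate_repeated_point_yields_single_pixel(self):
        scene = build_scene(image_size=(64, 64), pixel_spacing=1.0)
        img = rasterize_contour(np.array([[3.0, 3.0], [3.0, 3.0]]), scene)
        assert img.n_foreground == 1

    def test_all_points_outside_image_rejected(self):
        scene = build_scene(image_size=(32, 32), pixel_spacing=0.1)
        with pytest.raises(ValidationError, match="bounds"):
            rasterize_contour(np.array([[500.0, 500.0], [600.0, 600.0]]), scene)

    def test_single_point_contour_rejected(self):
        scene = build_scene(image_size=(32, 32), pixel_spacing=0.1)
        with pytest.raises(ValidationError):
            rasterize_contour(np.array([[0.0, 0.0]]), scene)


class TestContourCost:
    def _image(self, pixels, spacing=0.2):
        return EdgeImage(pixels, spacing)

    def test_identical_images_have_zero_cost(self, femur_edges):
        assert contour_cost(femur_edges, femur_edges) == 0.0

    def test_cost_is_symmetric(self):
        rng = np.random.default_rng(3)
        a = np.zeros((64, 64), bool)
        b = np.zeros((64, 64), bool)
        a[rng.integers(0, 64, 40), rng.integers(0, 64, 40)] = True
        b[rng.integers(0, 64, 40), rng.integers(0, 64, 40)] = True
        assert contour_cost(self._image(a), self._image(b)) == pytest.approx(
            contour_cost(self._image(b), self._image(a)), abs=1e-12
        )

    def test_one_pixel_shift_matches_brute_force(self):
        # an interior contour shifted by 1 px at 0.2 mm spacing costs ~0.2 mm
        a = np.zeros((64, 64), bool)
        a[20:40, 30] = True
        b = np.zeros((64, 64), bool)
        b[20:40, 31] = True
        cost = contour_cost(self._image(a), self._image(b))

        # brute-force nearest-foreground search
        pa = np.argwhere(a)
        pb = np.argwhere(b)
        d_ab = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2).min(1).mean()
        d_ba = np.linalg.norm(pb[:, None, :] - pa[None, :, :], axis=2).min(1).mean()
        expected = (d_ab + d_ba) * 0.2
        assert cost == pytest.approx(expected, abs=1e-12)
        assert cost == pytest.approx(0.4, abs=1e-6)  # 0.2 mm each way

    def test_cost_decreases_toward_ground_truth(self):
        scene = build_scene(
            caudal_angle=0, allow_nonstandard_angle=True, image_size=(256, 256),
            pixel_spacing=0.4,
        )
        sphere = icosphere(15.0, center=(0, 0, 100.0), subdivisions=3)
        truth = render_silhouette(sphere, scene)
        shifts = np.linspace(8.0, 0.0, 10)
        costs = []
        for dx in shifts:
            moved = sphere.replace(vertices=sphere.vertices + [dx, 0, 0])
            costs.append(contour_cost(render_silhouette(moved, scene), truth))
        assert all(np.diff(costs) < 0)
        assert costs[-1] == 0.0

    def test_empty_image_rejected(self, femur_edges):
        empty = EdgeImage(np.zeros((512, 512), bool), femur_edges.pixel_spacing)
        with pytest.raises(ValidationError):
            contour_cost(empty, femur_edges)

    def test_mismatched_grids_rejected(self, femur_edges):
        other = EdgeImage(np.ones((16, 16), bool), femur_edges.pixel_spacing)
        with pytest.raises(ValidationError):
            contour_cost(other, femur_edges)


class TestEdgeImageIO:
    def test_png_roundtrip_with_sidecar(self, tmp_path, femur_edges):
        path = tmp_path / "edges.png"
        femur_edges.save(path)
        assert path.exists() and path.with_suffix(".png.json").exists()
        loaded = EdgeImage.load(path)
        assert np.array_equal(loaded.pixels, femur_edges.pixels)
        assert loaded.pixel_spacing == femur_edges.pixel_spacing
        assert loaded.provenance == femur_edges.provenance

    def test_nonbinary_image_rejected(self):
        with pytest.raises(ValidationError):
            EdgeImage(np.arange(16).reshape(4, 4), 0.2)
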