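"""Discrete element analysis: spring law, pairing, load-control solve."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kneedea.dea import (
    CompartmentMetrics,
    ContactStressField,
    DEAMaterialParams,
    EquilibriumError,
    SpringSet,
    compartment_metrics,
    contact_force,
    find_contact_pairs,
    solve_equilibrium,
    spring_deformation,
    spring_stress,
)
from kneedea.experiments import flat_plate
from kneedea.geometry import RigidPose, TriangleSurface
from kneedea.phantom import conforming_phantom_spec, generate_knee_phantom, uv_sphere

# E(1-nu)/((1+nu)(1-2nu)) at E=12, nu=0.42, evaluated by hand
CONFINED_MODULUS = 12 * (1 - 0.42) / ((1 + 0.42) * (1 - 2 * 0.42))


class TestMaterialParams:
    def test_default_confined_modulus(self):
        p = DEAMaterialParams()
        assert p.confined_modulus == pytest.approx(30.63380281690141, abs=1e-10)
        assert p.foundation_stiffness == pytest.approx(CONFINED_MODULUS / 6, rel=1e-12)

    @pytest.mark.parametrize("nu", [0.5, 0.6, 0.0, -0.1])
    def test_poisson_ratio_outside_open_interval_rejected(self, nu):
        from kneedea.geometry import ValidationError

        with pytest.raises(ValidationError):
            DEAMaterialParams(nu=nu)


class TestSpringLaw:
    def test_deformation_cases(self):
        t = 6.0
        assert spring_deformation(6.0, t) == 0.0          # just-touching
        assert spring_deformation(5.7, t) == pytest.approx(0.3)
        assert spring_deformation(7.0, t) == 0.0          # tension never modelled
        assert spring_deformation(-0.5, t) == pytest.approx(6.5)  # overlap

    def test_stress_closed_form(self):
        p = DEAMaterialParams()
        assert spring_stress(0.0, p) == 0.0
        expected = CONFINED_MODULUS * 0.3 / 6.0
        assert spring_stress(0.3, p) == pytest.approx(expected, rel=1e-12)
        assert spring_stress(0.3, p) == pytest.approx(1.5317, abs=1e-4)

    def test_stress_is_linear(self):
        p = DEAMaterialParams()
        assert spring_stress(0.6, p) == pytest.approx(2 * spring_stress(0.3, p))

    def test_negative_deformation_rejected(self):
        from kneedea.geometry import ValidationError

        with pytest.raises(ValidationError):
            spring_stress(-0.1, DEAMaterialParams())


class TestContactForce:
    def _springs(self, n, directions, areas):
        return SpringSet(
            tibial_facets=np.arange(n),
            femoral_facets=np.zeros(n, dtype=int),
            deformations=np.ones(n),
            directions=np.asarray(directions, float),
            areas=np.asarray(areas, float),
        )

    def test_unit_bookkeeping(self):
        # 2 MPa on a 3 mm^2 facet along +z -> (0, 0, 6) N
        s = self._springs(1, [[0, 0, 1]], [3.0])
        np.testing.assert_allclose(contact_force(s, np.array([2.0])), [0, 0, 6])

    def test_empty_spring_set_gives_zero(self):
        s = self._springs(0, np.zeros((0, 3)), np.zeros(0))
        np.testing.assert_allclose(contact_force(s, np.zeros(0)), np.zeros(3))

    def test_mirror_symmetric_lateral_components_cancel(self):
        a = np.sqrt(0.5)
        s = self._springs(2, [[a, a, 0], [-a, a, 0]], [2.0, 2.0])
        f = contact_force(s, np.array([3.0, 3.0]))
        assert abs(f[0]) < 1e-12
        assert f[1] == pytest.approx(2 * 3.0 * 2.0 * a)


class TestContactPairs:
    def _square(self, y, n=2):
        return flat_plate(1.0, 2.0 / n, y=y)

    def test_parallel_squares_pair_facing_facets(self):
        lower, upper = self._square(0.0), self._square(1.0)
        ti, fi = find_contact_pairs(lower, upper, search_radius=2.0)
        assert len(ti) == len(lower.faces)
        np.testing.assert_array_equal(np.sort(ti), np.arange(len(lower.faces)))
        # the facing facet is the one directly above: same centroid (x, z)
        np.testing.assert_allclose(
            lower.face_centroids[ti][:, [0, 2]],
            upper.face_centroids[fi][:, [0, 2]],
            atol=1e-12,
        )

    def test_radius_below_gap_yields_empty_set(self):
        lower, upper = self._square(0.0), self._square(5.0)
        ti, fi = find_contact_pairs(lower, upper, search_radius=2.0)
        assert len(ti) == 0

    def test_partitioned_search_equals_brute_force(self):
        # two interlocking ~720-facet spheres, generic relative rotation
        a = uv_sphere(10.0)
        b = uv_sphere(10.0, center=(0.0, 12.0, 0.0))
        b = b.replace(
            vertices=(b.vertices - b.centroid)
            @ Rotation.from_euler("ZYX", [11, 23, 37], degrees=True).as_matrix().T
            + b.centroid
        )
        assert len(a.faces) <= 2000 and len(b.faces) <= 2000
        ti, fi = find_contact_pairs(a, b, search_radius=8.0)
        d = np.linalg.norm(
            a.face_centroids[:, None, :] - b.face_centroids[None, :, :], axis=2
        )
        brute_idx = d.argmin(axis=1)
        brute_dist = d.min(axis=1)
        keep = brute_dist <= 8.0
        np.testing.assert_array_equal(ti, np.nonzero(keep)[0])
        np.testing.assert_array_equal(fi, brute_idx[keep])

    def test_empty_surface_rejected(self):
        from kneedea.geometry import ValidationError

        empty = TriangleSurface(np.zeros((0, 3)), np.zeros((0, 3), int))
        with pytest.raises(ValidationError):
            find_contact_pairs(empty, uv_sphere(5.0), 1.0)


def _cap(R, rim, center_y, n_r=30, m=64):
    """Open spherical cap (concave up) around the -y pole of a sphere of
    radius R centred at (0, center_y, 0), out to lateral radius rim."""
    radii = np.linspace(0, rim, n_r + 1)[1:]
    ang = np.linspace(0, 2 * np.pi, m, endpoint=False)
    verts = [np.array([[0.0, center_y - R, 0.0]])]
    for r in radii:
        y = center_y - np.sqrt(R**2 - r**2)
        verts.append(
            np.column_stack([r * np.cos(ang), np.full(m, y), r * np.sin(ang)])
        )
    verts = np.vstack(verts)
    faces = []
    for j in range(m):  # centre fan
        faces.append([0, 1 + j, 1 + (j + 1) % m])
    for k in range(n_r - 1):
        a0 = 1 + k * m
        b0 = 1 + (k + 1) * m
        for j in range(m):
            jn = (j + 1) % m
            faces.append([a0 + j, b0 + j, b0 + jn])
            faces.append([a0 + j, b0 + jn, a0 + jn])
    surf = TriangleSurface(verts, np.asarray(faces, dtype=np.int64))
    if surf.face_normals[:, 1].mean() < 0:
        surf = TriangleSurface(surf.vertices, surf.faces[:, ::-1])
    return surf


class TestEquilibrium:
    def test_congruent_patches_force_uniform_pressure(self):
        # nested concentric caps with uniform 5.7 mm gap; load control must
        # drive the uniform stress to P / (projected contact area).  The
        # tibial normal rays are radial, so the femoral rim shadows a disc
        # scaled by the radius ratio: size it for a 500 mm^2 contact patch.
        rim_t = 16.0
        rim_f = np.sqrt(500.0 / np.pi) * (100.0 - 5.7) / 100.0
        tib = _cap(100.0, rim_t, center_y=100.0, n_r=40)
        fem = _cap(100.0 - 5.7, rim_f, center_y=100.0, n_r=30)
        field = solve_equilibrium(fem, tib, DEAMaterialParams())
        active = field.stress > 0
        assert active.any()
        stresses = field.stress[active]
        assert stresses.mean() == pytest.approx(2.0, rel=0.05)
        assert stresses.std() / stresses.mean() < 0.02  # uniform
        assert abs(field.vertical_force - 1000.0) <= 5.0

    def test_sphere_on_plate_matches_winkler_closed_form(self):
        from kneedea.experiments import winkler_sphere

        res = winkler_sphere(spacing=2.0)
        assert res.relative_error < 0.05

    def test_load_conservation_and_monotonicity(self):
        femur, tibia, _ = generate_knee_phantom(conforming_phantom_spec(0))
        peaks = []
        for load in (500.0, 1000.0, 1500.0):
            field = solve_equilibrium(femur, tibia, DEAMaterialParams(load=load))
            assert abs(field.vertical_force - load) <= 0.005 * load
            peaks.append(field.stress.max())
        assert peaks[0] < peaks[1] < peaks[2]

    def test_solver_is_deterministic(self):
        femur, tibia, _ = generate_knee_phantom(conforming_phantom_spec(0))
        a = solve_equilibrium(femur, tibia, DEAMaterialParams())
        b = solve_equilibrium(femur, tibia, DEAMaterialParams())
        assert np.array_equal(a.stress, b.stress)
        assert a.equilibrium_pose == b.equilibrium_pose

    def test_no_contact_within_travel_bound_raises(self):
        plate = flat_plate(10.0, 1.0, y=0.0)
        sphere = uv_sphere(5.0, center=(0, 50.0, 0))
        with pytest.raises(EquilibriumError, match="travel bound"):
            solve_equilibrium(sphere, plate, DEAMaterialParams(), travel_bound=10.0)


class TestCompartmentMetrics:
    def _field(self, stress, compartments, tibia):
        return ContactStressField(
            stress=np.asarray(stress, float),
            compartments=np.asarray(compartments),
            equilibrium_pose=RigidPose(),
            vertical_force=1000.0,
            converged=True,
            iterations=1,
            tibia=tibia,
            femur=tibia,
            load_axis=np.array([0.0, 1.0, 0.0]),
        )

    def test_symmetric_phantom_gives_equal_compartments(self):
        femur, tibia, _ = generate_knee_phantom(conforming_phantom_spec(0))
        field = solve_equilibrium(femur, tibia, DEAMaterialParams())
        m = compartment_metrics(field)
        assert m.peak_medial == pytest.approx(m.peak_lateral, rel=0.01)
        assert m.mean_medial == pytest.approx(m.mean_lateral, rel=0.01)
        assert m.peak_medial >= m.mean_medial > 0

    def test_uniform_field_peak_equals_mean(self):
        plate = flat_plate(2.0, 1.0)
        n = len(plate.faces)
        comp = np.where(plate.face_centroids[:, 0] < 0, "medial", "lateral")
        m = compartment_metrics(self._field(np.full(n, 2.0), comp, plate))
        assert m.peak_medial == m.mean_medial == 2.0
        assert m.peak_lateral == m.mean_lateral == 2.0

    def test_empty_compartment_reports_zero(self, caplog):
        plate = flat_plate(2.0, 1.0)
        n = len(plate.faces)
        stress = np.where(plate.face_centroids[:, 0] < 0, 1.5, 0.0)
        comp = np.where(plate.face_centroids[:, 0] < 0, "medial", "lateral")
        m = compartment_metrics(self._field(stress, comp, plate))
        assert m.peak_lateral == 0.0 and m.mean_lateral == 0.0
        assert m.peak_medial == pytest.approx(1.5)
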