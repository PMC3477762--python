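"""Synthetic knee phantoms and simulated study inputs.

The pipeline's real inputs (MRI-derived bone surfaces, radiograph edge
tracings, multi-rater contact-stress ratings) come from a restricted
cohort, so every test input is generated here instead:

* a parametric knee-like phantom — a femur with two unequal spherical
  condyles on a shaft stub, and a tibia whose plateau carries two matched
  shallow sockets (conforming, rim-limited contact);
* forward-rendered radiographic edge images at a known ground-truth pose,
  produced by the pipeline's own silhouette projector (zero model-image
  mismatch by construction);
* smooth segmentation-like surface perturbations with a controlled RMS
  amplitude and spatial correlation length;
* two-way random-effects ratings tables with known variance components for
  the reliability layer.

Default geometry: condyle radii 40/36 mm (unequal, so the silhouette fixes
the pose uniquely), intercondylar spacing 80 mm, radial socket clearance
0.5 mm, socket rim radius 15 mm.  The conforming variant (equal 40 mm
condyles, 40.5 mm sockets, 15 mm rims) reproduces near-uniform
tibiofemoral contact for the thickness-sensitivity experiments.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import sparse

from .geometry import RigidPose, TriangleSurface, ValidationError, apply_pose
from .projection import EdgeImage, RadiographicScene, render_silhouette
from .reliability import RatingsTable


# ---------------------------------------------------------------------------
# mesh primitives
# ---------------------------------------------------------------------------

def _orient_outward(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    s = TriangleSurface(verts, faces)
    if s.signed_volume < 0:
        return faces[:, ::-1].copy()
    return faces


def uv_sphere(radius: float, center=(0, 0, 0), n_theta: int = 16, n_phi: int = 24) -> TriangleSurface:
    """Closed latitude-longitude sphere mesh with outward winding."""
    c = np.asarray(center, dtype=float)
    thetas = np.linspace(0, np.pi, n_theta + 1)[1:-1]
    phis = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    rings = []
    for th in thetas:
        rings.append(
            np.column_stack(
                [
                    radius * np.sin(th) * np.cos(phis),
                    radius * np.cos(th) * np.ones_like(phis),
                    radius * np.sin(th) * np.sin(phis),
                ]
            )
        )
    # poles along +/- y (matches the phantom's superior-inferior axis)
    top = np.array([[0.0, radius, 0.0]])
    bot = np.array([[0.0, -radius, 0.0]])
    verts = np.vstack([top] + rings + [bot]) + c
    n_rings = len(thetas)
    faces = []
    ring0 = 1
    for j in range(n_phi):
        jn = (j + 1) % n_phi
        faces.append([0, ring0 + j, ring0 + jn])
    for i in range(n_rings - 1):
        a0 = ring0 + i * n_phi
        b0 = ring0 + (i + 1) * n_phi
        for j in range(n_phi):
            jn = (j + 1) % n_phi
            faces.append([a0 + j, b0 + j, b0 + jn])
            faces.append([a0 + j, b0 + jn, a0 + jn])
    last = ring0 + (n_rings - 1) * n_phi
    bottom = len(verts) - 1
    for j in range(n_phi):
        jn = (j + 1) % n_phi
        faces.append([bottom, last + jn, last + j])
    faces = np.asarray(faces, dtype=np.int64)
    return TriangleSurface(verts, _orient_outward(verts, faces))


def icosphere(radius: float = 1.0, center=(0, 0, 0), subdivisions: int = 3) -> TriangleSurface:
    """Subdivided-icosahedron sphere (near-uniform facets)."""
    t = (1 + np.sqrt(5)) / 2
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in cache:
                m = vlist[a] + vlist[b]
                m /= np.linalg.norm(m)
                cache[key] = len(vlist)
                vlist.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.asarray(vlist)
        faces = np.asarray(new_faces, dtype=np.int64)
    verts = verts * radius + np.asarray(center, dtype=float)
    return TriangleSurface(verts, _orient_outward(verts, faces))


def capped_cylinder(
    radius: float, y0: float, y1: float, center_xz=(0.0, 0.0), n_phi: int = 24
) -> TriangleSurface:
    """Closed cylinder along +y with fan-triangulated end caps."""
    cx, cz = center_xz
    phis = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    ring = np.column_stack([cx + radius * np.cos(phis), np.zeros(n_phi), cz + radius * np.sin(phis)])
    lower = ring + [0, y0, 0]
    upper = ring + [0, y1, 0]
    c_lo = np.array([[cx, y0, cz]])
    c_hi = np.array([[cx, y1, cz]])
    verts = np.vstack([lower, upper, c_lo, c_hi])
    i_lo, i_hi = 2 * n_phi, 2 * n_phi + 1
    faces = []
    for j in range(n_phi):
        jn = (j + 1) % n_phi
        faces.append([j, n_phi + j, n_phi + jn])
        faces.append([j, n_phi + jn, jn])
        faces.append([i_lo, j, jn])
        faces.append([i_hi, n_phi + jn, n_phi + j])
    faces = np.asarray(faces, dtype=np.int64)
    return TriangleSurface(verts, _orient_outward(verts, faces))


def merge_surfaces(surfaces: list[TriangleSurface], label: str = "") -> TriangleSurface:
    """Concatenate closed components into one surface (indices re-offset)."""
    verts = []
    faces = []
    offset = 0
    for s in surfaces:
        verts.append(s.vertices)
        faces.append(s.faces + offset)
        offset += len(s.vertices)
    return TriangleSurface(np.vstack(verts), np.vstack(faces), label)


def extruded_heightfield(
    xs: np.ndarray, zs: np.ndarray, top_y: np.ndarray, y_bottom: float, label: str = ""
) -> TriangleSurface:
    """Closed solid from a heightfield: triangulated top surface ``top_y``
    over the (x, z) grid, flat bottom at ``y_bottom``, vertical side walls."""
    nx, nz = len(xs), len(zs)
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    top = np.column_stack([X.ravel(), top_y.ravel(), Z.ravel()])
    bot = np.column_stack([X.ravel(), np.full(X.size, y_bottom), Z.ravel()])
    verts = np.vstack([top, bot])
    off = nx * nz

    def t(i, j):
        return i * nz + j

    faces = []
    for i in range(nx - 1):
        for j in range(nz - 1):
            a, b, c, d = t(i, j), t(i + 1, j), t(i + 1, j + 1), t(i, j + 1)
            faces += [[a, c, b], [a, d, c]]                 # top, +y outward
            faces += [[off + a, off + b, off + c], [off + a, off + c, off + d]]
    # boundary loop of the grid (ordered walk)
    loop = (
        [t(i, 0) for i in range(nx)]
        + [t(nx - 1, j) for j in range(1, nz)]
        + [t(i, nz - 1) for i in range(nx - 2, -1, -1)]
        + [t(0, j) for j in range(nz - 2, 0, -1)]
    )
    for k in range(len(loop)):
        p, q = loop[k], loop[(k + 1) % len(loop)]
        faces += [[p, q, off + q], [p, off + q, off + p]]
    faces = np.asarray(faces, dtype=np.int64)
    return TriangleSurface(verts, _orient_outward(verts, faces), label)


# ---------------------------------------------------------------------------
# knee phantom
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a knee-like phantom (all lengths mm).

    ``socket_clearance`` is the uniform radial gap between each condyle and
    its matched socket; socket sphere radius = condyle radius + clearance.
    ``refinement`` doubles mesh resolution per level (facet count ~x4).
    """

    condyle_radii: tuple[float, float] = (40.0, 36.0)
    intercondylar_spacing: float = 80.0
    socket_clearance: float = 0.5
    socket_rim_radius: float = 15.0
    shaft_radius: float = 18.0
    plateau_depth: float = 30.0
    refinement: int = 0
    seed: int = 0

    @property
    def socket_radii(self) -> tuple[float, float]:
        return (
            self.condyle_radii[0] + self.socket_clearance,
            self.condyle_radii[1] + self.socket_clearance,
        )

    def validate(self) -> None:
        r1, r2 = self.condyle_radii
        if r1 <= 0 or r2 <= 0:
            raise ValidationError("condyle radii must be positive")
        if self.socket_clearance < 0:
            raise ValidationError("socket radius must be >= condyle radius (conforming)")
        if self.intercondylar_spacing <= r1 + r2:
            raise ValidationError(
                f"condyles overlap: spacing {self.intercondylar_spacing} <= "
                f"radius sum {r1 + r2}"
            )
        if self.socket_rim_radius <= 0 or self.socket_rim_radius >= min(self.socket_radii):
            raise ValidationError("socket rim radius must lie in (0, socket radius)")


def generate_knee_phantom(
    spec: PhantomSpec = PhantomSpec(),
) -> tuple[TriangleSurface, TriangleSurface, RigidPose]:
    """Build (femur, tibia, ground-truth relative pose).

    The bones are generated already in loaded apposition — each condyle sits
    concentric in its socket with a uniform radial gap of
    ``spec.socket_clearance`` — so the ground-truth relative pose is the
    identity.  Both surfaces are closed and outward-wound; construction is
    deterministic.
    """
    spec.validate()
    n = 2**spec.refinement
    rr = spec.socket_rim_radius
    half = spec.intercondylar_spacing / 2.0
    centers_x = (-half, half)
    socket_h = [np.sqrt(rs**2 - rr**2) for rs in spec.socket_radii]

    # each condyle rests touching its socket bottom: centre lowered by the
    # clearance so the gap grows parabolically toward the rim (effective
    # radius R_c (R_c + clearance) / clearance) and contact peaks at the
    # smooth cup centre
    condyles = [
        uv_sphere(
            rc,
            center=(cx, h - spec.socket_clearance, 0.0),
            n_theta=16 * n,
            n_phi=24 * n,
        )
        for rc, cx, h in zip(spec.condyle_radii, centers_x, socket_h)
    ]
    shaft_y0 = max(socket_h[i] + spec.condyle_radii[i] for i in range(2)) * 0.5
    shaft = capped_cylinder(
        spec.shaft_radius, shaft_y0, shaft_y0 + 90.0, n_phi=24 * n
    )
    femur = merge_surfaces(condyles + [shaft], label="femur")

    margin = 8.0
    x_ext = half + rr + margin
    z_ext = rr + margin
    xs = np.linspace(-x_ext, x_ext, 64 * n + 1)
    zs = np.linspace(-z_ext, z_ext, 28 * n + 1)
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    top = np.zeros_like(X)
    for rs, cx, h in zip(spec.socket_radii, centers_x, socket_h):
        d2 = (X - cx) ** 2 + Z**2
        inside = d2 < rr**2
        top = np.where(inside, h - np.sqrt(np.maximum(rs**2 - d2, 0.0)), top)
    tibia = extruded_heightfield(xs, zs, top, -spec.plateau_depth, label="tibia")
    return femur, tibia, RigidPose()


def conforming_phantom_spec(refinement: int = 0) -> PhantomSpec:
    """Equal 40 mm condyles in 40.5 mm sockets with 15 mm rims: rim-limited,
    near-uniform contact for thickness-sensitivity experiments."""
    return PhantomSpec(
        condyle_radii=(40.0, 40.0),
        intercondylar_spacing=85.0,
        socket_clearance=0.5,
        socket_rim_radius=15.0,
        refinement=refinement,
    )


# ---------------------------------------------------------------------------
# scene placement and synthetic radiographs
# ---------------------------------------------------------------------------

def place_in_scene(surface: TriangleSurface, scene: RadiographicScene) -> TriangleSurface:
    """Translate a phantom built around the origin to the scene's nominal
    knee position between the source and detector."""
    offset = scene.nominal_object_center
    return surface.replace(vertices=surface.vertices + offset)


def synthesize_radiograph_edges(
    surfaces: list[TriangleSurface],
    scene: RadiographicScene,
    pose: RigidPose = RigidPose(),
    center=None,
) -> list[EdgeImage]:
    """Forward-render edge images for each surface at a known pose.

    Surfaces are placed at the scene's nominal object position, posed
    (rotation about ``center``, default the scene's nominal object centre),
    and ray-cast with the pipeline's own silhouette projector — so a
    registration started from the truth sees zero cost by construction.
    """
    c = scene.nominal_object_center if center is None else np.asarray(center, float)
    images = []
    for s in surfaces:
        posed = apply_pose(place_in_scene(s, scene), pose, center=c)
        img = render_silhouette(posed, scene)
        img.provenance = "radiograph tracing (synthetic)"
        images.append(img)
    return images


# ---------------------------------------------------------------------------
# segmentation-like perturbation
# ---------------------------------------------------------------------------

def _vertex_normals(surface: TriangleSurface) -> np.ndarray:
    vn = np.zeros_like(surface.vertices)
    fn = surface.face_normals * surface.face_areas[:, None]
    for k in range(3):
        np.add.at(vn, surface.faces[:, k], fn)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    return vn / np.maximum(norms, 1e-30)


def perturb_segmentation(
    surface: TriangleSurface,
    amplitude: float,
    correlation_length: float = 5.0,
    seed: int = 0,
) -> TriangleSurface:
    """Displace vertices along their normals by smooth correlated noise.

    White per-vertex noise is smoothed over the mesh graph by iterated
    neighbour averaging (random-walk smoothing spreads over roughly
    sqrt(iterations) edge lengths) and rescaled so the RMS normal
    displacement equals ``amplitude`` (mm).  Topology is unchanged;
    deterministic given ``seed``.
    """
    if amplitude < 0:
        raise ValidationError("amplitude must be >= 0")
    if amplitude == 0:
        return surface.replace()
    edges = surface.edges
    mean_edge = float(
        np.linalg.norm(
            surface.vertices[edges[:, 0]] - surface.vertices[edges[:, 1]], axis=1
        ).mean()
    )
    extents = surface.vertices.max(axis=0) - surface.vertices.min(axis=0)
    if amplitude > 0.1 * extents.min() / 2:
        warnings.warn(
            "perturbation amplitude exceeds 10% of the smallest half-extent; "
            "the surface may self-intersect",
            stacklevel=2,
        )
    n_iter = int(np.clip(round((correlation_length / mean_edge) ** 2), 1, 200))
    nv = len(surface.vertices)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    A = sparse.csr_matrix((np.ones(len(i)), (i, j)), shape=(nv, nv))
    deg = np.asarray(A.sum(axis=1)).ravel()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(nv)
    for _ in range(n_iter):
        noise = 0.5 * noise + 0.5 * (A @ noise) / np.maximum(deg, 1)
    rms = np.sqrt(np.mean(noise**2))
    noise *= amplitude / max(rms, 1e-30)
    verts = surface.vertices + noise[:, None] * _vertex_normals(surface)
    return surface.replace(vertices=verts)


# ---------------------------------------------------------------------------
# simulated ratings
# ---------------------------------------------------------------------------

def simulate_ratings(
    n_targets: int,
    k_raters: int,
    n_days: int,
    variance_components: tuple[float, float, float],
    grand_mean: float = 3.0,
    seed: int = 0,
    metric: str = "peak",
    compartment: str = "medial",
) -> RatingsTable:
    """Two-way random-effects ratings: value(i, j, d) = mu + a_i + b_j +
    e_ijd with independent zero-mean normal effects at the stated variances
    (sigma2_target, sigma2_rater, sigma2_error).

    The population single-score ICC of this model is
    sigma2_target / (sigma2_target + sigma2_rater + sigma2_error).
    """
    s2t, s2r, s2e = variance_components
    if min(s2t, s2r, s2e) < 0:
        raise ValidationError("variance components must be nonnegative")
    if n_targets < 2:
        raise ValidationError("need at least 2 targets")
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, np.sqrt(s2t), size=n_targets)
    b = rng.normal(0.0, np.sqrt(s2r), size=k_raters)
    e = rng.normal(0.0, np.sqrt(s2e), size=(n_targets, k_raters, n_days))
    values = grand_mean + a[:, None, None] + b[None, :, None] + e
    return RatingsTable(values=values, metric=metric, compartment=compartment)


def population_icc(variance_components: tuple[float, float, float]) -> float:
    s2t, s2r, s2e = variance_components
    return s2t / (s2t + s2r + s2e)
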