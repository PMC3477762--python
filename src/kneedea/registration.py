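"""3D-to-2D bone registration by silhouette matching with CMA-ES.

Each bone's 6-DOF pose (tx, ty, tz translations in mm; rx, ry, rz intrinsic
z-y-x rotations in degrees, about the bone centroid fixed at optimization
start) is found by minimizing the symmetric distance-transform cost between
the ray-cast model silhouette and the radiograph edge tracing.  Because the
landscape is nonconvex, several independently seeded CMA-ES runs (default
3, 70 candidates per generation, up to 8000 cost evaluations each) are
executed and the lowest-cost run wins, ties broken by run index.

The femur is aligned first; its best transform is applied to the tibia as
the tibial starting pose, and the tibial cost adds a proximity penalty that
grows once the minimum tibiofemoral gap exceeds a threshold (default 6 mm,
the combined cartilage thickness).

Initial search scales default to (5, 5, 10) mm and (3, 3, 3) degrees — the
out-of-plane (depth) translation gets the larger scale because a single
projection constrains it only through magnification.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .cmaes import CMAResult, cma_es_minimize
from .geometry import RigidPose, TriangleSurface, ValidationError, apply_pose
from .projection import (
    EdgeImage,
    RadiographicScene,
    _sample_segments_px,
)

DEFAULT_SIGMA0 = (5.0, 5.0, 10.0, 3.0, 3.0, 3.0)
#: cost assigned when a candidate pose projects fully outside the image
OUT_OF_IMAGE_COST = 1e6


class InitializationError(ValidationError):
    """The initial pose projects the silhouette fully outside the image."""


class KneeRegistrationError(RuntimeError):
    """Sequential knee registration failed; carries the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"{stage} registration failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass(frozen=True)
class RunRecord:
    pose: RigidPose
    cost: float
    evaluations: int
    seed: int
    converged: bool


@dataclasses.dataclass
class RegistrationResult:
    """Outcome of one bone's registration (best of the independent runs)."""

    best_pose: RigidPose
    best_cost: float
    per_run: list[RunRecord]
    converged: bool
    best_index: int
    rotation_center: np.ndarray

    def to_dict(self) -> dict:
        return {
            "best_pose": list(self.best_pose.vector),
            "best_cost": self.best_cost,
            "converged": self.converged,
            "best_index": self.best_index,
            "rotation_center": list(map(float, self.rotation_center)),
            "per_run": [
                {
                    "pose": list(r.pose.vector),
                    "cost": r.cost,
                    "evaluations": r.evaluations,
                    "seed": r.seed,
                    "converged": r.converged,
                }
                for r in self.per_run
            ],
        }


def _derive_seed(seed: int, index: int) -> int:
    """Distinct per-run seeds, deterministic in (seed, index)."""
    return int((seed * 1000003 + index * 7919 + 1) % (2**31))


class _SilhouetteCost:
    """Fast repeated evaluation of the silhouette contour cost.

    Precomputes the mesh topology (edge->face table), the radiograph's
    distance transform and foreground pixels, and the fixed rotation
    centre; each evaluation transforms vertices, finds silhouette edges
    from per-facet facing signs, projects them and scores the rasterized
    pixels.  Identical numbers to ``contour_cost(render_silhouette(...))``.
    """

    def __init__(
        self,
        surface: TriangleSurface,
        edges_image: EdgeImage,
        scene: RadiographicScene,
        center: np.ndarray,
        extra_cost=None,
    ):
        if edges_image.n_foreground == 0:
            raise ValidationError("radiograph edge image is empty")
        self.scene = scene
        self.center = np.asarray(center, dtype=float)
        self.base_vertices = surface.vertices.copy()
        self.faces = surface.faces
        edges, table = surface.edge_faces
        n_inc = (table >= 0).sum(axis=1)
        self.interior = n_inc == 2
        self.boundary = n_inc == 1
        self.edge_pairs = edges
        self.f0 = table[:, 0]
        self.f1 = table[:, 1] if table.shape[1] > 1 else table[:, 0]
        self.radio_dt = edges_image.distance_transform
        self.radio_px = edges_image.foreground_pixels
        self.spacing = edges_image.pixel_spacing
        self.src = scene.source_point
        self.extra_cost = extra_cost
        self.n_eval = 0

    def silhouette_pixels(self, pose_vector: np.ndarray) -> np.ndarray | None:
        """In-bounds (row, col) silhouette pixels at a pose, or None when
        the projection misses the image entirely."""
        pose = RigidPose.from_vector(pose_vector)
        R = pose.rotation.as_matrix()
        verts = (self.base_vertices - self.center) @ R.T + self.center + pose.translation
        tri = verts[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        centroids = tri.mean(axis=1)
        facing = np.einsum("ij,ij->i", cross, centroids - self.src)
        flip = np.zeros(len(self.edge_pairs), dtype=bool)
        ii = self.interior
        flip[ii] = np.sign(facing[self.f0[ii]]) != np.sign(facing[self.f1[ii]])
        keep = self.boundary | flip
        sil = self.edge_pairs[keep]
        if len(sil) == 0:
            return None
        pts = verts[sil.ravel()]
        src = self.src
        denom = src[2] - pts[:, 2]
        ok = np.abs(denom) > 1e-12
        t = np.zeros(len(pts))
        t[ok] = src[2] / denom[ok]
        hit = src + t[:, None] * (pts - src)
        uv = hit[:, :2]
        pairs_ok = ok.reshape(-1, 2).all(axis=1)
        uv_pairs = uv.reshape(-1, 2, 2)[pairs_ok]
        if len(uv_pairs) == 0:
            return None
        p0 = self.scene.mm_to_pixel(uv_pairs[:, 0])
        p1 = self.scene.mm_to_pixel(uv_pairs[:, 1])
        px = _sample_segments_px(p0, p1)
        h, w = self.scene.image_size
        inb = (px[:, 0] >= 0) & (px[:, 0] < h) & (px[:, 1] >= 0) & (px[:, 1] < w)
        px = px[inb]
        if len(px) == 0:
            return None
        # deduplicate via 1D raster codes (much faster than row-wise unique)
        codes = np.unique(px[:, 0] * w + px[:, 1])
        return np.column_stack(np.divmod(codes, w))

    def __call__(self, x: np.ndarray) -> float:
        self.n_eval += 1
        px = self.silhouette_pixels(x)
        if px is None:
            return OUT_OF_IMAGE_COST
        term1 = float(self.radio_dt[px[:, 0], px[:, 1]].mean())
        tree = cKDTree(px, balanced_tree=False, compact_nodes=False)
        term2 = float(tree.query(self.radio_px)[0].mean())
        cost = (term1 + term2) * self.spacing
        if self.extra_cost is not None:
            cost += self.extra_cost(x)
        return cost


def register_bone(
    surface: TriangleSurface,
    edges: EdgeImage,
    scene: RadiographicScene,
    init_pose: RigidPose | None = None,
    n_runs: int = 3,
    seed: int = 0,
    popsize: int = 70,
    max_evals: int = 8000,
    sigma0=DEFAULT_SIGMA0,
    center=None,
    extra_cost=None,
    edge_confirm=None,
) -> RegistrationResult:
    """Register one bone to its radiograph edge image.

    Runs ``n_runs`` independently seeded CMA-ES minimizations of the
    silhouette contour cost starting from ``init_pose`` (default identity)
    and reports the lowest-cost run (ties broken by run index).
    Deterministic given ``seed``.

    ``edge_confirm`` is an optional supervision hook called with the edge
    image before optimization (mirroring an interactive check that the
    traced edges follow the bony outline); returning falsy aborts the
    registration.
    """
    if edge_confirm is not None and not edge_confirm(edges):
        raise ValidationError("edge tracing rejected by the confirmation hook")
    init_pose = init_pose or RigidPose()
    c = surface.centroid if center is None else np.asarray(center, dtype=float)
    evaluator = _SilhouetteCost(surface, edges, scene, c, extra_cost=extra_cost)
    if evaluator.silhouette_pixels(init_pose.vector) is None:
        raise InitializationError(
            "silhouette projects fully outside the image at the initial pose; "
            "re-center the model between source and detector"
        )
    runs: list[RunRecord] = []
    for i in range(n_runs):
        run_seed = _derive_seed(seed, i)
        res: CMAResult = cma_es_minimize(
            evaluator,
            x0=init_pose.vector,
            sigma0=np.asarray(sigma0, dtype=float),
            popsize=popsize,
            max_evals=max_evals,
            seed=run_seed,
        )
        runs.append(
            RunRecord(
                pose=RigidPose.from_vector(res.x),
                cost=res.cost,
                evaluations=res.evaluations,
                seed=run_seed,
                converged=res.converged,
            )
        )
    costs = [r.cost for r in runs]
    best = int(np.argmin(costs))  # argmin takes the first of equal minima
    return RegistrationResult(
        best_pose=runs[best].pose,
        best_cost=runs[best].cost,
        per_run=runs,
        converged=runs[best].converged,
        best_index=best,
        rotation_center=c,
    )


def tibia_penalty(
    femur_posed: TriangleSurface,
    tibia_posed: TriangleSurface,
    weight: float = 1.0,
    gap_threshold: float = 6.0,
) -> float:
    """Proximity penalty keeping the tibia near the femur:
    weight * max(0, gap - gap_threshold), where gap is the minimum
    intersurface distance (mm, vertex-sampled) and the threshold defaults
    to the 6 mm combined cartilage thickness."""
    gap, _ = cKDTree(femur_posed.vertices).query(tibia_posed.vertices)
    return float(weight * max(0.0, gap.min() - gap_threshold))


def register_knee(
    femur: TriangleSurface,
    tibia: TriangleSurface,
    femur_edges: EdgeImage,
    tibia_edges: EdgeImage,
    scene: RadiographicScene,
    seed: int = 0,
    init_pose: RigidPose | None = None,
    penalty_weight: float = 1.0,
    gap_threshold: float = 6.0,
    **options,
) -> tuple[RegistrationResult, RegistrationResult]:
    """Sequential knee registration: femur first, then tibia.

    The femur's best transform is applied to the tibia to form its
    starting pose; the tibial cost is contour cost plus the proximity
    penalty against the (fixed) registered femur.  If the femur stage
    fails, the tibia is not attempted and a paired
    :class:`KneeRegistrationError` is raised.

    The tibial result's ``best_pose`` is relative to the femur-transformed
    tibia (compose with the femur's best pose for the full transform);
    :func:`posed_surface` applies a result to its bone.
    """
    try:
        femur_result = register_bone(
            femur, femur_edges, scene, init_pose=init_pose, seed=seed, **options
        )
    except Exception as exc:
        raise KneeRegistrationError("femur", exc) from exc

    # move the tibia with the femur's best transform (same spatial map:
    # rotation about the femur's centre)
    tibia_start = apply_pose(
        tibia, femur_result.best_pose, center=femur_result.rotation_center
    )
    femur_posed = apply_pose(
        femur, femur_result.best_pose, center=femur_result.rotation_center
    )
    fem_tree = cKDTree(femur_posed.vertices)
    tib_center = tibia_start.centroid
    base = tibia_start.vertices - tib_center

    def proximity(x: np.ndarray) -> float:
        pose = RigidPose.from_vector(x)
        verts = base @ pose.rotation.as_matrix().T + tib_center + pose.translation
        gap, _ = fem_tree.query(verts)
        return penalty_weight * max(0.0, float(gap.min()) - gap_threshold)

    try:
        tibia_result = register_bone(
            tibia_start,
            tibia_edges,
            scene,
            init_pose=RigidPose(),
            seed=_derive_seed(seed, 101),
            center=tib_center,
            extra_cost=proximity,
            **options,
        )
    except Exception as exc:
        raise KneeRegistrationError("tibia", exc) from exc
    return femur_result, tibia_result


def posed_surface(surface: TriangleSurface, result: RegistrationResult) -> TriangleSurface:
    """Apply a registration result's best pose to its bone."""
    return apply_pose(surface, result.best_pose, center=result.rotation_center)
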