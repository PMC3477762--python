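"""Virtual radiographic scene and silhouette projection.

The posterior-anterior fixed-flexion acquisition is recreated in virtual
space: a point X-ray source sits 72 in (1828.8 mm) from the detector along a
central ray tilted caudally by 5, 10 or 15 degrees; the detector is a
rectangle in the plane z = 0 (modelled, as on real systems, by two adjacent
coplanar polygons).  Bone-model silhouette edges are found from facet
orientation relative to the source, ray-cast onto the detector, rasterized
with a line-drawing algorithm into a binary edge image, and compared with a
radiograph edge tracing through a symmetric mean distance-transform cost.

Scene frame: the detector spans x (horizontal, medial-lateral) and
y (vertical) in its plane; z points from the detector toward the source.
The caudal angle tilts the source about the detector's horizontal (x) axis
while keeping the source-detector distance along the central ray.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from functools import cached_property
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from .geometry import TriangleSurface, ValidationError

#: 72 inches, exactly, in millimetres
DEFAULT_SDD_MM = 1828.8
STANDARD_CAUDAL_ANGLES = (5.0, 10.0, 15.0)


@dataclasses.dataclass(frozen=True)
class RadiographicScene:
    """Geometry of the virtual radiographic acquisition.

    Parameters
    ----------
    source_detector_distance : mm from the source to the detector centre
        along the central ray (default 1828.8 = 72 in).
    caudal_angle : degrees of downward beam tilt about the detector's
        horizontal axis; the acquisition protocol uses 5, 10 or 15.
    pixel_spacing : detector sampling, mm/pixel.
    image_size : (rows, cols) of the detector raster.
    object_detector_distance : mm from the detector plane to the nominal
        knee position along the central ray.
    """

    source_detector_distance: float = DEFAULT_SDD_MM
    caudal_angle: float = 10.0
    pixel_spacing: float = 0.2
    image_size: tuple[int, int] = (768, 768)
    object_detector_distance: float = 100.0

    @property
    def source_point(self) -> np.ndarray:
        """Source position, mm: SDD from the detector centre along the
        central ray tilted by the caudal angle about +x."""
        th = np.radians(self.caudal_angle)
        return self.source_detector_distance * np.array(
            [0.0, np.sin(th), np.cos(th)]
        )

    @property
    def detector_center(self) -> np.ndarray:
        return np.zeros(3)

    @property
    def detector_normal(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])

    @property
    def detector_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane (u, v) unit axes of the detector."""
        return np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])

    @property
    def detector_size_mm(self) -> tuple[float, float]:
        """(width, height) of the detector rectangle, mm."""
        h, w = self.image_size
        return w * self.pixel_spacing, h * self.pixel_spacing

    @property
    def detector_polygons(self) -> list[np.ndarray]:
        """The detector rectangle as two adjacent coplanar polygons
        (triangles), each (3, 3) mm."""
        w, h = self.detector_size_mm
        c = np.array(
            [[-w / 2, -h / 2, 0.0], [w / 2, -h / 2, 0.0],
             [w / 2, h / 2, 0.0], [-w / 2, h / 2, 0.0]]
        )
        return [c[[0, 1, 2]], c[[0, 2, 3]]]

    @property
    def central_ray(self) -> np.ndarray:
        """Unit vector from the source toward the detector centre."""
        d = self.detector_center - self.source_point
        return d / np.linalg.norm(d)

    @property
    def nominal_object_center(self) -> np.ndarray:
        """Nominal knee position between the source and detector: the point
        on the central ray at the object-to-detector distance."""
        return self.detector_center - self.object_detector_distance * self.central_ray

    # -- detector-plane (mm) <-> pixel (row, col) mapping ------------------

    def mm_to_pixel(self, uv: np.ndarray) -> np.ndarray:
        """Detector in-plane mm coordinates -> fractional (row, col)."""
        uv = np.atleast_2d(uv)
        h, w = self.image_size
        col = uv[:, 0] / self.pixel_spacing + (w - 1) / 2.0
        row = (h - 1) / 2.0 - uv[:, 1] / self.pixel_spacing
        return np.column_stack([row, col])

    def pixel_to_mm(self, rc: np.ndarray) -> np.ndarray:
        rc = np.atleast_2d(rc)
        h, w = self.image_size
        u = (rc[:, 1] - (w - 1) / 2.0) * self.pixel_spacing
        v = ((h - 1) / 2.0 - rc[:, 0]) * self.pixel_spacing
        return np.column_stack([u, v])


def build_scene(
    source_detector_distance: float = DEFAULT_SDD_MM,
    caudal_angle: float = 10.0,
    pixel_spacing: float = 0.2,
    image_size: tuple[int, int] = (768, 768),
    object_detector_distance: float = 100.0,
    allow_nonstandard_angle: bool = False,
) -> RadiographicScene:
    """Construct a :class:`RadiographicScene`, validating the acquisition
    parameters (caudal angle restricted to the protocol's 5/10/15 degrees
    unless ``allow_nonstandard_angle``)."""
    if source_detector_distance <= 0:
        raise ValidationError("source-detector distance must be positive")
    if object_detector_distance <= 0 or object_detector_distance >= source_detector_distance:
        raise ValidationError("object-detector distance must lie between detector and source")
    if pixel_spacing <= 0:
        raise ValidationError("pixel spacing must be positive")
    if image_size[0] <= 0 or image_size[1] <= 0:
        raise ValidationError("image size must be positive")
    if not allow_nonstandard_angle and float(caudal_angle) not in STANDARD_CAUDAL_ANGLES:
        raise ValidationError(
            f"caudal angle {caudal_angle} not in protocol set {STANDARD_CAUDAL_ANGLES}; "
            "pass allow_nonstandard_angle=True to override"
        )
    return RadiographicScene(
        source_detector_distance=float(source_detector_distance),
        caudal_angle=float(caudal_angle),
        pixel_spacing=float(pixel_spacing),
        image_size=(int(image_size[0]), int(image_size[1])),
        object_detector_distance=float(object_detector_distance),
    )


# ---------------------------------------------------------------------------
# edge images
# ---------------------------------------------------------------------------

@dataclasses.dataclass(eq=False)
class EdgeImage:
    """A binary bone-edge raster on the detector grid.

    ``provenance`` records whether the foreground came from a radiograph
    tracing or from the ray-cast model projection.
    """

    pixels: np.ndarray
    pixel_spacing: float
    origin_mm: tuple[float, float] = (0.0, 0.0)
    provenance: str = "radiograph tracing"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError("edge image must be a 2D raster")
        if px.dtype != bool:
            vals = np.unique(px)
            if not np.all(np.isin(vals, (0, 1, 255))):
                raise ValidationError("edge image must be strictly binary")
            px = px > 0
        self.pixels = px

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())

    @cached_property
    def foreground_pixels(self) -> np.ndarray:
        """(k, 2) array of foreground (row, col) coordinates."""
        return np.argwhere(self.pixels)

    @cached_property
    def distance_transform(self) -> np.ndarray:
        """Euclidean distance (pixels) from each pixel to the nearest
        foreground pixel."""
        if self.n_foreground == 0:
            raise ValidationError("edge image has no foreground pixels")
        return distance_transform_edt(~self.pixels)

    def save(self, path) -> None:
        """Write as a single-channel 0/255 PNG/TIFF with a JSON sidecar
        carrying pixel spacing, origin and provenance."""
        path = Path(path)
        iio.imwrite(path, (self.pixels.astype(np.uint8) * 255))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "pixel_spacing_mm": self.pixel_spacing,
                    "origin_mm": list(self.origin_mm),
                    "provenance": self.provenance,
                }
            )
        )

    @classmethod
    def load(cls, path) -> "EdgeImage":
        path = Path(path)
        px = np.asarray(iio.imread(path))
        if px.ndim == 3:
            px = px[..., 0]
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            pixels=px > 0,
            pixel_spacing=float(meta.get("pixel_spacing_mm", 1.0)),
            origin_mm=tuple(meta.get("origin_mm", (0.0, 0.0))),
            provenance=meta.get("provenance", "radiograph tracing"),
        )


# ---------------------------------------------------------------------------
# silhouette extraction and projection
# ---------------------------------------------------------------------------

def extract_silhouette_edges(surface: TriangleSurface, source_point) -> np.ndarray:
    """Mesh edges on the model silhouette as seen from ``source_point``.

    An interior edge is a silhouette edge when its two adjacent faces have
    opposite-signed dot products of face normal with the view direction
    (facet centroid minus source); boundary edges are always included.

    Returns a (k, 2) array of vertex index pairs.
    """
    if len(surface.faces) == 0:
        raise ValidationError("cannot extract silhouette of an empty surface")
    src = np.asarray(source_point, dtype=float)
    facing = np.einsum(
        "ij,ij->i", surface.face_normals, surface.face_centroids - src
    )
    edges, table = surface.edge_faces
    n_inc = (table >= 0).sum(axis=1)
    boundary = n_inc == 1
    interior = n_inc == 2
    f0 = table[:, 0]
    f1 = np.where(interior, table[:, 1] if table.shape[1] > 1 else -1, f0)
    sign_flip = np.zeros(len(edges), dtype=bool)
    sign_flip[interior] = (
        np.sign(facing[f0[interior]]) != np.sign(facing[f1[interior]])
    )
    keep = boundary | sign_flip
    result = edges[keep]
    if len(result) == 0:
        raise ValidationError("surface has no silhouette edges (degenerate view)")
    return result


def project_to_detector(points, scene: RadiographicScene) -> np.ndarray:
    """Intersect source->point rays with the detector plane.

    Returns (n, 2) detector in-plane mm coordinates.  Points whose ray is
    parallel to the detector plane (or that coincide with the source) are
    excluded with a warning.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    src = scene.source_point
    d = pts - src
    if np.any(np.linalg.norm(d, axis=1) < 1e-12):
        raise ValidationError("a point coincides with the X-ray source")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = src[2] / (src[2] - pts[:, 2])
    valid = np.isfinite(t) & (np.abs(src[2] - pts[:, 2]) > 1e-12)
    if not np.all(valid):
        warnings.warn(
            f"{int((~valid).sum())} rays parallel to the detector plane excluded",
            stacklevel=2,
        )
    hit = src + t[valid, None] * d[valid]
    u_ax, v_ax = scene.detector_axes
    return np.column_stack([hit @ u_ax, hit @ v_ax])


def _sample_segments_px(p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Densely sample line segments (fractional pixel endpoints) at unit
    steps along the dominant axis; rounding yields 8-connected runs.

    ``p0``/``p1`` are (n, 2) (row, col).  Returns integer (m, 2) pixels.
    """
    d = p1 - p0
    nsteps = np.maximum(np.ceil(np.abs(d).max(axis=1)).astype(int), 0) + 1
    total = int(nsteps.sum())
    seg = np.repeat(np.arange(len(p0)), nsteps)
    starts = np.concatenate([[0], np.cumsum(nsteps)[:-1]])
    step = np.arange(total) - starts[seg]
    denom = np.maximum(nsteps - 1, 1)
    t = step / denom[seg]
    pts = p0[seg] + t[:, None] * d[seg]
    # round half-up (np.rint's round-half-even leaves gaps on exact .5 grids)
    return np.floor(pts + 0.5).astype(np.int64)


def rasterize_segments(
    segments_mm: np.ndarray, scene: RadiographicScene, provenance: str = "ray-cast projection"
) -> EdgeImage:
    """Rasterize 2D mm line segments ((n, 2, 2): endpoint pairs) into a
    binary edge image on the scene's detector grid."""
    segments_mm = np.asarray(segments_mm, dtype=float)
    p0 = scene.mm_to_pixel(segments_mm[:, 0])
    p1 = scene.mm_to_pixel(segments_mm[:, 1])
    px = _sample_segments_px(p0, p1)
    h, w = scene.image_size
    inb = (px[:, 0] >= 0) & (px[:, 0] < h) & (px[:, 1] >= 0) & (px[:, 1] < w)
    if not np.any(inb):
        raise ValidationError(
            f"all rasterized points fall outside the {h}x{w} image bounds"
        )
    img = np.zeros((h, w), dtype=bool)
    img[px[inb, 0], px[inb, 1]] = True
    return EdgeImage(img, scene.pixel_spacing, provenance=provenance)


def rasterize_contour(
    points2d: np.ndarray, scene: RadiographicScene, close: bool = False,
    provenance: str = "ray-cast projection",
) -> EdgeImage:
    """Connect ordered 2D mm points with line segments (Bresenham-style
    8-connected runs) into a binary contour image."""
    pts = np.atleast_2d(np.asarray(points2d, dtype=float))
    if len(pts) < 2:
        raise ValidationError("a contour needs at least 2 points")
    if close:
        pts = np.vstack([pts, pts[:1]])
    segments = np.stack([pts[:-1], pts[1:]], axis=1)
    return rasterize_segments(segments, scene, provenance=provenance)


def render_silhouette(
    surface: TriangleSurface, scene: RadiographicScene
) -> EdgeImage:
    """Forward model: silhouette edges ray-cast from the source onto the
    detector and rasterized into a binary edge image."""
    rc = project_silhouette_pixels(surface, scene)
    h, w = scene.image_size
    img = np.zeros((h, w), dtype=bool)
    img[rc[:, 0], rc[:, 1]] = True
    return EdgeImage(img, scene.pixel_spacing, provenance="ray-cast projection")


def project_silhouette_pixels(
    surface: TriangleSurface, scene: RadiographicScene
) -> np.ndarray:
    """In-bounds foreground (row, col) pixels of the projected silhouette
    (the fast path shared by :func:`render_silhouette` and the registration
    cost)."""
    edges = extract_silhouette_edges(surface, scene.source_point)
    endpoints = surface.vertices[edges.ravel()]
    uv = project_to_detector(endpoints, scene)
    if len(uv) != len(endpoints):  # parallel rays dropped: fall back per-edge
        uv_all = np.full((len(endpoints), 2), np.nan)
        # recompute keeping alignment
        src = scene.source_point
        d = endpoints - src
        denom = src[2] - endpoints[:, 2]
        ok = np.abs(denom) > 1e-12
        t = np.zeros(len(endpoints))
        t[ok] = src[2] / denom[ok]
        hit = src + t[:, None] * d
        u_ax, v_ax = scene.detector_axes
        uv_all[ok] = np.column_stack([hit[ok] @ u_ax, hit[ok] @ v_ax])
        uv_pairs = uv_all.reshape(-1, 2, 2)
        good = ~np.isnan(uv_pairs).any(axis=(1, 2))
        uv_pairs = uv_pairs[good]
    else:
        uv_pairs = uv.reshape(-1, 2, 2)
    if len(uv_pairs) == 0:
        raise ValidationError("no projectable silhouette edges")
    p0 = scene.mm_to_pixel(uv_pairs[:, 0])
    p1 = scene.mm_to_pixel(uv_pairs[:, 1])
    px = _sample_segments_px(p0, p1)
    h, w = scene.image_size
    inb = (px[:, 0] >= 0) & (px[:, 0] < h) & (px[:, 1] >= 0) & (px[:, 1] < w)
    px = px[inb]
    if len(px) == 0:
        raise ValidationError(
            "silhouette projects fully outside the image; re-center the model"
        )
    return np.unique(px, axis=0)


# ---------------------------------------------------------------------------
# contour cost
# ---------------------------------------------------------------------------

def _cost_from_pixels(
    model_rc: np.ndarray,
    radiograph_dt: np.ndarray,
    radiograph_rc: np.ndarray,
    pixel_spacing: float,
) -> float:
    """Symmetric mean distance-transform cost (mm) from pixel sets.

    Term 1 samples the radiograph's distance transform at model pixels;
    term 2 is the mean nearest-model-pixel distance over radiograph pixels
    (computed by KD-tree query, which equals the model image's distance
    transform sampled at those pixels).
    """
    term1 = float(radiograph_dt[model_rc[:, 0], model_rc[:, 1]].mean())
    dist, _ = cKDTree(model_rc).query(radiograph_rc)
    term2 = float(dist.mean())
    return (term1 + term2) * pixel_spacing


def contour_cost(model_edges: EdgeImage, radiograph_edges: EdgeImage) -> float:
    """Symmetric mean distance between two binary edge images, in mm.

    cost = mean over model pixels of distance to the nearest radiograph
    pixel + mean over radiograph pixels of distance to the nearest model
    pixel.  Zero iff the foreground sets coincide; symmetric by
    construction.
    """
    if model_edges.pixels.shape != radiograph_edges.pixels.shape:
        raise ValidationError("edge images must share one pixel grid")
    if abs(model_edges.pixel_spacing - radiograph_edges.pixel_spacing) > 1e-12:
        raise ValidationError("edge images must share one pixel spacing")
    if model_edges.n_foreground == 0 or radiograph_edges.n_foreground == 0:
        raise ValidationError("contour cost undefined for an empty edge image")
    return _cost_from_pixels(
        model_edges.foreground_pixels,
        radiograph_edges.distance_transform,
        radiograph_edges.foreground_pixels,
        model_edges.pixel_spacing,
    )
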