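"""Triangle-mesh surfaces and rigid-body poses.

All coordinates are millimetres in a right-handed frame; rotations are
degrees.  A :class:`TriangleSurface` carries one bone (femur or tibia) as an
indexed triangle mesh; a :class:`RigidPose` is a 6-DOF transform
(three translations, three intrinsic z-y-x Euler rotations).

File I/O covers the three mesh formats segmentation pipelines commonly emit
(STL ASCII/binary, ASCII PLY, OBJ).  Loading merges duplicate vertices and
drops degenerate (zero-area) facets so that downstream normal and area
computations are well defined.
"""

from __future__ import annotations

import dataclasses
import logging
import struct
from functools import cached_property
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

#: facets with area below this (mm^2) are dropped at load time
DEGENERATE_AREA = 1e-12
#: duplicate vertices closer than this (mm) are merged at load time
MERGE_TOLERANCE = 1e-6


class ValidationError(ValueError):
    """An input violates a documented precondition or mesh invariant."""


# ---------------------------------------------------------------------------
# rigid poses
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RigidPose:
    """6-DOF rigid transform: translation (mm) and intrinsic z-y-x Euler
    rotation (degrees).

    The rotation matrix is ``Rz(rz) @ Ry(ry) @ Rx(rx)``.  The pose's
    homogeneous matrix (:meth:`matrix`) rotates about a caller-supplied
    centre (default: the origin) and then translates.
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vector)):
            raise ValidationError(f"non-finite pose components: {self.vector}")

    @property
    def vector(self) -> np.ndarray:
        """(tx, ty, tz, rx, ry, rz) as a float array."""
        return np.array(
            [self.tx, self.ty, self.tz, self.rx, self.ry, self.rz], dtype=float
        )

    @classmethod
    def from_vector(cls, x) -> "RigidPose":
        x = np.asarray(x, dtype=float)
        if x.shape != (6,):
            raise ValidationError(f"pose vector must have 6 components, got {x.shape}")
        return cls(*x)

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler("ZYX", [self.rz, self.ry, self.rx], degrees=True)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz], dtype=float)

    def matrix(self, center=None) -> np.ndarray:
        """4x4 homogeneous matrix rotating about ``center`` then translating."""
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        R = self.rotation.as_matrix()
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c - R @ c + self.translation
        return M

    @classmethod
    def from_matrix(cls, M) -> "RigidPose":
        M = np.asarray(M, dtype=float)
        rz, ry, rx = Rotation.from_matrix(M[:3, :3]).as_euler("ZYX", degrees=True)
        tx, ty, tz = M[:3, 3]
        return cls(tx, ty, tz, rx, ry, rz)

    def inverse(self) -> "RigidPose":
        """Pose whose origin-centred matrix is the inverse of this pose's."""
        return RigidPose.from_matrix(np.linalg.inv(self.matrix()))

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Pose equivalent to applying ``other`` first, then ``self``
        (origin-centred matrices: ``self.matrix() @ other.matrix()``)."""
        return RigidPose.from_matrix(self.matrix() @ other.matrix())

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(np.all(np.abs(self.vector) <= tol))


def compose(p1: RigidPose, p2: RigidPose) -> RigidPose:
    """Functional form of :meth:`RigidPose.compose`."""
    return p1.compose(p2)


def pose_to_matrix(pose: RigidPose, center=None) -> np.ndarray:
    return pose.matrix(center)


# ---------------------------------------------------------------------------
# triangle surfaces
# ---------------------------------------------------------------------------

@dataclasses.dataclass(eq=False)
class TriangleSurface:
    """An indexed triangle mesh for one bone.

    Attributes
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices (outward counter-clockwise
        winding for closed surfaces)
    label : bone identity, e.g. ``"femur"`` or ``"tibia"``
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError(f"faces must be (m, 3), got {self.faces.shape}")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValidationError("face vertex index out of range")

    # -- derived geometry (cached; invalidated by replace(), not mutation) --

    @cached_property
    def _tri(self) -> np.ndarray:
        return self.vertices[self.faces]  # (m, 3, 3)

    @cached_property
    def _cross(self) -> np.ndarray:
        t = self._tri
        return np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])

    @cached_property
    def face_areas(self) -> np.ndarray:
        """Per-facet area, mm^2 (half cross-product norm)."""
        return 0.5 * np.linalg.norm(self._cross, axis=1)

    @cached_property
    def face_normals(self) -> np.ndarray:
        """Unit outward facet normals."""
        n = np.linalg.norm(self._cross, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self._cross / n[:, None]

    @cached_property
    def face_centroids(self) -> np.ndarray:
        return self._tri.mean(axis=1)

    @property
    def centroid(self) -> np.ndarray:
        """Mean vertex position (the rotation centre used by default)."""
        return self.vertices.mean(axis=0)

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    @property
    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive for closed outward-wound
        surfaces."""
        t = self._tri
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    @cached_property
    def edges(self) -> np.ndarray:
        """(e, 2) unique undirected edges (sorted vertex index pairs)."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    @cached_property
    def edge_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """``(edges, face_lists)``: for each unique undirected edge, the
        indices of its incident faces (-1 padding, up to the max incidence)."""
        e = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        face_idx = np.tile(np.arange(len(self.faces)), 3)
        uniq, inverse, counts = np.unique(
            e, axis=0, return_inverse=True, return_counts=True
        )
        order = np.argsort(inverse, kind="stable")
        max_inc = int(counts.max()) if len(counts) else 0
        table = np.full((len(uniq), max_inc), -1, dtype=np.int64)
        starts = np.concatenate([[0], np.cumsum(counts)])
        sorted_faces = face_idx[order]
        for slot in range(max_inc):
            sel = counts > slot
            table[sel, slot] = sorted_faces[starts[:-1][sel] + slot]
        return uniq, table

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any broken invariant."""
        if len(self.faces) == 0:
            raise ValidationError("surface has no faces")
        if self.face_areas.min() <= DEGENERATE_AREA:
            raise ValidationError("surface contains degenerate (zero-area) faces")
        norms = np.linalg.norm(self.face_normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValidationError("face normals are not unit length")

    def replace(self, **kw) -> "TriangleSurface":
        """Copy with some fields replaced (derived caches recomputed)."""
        return TriangleSurface(
            vertices=kw.get("vertices", self.vertices.copy()),
            faces=kw.get("faces", self.faces.copy()),
            label=kw.get("label", self.label),
        )


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def apply_pose(surface: TriangleSurface, pose: RigidPose, center=None) -> TriangleSurface:
    """Apply ``pose`` to ``surface``: rotate about ``center`` (default the
    surface centroid at call time) then translate.

    The identity pose returns bit-identical vertices; rigid transforms
    preserve facet areas.
    """
    if pose.is_identity(tol=0.0):
        return surface.replace()
    c = surface.centroid if center is None else np.asarray(center, dtype=float)
    R = pose.rotation.as_matrix()
    verts = (surface.vertices - c) @ R.T + c + pose.translation
    return surface.replace(vertices=verts)


def surface_geometry(surface: TriangleSurface) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-facet ``(centroids, normals, areas)``."""
    return surface.face_centroids, surface.face_normals, surface.face_areas


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def merge_duplicate_vertices(
    surface: TriangleSurface, tolerance: float = MERGE_TOLERANCE
) -> TriangleSurface:
    """Merge vertices closer than ``tolerance`` (snap-to-grid at half the
    tolerance, exact for true duplicates); face topology is re-indexed."""
    key = np.round(surface.vertices / tolerance).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    verts = surface.vertices[first]
    faces = inverse[surface.faces]
    return TriangleSurface(verts, faces, surface.label)


def drop_degenerate_faces(
    surface: TriangleSurface, min_area: float = DEGENERATE_AREA
) -> TriangleSurface:
    """Remove zero-area facets (including collapsed faces with repeated
    vertex indices); the dropped count is logged."""
    collapsed = (
        (surface.faces[:, 0] == surface.faces[:, 1])
        | (surface.faces[:, 1] == surface.faces[:, 2])
        | (surface.faces[:, 2] == surface.faces[:, 0])
    )
    keep = (~collapsed) & (surface.face_areas > min_area)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d degenerate faces from %r", dropped, surface.label)
    return TriangleSurface(surface.vertices.copy(), surface.faces[keep], surface.label)


def check_manifold(surface: TriangleSurface, max_fraction: float = 0.0) -> None:
    """Raise if the fraction of edges with more than two incident faces
    exceeds ``max_fraction``; the error names offending edges."""
    edges, table = surface.edge_faces
    bad = (table >= 0).sum(axis=1) > 2
    n_bad = int(bad.sum())
    if len(edges) and n_bad / len(edges) > max_fraction:
        offending = edges[bad][:10].tolist()
        raise ValidationError(
            f"{n_bad}/{len(edges)} non-manifold edges (first: {offending})"
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_FORMATS = ("stl", "ply", "obj")


def _format_from_path(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValidationError(f"unsupported mesh format {fmt!r} (use one of {_FORMATS})")
    return fmt


def load_surface(
    path,
    fmt: str | None = None,
    label: str = "",
    max_nonmanifold_fraction: float = 0.0,
) -> TriangleSurface:
    """Load a triangulated bone surface from STL/PLY/OBJ.

    Duplicate vertices (within 1e-6 mm) are merged and zero-area facets are
    dropped with a logged count.  Edges incident to more than two faces
    beyond ``max_nonmanifold_fraction`` raise a :class:`ValidationError`.
    """
    path = Path(path)
    fmt = _format_from_path(path, fmt)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    try:
        if fmt == "stl":
            verts, faces = _read_stl(path)
        elif fmt == "ply":
            verts, faces = _read_ply(path)
        else:
            verts, faces = _read_obj(path)
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface a parse failure as I/O
        raise IOError(f"could not parse {path} as {fmt}: {exc}") from exc
    surf = TriangleSurface(verts, faces, label or path.stem)
    surf = merge_duplicate_vertices(surf)
    surf = drop_degenerate_faces(surf)
    check_manifold(surf, max_fraction=max_nonmanifold_fraction)
    return surf


def save_surface(surface: TriangleSurface, path, fmt: str | None = None) -> None:
    """Write ``surface`` as ASCII STL, ASCII PLY, or OBJ (by extension)."""
    path = Path(path)
    fmt = _format_from_path(path, fmt)
    if fmt == "stl":
        _write_stl_ascii(surface, path)
    elif fmt == "ply":
        _write_ply(surface, path)
    else:
        _write_obj(surface, path)


def _read_stl(path: Path) -> tuple[np.ndarray, np.ndarray]:
    raw = path.read_bytes()
    if raw[:5].lower() == b"solid":
        try:
            return _read_stl_ascii(raw.decode("latin-1"))
        except Exception:  # some binary files begin with "solid"
            pass
    return _read_stl_binary(raw)


def _read_stl_ascii(text: str) -> tuple[np.ndarray, np.ndarray]:
    coords = []
    for line in text.splitlines():
        parts = line.split()
        if parts and parts[0] == "vertex":
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
    verts = np.array(coords, dtype=float)
    if len(verts) == 0 or len(verts) % 3 != 0:
        raise ValueError("ASCII STL vertex count not a multiple of 3")
    faces = np.arange(len(verts), dtype=np.int64).reshape(-1, 3)
    return verts, faces


def _read_stl_binary(raw: bytes) -> tuple[np.ndarray, np.ndarray]:
    if len(raw) < 84:
        raise ValueError("binary STL too short")
    (n,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + n * 50
    if len(raw) < expected:
        raise ValueError("binary STL truncated")
    rec = np.frombuffer(raw, dtype=np.uint8, count=n * 50, offset=84).reshape(n, 50)
    tri = rec[:, 12:48].copy().view("<f4").reshape(n, 3, 3).astype(float)
    verts = tri.reshape(-1, 3)
    faces = np.arange(len(verts), dtype=np.int64).reshape(-1, 3)
    return verts, faces


def _write_stl_ascii(surface: TriangleSurface, path: Path) -> None:
    tri = surface.vertices[surface.faces]
    normals = surface.face_normals
    lines = [f"solid {surface.label or 'surface'}"]
    for t, n in zip(tri, normals):
        lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
        lines.append("    outer loop")
        for v in t:
            lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append(f"endsolid {surface.label or 'surface'}")
    path.write_text("\n".join(lines) + "\n")


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray]:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError("missing ply magic")
    n_vert = n_face = 0
    i = 1
    fmt_ok = False
    while i < len(lines):
        parts = lines[i].split()
        i += 1
        if not parts:
            continue
        if parts[0] == "format":
            fmt_ok = parts[1] == "ascii"
        elif parts[0] == "element" and parts[1] == "vertex":
            n_vert = int(parts[2])
        elif parts[0] == "element" and parts[1] == "face":
            n_face = int(parts[2])
        elif parts[0] == "end_header":
            break
    if not fmt_ok:
        raise ValueError("only ASCII PLY is supported")
    verts = np.array(
        [[float(x) for x in lines[i + j].split()[:3]] for j in range(n_vert)]
    )
    faces = []
    for j in range(n_face):
        parts = [int(x) for x in lines[i + n_vert + j].split()]
        if parts[0] != 3:
            raise ValueError("PLY faces must be triangles")
        faces.append(parts[1:4])
    return verts, np.array(faces, dtype=np.int64).reshape(-1, 3)


def _write_ply(surface: TriangleSurface, path: Path) -> None:
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(surface.vertices)}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {len(surface.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines += [f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}" for v in surface.vertices]
    lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in surface.faces]
    path.write_text("\n".join(lines) + "\n")


def _read_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    verts, faces = [], []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(parts[1]), float(parts[2]), float(parts[3])])
        elif parts[0] == "f":
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
            # fan-triangulate polygonal faces
            for k in range(1, len(idx) - 1):
                faces.append([idx[0], idx[k], idx[k + 1]])
    if not verts or not faces:
        raise ValueError("OBJ file has no geometry")
    return np.array(verts, dtype=float), np.array(faces, dtype=np.int64)


def _write_obj(surface: TriangleSurface, path: Path) -> None:
    lines = [f"v {v[0]:.12g} {v[1]:.12g} {v[2]:.12g}" for v in surface.vertices]
    lines += [f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}" for f in surface.faces]
    path.write_text("\n".join(lines) + "\n")
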