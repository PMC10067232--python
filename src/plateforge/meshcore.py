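"""Triangle-mesh data model, STL I/O, and proximity queries.

All coordinates are millimetres throughout the package (STL itself is
unitless; the mm convention is fixed here and documented in the CLI help).
Meshes are plain vertex/face arrays; spatial acceleration structures are
built lazily and are invisible to callers — the contract of every query is
equality with the exhaustive per-triangle result.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceMesh",
    "ClosestPointResult",
    "STLParseError",
    "read_stl",
    "write_stl",
    "vertex_normal",
    "closest_point",
    "closest_points",
    "min_clearance",
    "meshes_intersect",
    "weld",
    "concatenate",
    "repair_orientation",
]


class STLParseError(ValueError):
    """Raised on malformed STL input; carries the offending byte offset."""

    def __init__(self, message: str, byte_offset: Optional[int] = None):
        if byte_offset is not None:
            message = f"{message} (byte offset {byte_offset})"
        super().__init__(message)
        self.byte_offset = byte_offset


@dataclass(frozen=True)
class ClosestPointResult:
    """Closest point on a mesh to a query point.

    ``normal`` is the unit face normal of ``face_index``; vertex/edge ties
    are resolved toward the lowest face index.
    """

    point: np.ndarray
    face_index: int
    distance: float
    normal: np.ndarray


class SurfaceMesh:
    """Triangulated surface: ``vertices`` (n, 3) float64 mm, ``faces`` (m, 3) int.

    Invariants enforced at construction: all face indices in range, no face
    with a repeated vertex index. Orientation consistency is not enforced
    (use :func:`repair_orientation`).
    """

    def __init__(self, vertices, faces, metadata: Optional[dict] = None,
                 validate: bool = True):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64).reshape(-1, 3)
        self.metadata = dict(metadata) if metadata else {}
        self._cache: dict = {}
        if validate and len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("face with repeated vertex index")

    # -- basic measures -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(),
                           metadata=dict(self.metadata), validate=False)

    def with_vertices(self, vertices) -> "SurfaceMesh":
        return SurfaceMesh(vertices, self.faces.copy(),
                           metadata=dict(self.metadata), validate=False)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_cross(self) -> np.ndarray:
        """Unnormalized face normals (cross products); magnitude = 2*area."""
        t = self.triangles
        return np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])

    @property
    def face_normals(self) -> np.ndarray:
        if "face_normals" not in self._cache:
            c = self.face_cross()
            n = np.linalg.norm(c, axis=1)
            out = np.zeros_like(c)
            ok = n > 0
            out[ok] = c[ok] / n[ok, None]
            self._cache["face_normals"] = out
        return self._cache["face_normals"]

    @property
    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_cross(), axis=1)

    def surface_area(self) -> float:
        return float(self.face_areas.sum())

    def volume(self) -> float:
        """Signed enclosed volume via the divergence theorem."""
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0],
                               np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array [min_corner, max_corner]."""
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    # -- topology -------------------------------------------------------

    def _edge_maps(self):
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                            self.faces[:, [2, 0]]])
        und = np.sort(e, axis=1)
        return e, und

    def boundary_edge_count(self) -> int:
        _, und = self._edge_maps()
        _, counts = np.unique(und, axis=0, return_counts=True)
        return int(np.sum(counts == 1))

    def is_watertight(self) -> bool:
        if self.is_empty:
            return False
        _, und = self._edge_maps()
        _, counts = np.unique(und, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def is_orientation_consistent(self) -> bool:
        e, _ = self._edge_maps()
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 1))

    # -- acceleration ---------------------------------------------------

    def _proximity(self) -> "_ProximityQuery":
        if "prox" not in self._cache:
            self._cache["prox"] = _ProximityQuery(self)
        return self._cache["prox"]


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------

_HEADER_TEXT = b"plateforge binary STL; units: mm"


def read_stl(path: Union[str, Path]) -> SurfaceMesh:
    """Read a binary or ASCII STL file.

    Vertices are deduplicated by exact coordinate equality (deterministic
    topology); use :func:`weld` for tolerance-based merging. Coordinates are
    interpreted as millimetres.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) >= 84:
        (count,) = struct.unpack_from("<I", raw, 80)
        if len(raw) == 84 + 50 * count:
            return _parse_binary(raw, count)
    if raw[:5].lower() == b"solid":
        return _parse_ascii(raw)
    if len(raw) < 84:
        raise STLParseError(f"file too short for binary STL ({len(raw)} bytes)",
                            byte_offset=len(raw))
    (count,) = struct.unpack_from("<I", raw, 80)
    raise STLParseError(
        f"binary STL facet count {count} implies {84 + 50 * count} bytes, "
        f"file has {len(raw)}", byte_offset=80)


def _parse_binary(raw: bytes, count: int) -> SurfaceMesh:
    if count == 0:
        logger.warning("binary STL with zero facets: returning empty mesh")
        return SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int),
                           validate=False)
    body = np.frombuffer(raw, dtype=np.uint8, count=50 * count, offset=84)
    rec = body.reshape(count, 50)
    tri = rec[:, 12:48].copy().view("<f4").reshape(count, 3, 3).astype(np.float64)
    return _from_triangle_soup(tri)


def _parse_ascii(raw: bytes) -> SurfaceMesh:
    try:
        text = raw.decode("ascii", errors="strict")
    except UnicodeDecodeError as exc:
        raise STLParseError("non-ASCII bytes in ASCII STL",
                            byte_offset=exc.start) from exc
    tokens = text.split()
    tris = []
    i = 0
    n = len(tokens)
    # byte offsets of each token for error reporting
    while i < n:
        tok = tokens[i]
        if tok == "vertex":
            if i + 3 >= n:
                raise STLParseError("truncated vertex record", byte_offset=len(raw))
            try:
                v = [float(tokens[i + 1]), float(tokens[i + 2]), float(tokens[i + 3])]
            except ValueError:
                off = text.find(tokens[i + 1])
                raise STLParseError("unparseable vertex coordinate",
                                    byte_offset=off if off >= 0 else None)
            tris.append(v)
            i += 4
        else:
            i += 1
    if len(tris) % 3 != 0:
        raise STLParseError(f"vertex count {len(tris)} not a multiple of 3",
                            byte_offset=len(raw))
    if not tris:
        logger.warning("ASCII STL with zero facets: returning empty mesh")
        return SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int),
                           validate=False)
    tri = np.asarray(tris, dtype=np.float64).reshape(-1, 3, 3)
    return _from_triangle_soup(tri)


def _from_triangle_soup(tri: np.ndarray) -> SurfaceMesh:
    flat = tri.reshape(-1, 3)
    verts, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    # drop faces that collapsed to a repeated index (degenerate input facets)
    bad = (faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2]) | \
          (faces[:, 0] == faces[:, 2])
    if bad.any():
        logger.warning("dropping %d degenerate STL facets", int(bad.sum()))
        faces = faces[~bad]
    return SurfaceMesh(verts, faces, validate=False)


def write_stl(mesh: SurfaceMesh, path: Union[str, Path], mode: str = "binary") -> None:
    """Write *mesh* as binary (default) or ASCII STL.

    Facet normals are recomputed from the winding; zero-area facets get a
    zero normal (with a warning). Binary layout: 80-byte header, uint32
    facet count, 50 bytes per facet, little-endian.
    """
    if mesh.is_empty:
        raise ValueError("refusing to write an empty mesh")
    if mode not in ("binary", "ascii"):
        raise ValueError(f"mode must be 'binary' or 'ascii', got {mode!r}")
    path = Path(path)
    tri = mesh.triangles.astype(np.float32)
    normals = mesh.face_normals.astype(np.float32)
    n_zero = int(np.sum(np.linalg.norm(normals, axis=1) == 0))
    if n_zero:
        logger.warning("writing %d zero-area facets with zero normals", n_zero)
    if mode == "binary":
        count = len(tri)
        rec = np.zeros((count, 50), dtype=np.uint8)
        block = np.concatenate([normals[:, None, :], tri], axis=1)  # (m, 4, 3)
        rec[:, 0:48] = np.frombuffer(
            np.ascontiguousarray(block, dtype="<f4").tobytes(),
            dtype=np.uint8).reshape(count, 48)
        header = _HEADER_TEXT.ljust(80, b"\0")
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(struct.pack("<I", count))
            fh.write(rec.tobytes())
    else:
        lines = ["solid plateforge"]
        for nrm, t in zip(normals, tri):
            lines.append(f"  facet normal {nrm[0]:.9e} {nrm[1]:.9e} {nrm[2]:.9e}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid plateforge")
        path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# normals
# ---------------------------------------------------------------------------

def vertex_normal(mesh: SurfaceMesh, vertex_index: int) -> np.ndarray:
    """Area-weighted average of incident face normals, normalized.

    Raises for isolated vertices. Requires a consistently oriented mesh for
    a meaningful result.
    """
    incident = np.nonzero(np.any(mesh.faces == vertex_index, axis=1))[0]
    if len(incident) == 0:
        raise ValueError(f"vertex {vertex_index} has no incident faces")
    # cross products carry the area weighting
    acc = mesh.face_cross()[incident].sum(axis=0)
    norm = np.linalg.norm(acc)
    if norm == 0:
        raise ValueError(f"degenerate normal at vertex {vertex_index}")
    return acc / norm


def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Area-weighted normals for all vertices (zero where degenerate)."""
    if "vertex_normals" in mesh._cache:
        return mesh._cache["vertex_normals"]
    cross = mesh.face_cross()
    acc = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], cross)
    norms = np.linalg.norm(acc, axis=1)
    ok = norms > 0
    acc[ok] /= norms[ok, None]
    mesh._cache["vertex_normals"] = acc
    return acc


def interpolated_normal(mesh: SurfaceMesh, result: ClosestPointResult) -> np.ndarray:
    """Smoothly varying surface normal at a closest-point result.

    Barycentric interpolation of the area-weighted vertex normals (Phong);
    falls back to the face normal where degenerate.
    """
    a, b, c = mesh.vertices[mesh.faces[result.face_index]]
    vn = vertex_normals(mesh)[mesh.faces[result.face_index]]
    v0, v1, v2 = b - a, c - a, result.point - a
    d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
    d20, d21 = v2 @ v0, v2 @ v1
    denom = d00 * d11 - d01 * d01
    if denom == 0:
        return result.normal
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    bary = np.array([1.0 - v - w, v, w]).clip(0.0, 1.0)
    n = bary @ vn
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        return result.normal
    return n / norm


# ---------------------------------------------------------------------------
# point-triangle distance (Ericson closest-point construction, vectorized
# over triangles for a single query point)
# ---------------------------------------------------------------------------

def _closest_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                          c: np.ndarray) -> np.ndarray:
    """Closest points to ``p`` on each triangle (a[i], b[i], c[i]); (m, 3)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    # vertex A
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    # vertex B
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1 - d3
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, d1 / denom, 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m
    # vertex C
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2 - d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom != 0, d2 / denom, 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m
    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m
    # interior
    m = ~done
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class _ProximityQuery:
    """KD-tree accelerated closest-point queries; result equals brute force."""

    def __init__(self, mesh: SurfaceMesh):
        self.mesh = mesh
        tri = mesh.triangles
        self.centroids = tri.mean(axis=1)
        self.radii = np.linalg.norm(tri - self.centroids[:, None, :],
                                    axis=2).max(axis=1)
        self.r_max = float(self.radii.max()) if len(self.radii) else 0.0
        self.vtree = cKDTree(mesh.vertices)
        self.ctree = cKDTree(self.centroids)
        self.tri = tri

    def query_one(self, point: np.ndarray) -> ClosestPointResult:
        p = np.asarray(point, dtype=np.float64).reshape(3)
        d_vert, _ = self.vtree.query(p)
        # every triangle achieving the minimum distance d* <= d_vert has its
        # centroid within d* + r_max; widen slightly for float safety
        radius = d_vert + self.r_max + 1e-9
        cand = np.asarray(sorted(self.ctree.query_ball_point(p, radius)),
                          dtype=np.int64)
        if len(cand) == 0:  # pragma: no cover - radius always catches >=1
            cand = np.arange(len(self.tri))
        pts = _closest_on_triangles(p, self.tri[cand, 0], self.tri[cand, 1],
                                    self.tri[cand, 2])
        d = np.linalg.norm(pts - p, axis=1)
        best = int(np.argmin(d))  # candidates sorted: first min = lowest face
        fi = int(cand[best])
        return ClosestPointResult(point=pts[best], face_index=fi,
                                  distance=float(d[best]),
                                  normal=self.mesh.face_normals[fi].copy())

    def distances(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        n = len(points)
        m = len(self.tri)
        d_vert, _ = self.vtree.query(points)
        k = min(32, m)
        dc, ic = self.ctree.query(points, k=k)
        if k == 1:
            dc = dc[:, None]
            ic = ic[:, None]
        # exact distances to the k nearest-centroid triangles, vectorized
        flat_idx = ic.reshape(-1)
        rep_pts = np.repeat(points, k, axis=0)
        cp = _closest_on_triangles(rep_pts, self.tri[flat_idx, 0],
                                   self.tri[flat_idx, 1], self.tri[flat_idx, 2])
        out = np.linalg.norm(cp - rep_pts, axis=1).reshape(n, k).min(axis=1)
        if k < m:
            # candidates are guaranteed complete only when the kth centroid
            # lies beyond the d_vert + r_max bound; redo the rest exactly
            unsure = np.nonzero(dc[:, -1] < d_vert + self.r_max + 1e-9)[0]
            for i in unsure:
                p = points[i]
                cand = self.ctree.query_ball_point(p, d_vert[i] + self.r_max + 1e-9)
                idx = np.asarray(cand, dtype=np.int64)
                pts = _closest_on_triangles(p, self.tri[idx, 0],
                                            self.tri[idx, 1], self.tri[idx, 2])
                out[i] = np.linalg.norm(pts - p, axis=1).min()
        return out


def closest_point(mesh: SurfaceMesh, query) -> ClosestPointResult:
    """Global closest point on *mesh* to *query* (faces, edges, vertices).

    Ties between faces (query on a shared edge/vertex) resolve to the lowest
    face index, matching a first-occurrence argmin over all triangles.
    """
    if mesh.is_empty:
        raise ValueError("closest_point on empty mesh")
    return mesh._proximity().query_one(np.asarray(query, dtype=np.float64))


def closest_points(mesh: SurfaceMesh, queries) -> list[ClosestPointResult]:
    prox = mesh._proximity()
    return [prox.query_one(q) for q in np.asarray(queries, dtype=np.float64).reshape(-1, 3)]


def surface_distances(mesh: SurfaceMesh, points) -> np.ndarray:
    """Unsigned distances from each point to the mesh surface."""
    return mesh._proximity().distances(points)


# ---------------------------------------------------------------------------
# triangle-triangle intersection (Moller interval test)
# ---------------------------------------------------------------------------

def _tri_tri_intersect(t1: np.ndarray, t2: np.ndarray, eps: float = 1e-12) -> bool:
    n1 = np.cross(t1[1] - t1[0], t1[2] - t1[0])
    d2 = (t2 - t1[0]) @ n1
    if np.all(d2 > eps) or np.all(d2 < -eps):
        return False
    n2 = np.cross(t2[1] - t2[0], t2[2] - t2[0])
    d1 = (t1 - t2[0]) @ n2
    if np.all(d1 > eps) or np.all(d1 < -eps):
        return False
    direction = np.cross(n1, n2)
    if np.linalg.norm(direction) <= eps * max(np.linalg.norm(n1), np.linalg.norm(n2), 1.0):
        # coplanar: handled by surface sampling (distance 0 at overlap)
        return False
    i1 = _interval_on_line(t1, d1, direction)
    i2 = _interval_on_line(t2, d2, direction)
    if i1 is None or i2 is None:
        return False
    return max(i1[0], i2[0]) <= min(i1[1], i2[1]) + eps


def _interval_on_line(tri, d, direction):
    proj = tri @ direction
    pos = d > 0
    if pos.sum() in (0, 3):
        # a vertex lies on the plane (|d| <= eps path): clamp to that vertex
        onplane = np.argmin(np.abs(d))
        t = proj[onplane]
        return (t, t)
    # isolate the vertex on one side
    solo = int(np.argmax(pos)) if pos.sum() == 1 else int(np.argmax(~pos))
    others = [i for i in range(3) if i != solo]
    ts = []
    for o in others:
        denom = d[solo] - d[o]
        if denom == 0:
            ts.append(proj[o])
        else:
            frac = d[solo] / denom
            ts.append(proj[solo] + frac * (proj[o] - proj[solo]))
    return (min(ts), max(ts))


def meshes_intersect(mesh_a: SurfaceMesh, mesh_b: SurfaceMesh) -> bool:
    """True if any triangle of A properly intersects any triangle of B."""
    if mesh_a.is_empty or mesh_b.is_empty:
        return False
    pa = mesh_a._proximity()
    pb = mesh_b._proximity()
    # broad phase: centroid balls
    pairs = pa.ctree.query_ball_tree(pb.ctree, pa.r_max + pb.r_max + 1e-9)
    ta, tb = pa.tri, pb.tri
    lo_a = ta.min(axis=1)
    hi_a = ta.max(axis=1)
    lo_b = tb.min(axis=1)
    hi_b = tb.max(axis=1)
    for ia, cand in enumerate(pairs):
        if not cand:
            continue
        idx = np.asarray(cand)
        keep = np.all(lo_a[ia] <= hi_b[idx], axis=1) & \
            np.all(hi_a[ia] >= lo_b[idx], axis=1)
        for ib in idx[keep]:
            if _tri_tri_intersect(ta[ia], tb[ib]):
                return True
    return False


# ---------------------------------------------------------------------------
# clearance
# ---------------------------------------------------------------------------

def _face_samples(mesh: SurfaceMesh, density: float) -> np.ndarray:
    """Deterministic quasi-random surface samples, ~density per mm^2."""
    areas = mesh.face_areas
    counts = np.ceil(areas * density).astype(int)
    total = int(counts.sum())
    if total == 0:
        return np.zeros((0, 3))
    tri = mesh.triangles
    out = np.empty((total, 3))
    pos = 0
    phi1 = 0.7548776662466927  # plastic-number sequence: deterministic
    phi2 = 0.5698402909980532
    for f in range(len(tri)):
        k = counts[f]
        if k == 0:
            continue
        i = np.arange(k)
        r1 = np.mod((i + 1) * phi1 + 0.5, 1.0)
        r2 = np.mod((i + 1) * phi2 + 0.5, 1.0)
        s = np.sqrt(r1)
        b0 = 1.0 - s
        b1 = s * (1.0 - r2)
        b2 = s * r2
        out[pos:pos + k] = (b0[:, None] * tri[f, 0] + b1[:, None] * tri[f, 1]
                            + b2[:, None] * tri[f, 2])
        pos += k
    return out


def min_clearance(mesh_a: SurfaceMesh, mesh_b: SurfaceMesh,
                  sample_density: float = 1.0) -> float:
    """Minimum distance from A (vertices + face samples) to B; 0 on overlap.

    A triangle-pair intersection test runs first; any proper crossing short
    circuits to 0. Otherwise the minimum is taken over A's vertices plus
    quasi-random face samples at ``sample_density`` per mm^2.
    """
    if mesh_a.is_empty or mesh_b.is_empty:
        raise ValueError("min_clearance requires non-empty meshes")
    if meshes_intersect(mesh_a, mesh_b):
        return 0.0
    pts = np.vstack([mesh_a.vertices, _face_samples(mesh_a, sample_density)])
    return float(surface_distances(mesh_b, pts).min())


# ---------------------------------------------------------------------------
# utilities
# ---------------------------------------------------------------------------

def weld(mesh: SurfaceMesh, tolerance: float) -> SurfaceMesh:
    """Merge vertices closer than *tolerance* (grid quantization)."""
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    keys = np.round(mesh.vertices / tolerance).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True,
                                  return_inverse=True)
    verts = mesh.vertices[first]
    faces = inverse[mesh.faces]
    bad = (faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2]) | \
          (faces[:, 0] == faces[:, 2])
    return SurfaceMesh(verts, faces[~bad], metadata=dict(mesh.metadata),
                       validate=False)


def concatenate(meshes: Iterable[SurfaceMesh]) -> SurfaceMesh:
    meshes = list(meshes)
    if not meshes:
        raise ValueError("nothing to concatenate")
    verts = []
    faces = []
    offset = 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + offset)
        offset += len(m.vertices)
    return SurfaceMesh(np.vstack(verts), np.vstack(faces), validate=False)


def repair_orientation(mesh: SurfaceMesh) -> SurfaceMesh:
    """Flip faces so adjacent windings agree; orient outward if watertight."""
    faces = mesh.faces.copy()
    m = len(faces)
    if m == 0:
        return mesh.copy()
    # adjacency over undirected edges
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    owner = np.tile(np.arange(m), 3)  # edges are stacked slot-major
    und = np.sort(edges, axis=1)
    order = np.lexsort((und[:, 1], und[:, 0]))
    und_s, owner_s, edges_s = und[order], owner[order], edges[order]
    same = np.all(und_s[1:] == und_s[:-1], axis=1)
    adj: dict[int, list[tuple[int, bool]]] = {i: [] for i in range(m)}
    for k in np.nonzero(same)[0]:
        f1, f2 = int(owner_s[k]), int(owner_s[k + 1])
        # windings consistent iff the shared edge is traversed oppositely
        consistent = not np.array_equal(edges_s[k], edges_s[k + 1])
        adj[f1].append((f2, consistent))
        adj[f2].append((f1, consistent))
    flipped = np.zeros(m, dtype=bool)
    visited = np.zeros(m, dtype=bool)
    for seed in range(m):
        if visited[seed]:
            continue
        stack = [seed]
        visited[seed] = True
        while stack:
            f = stack.pop()
            for g, consistent in adj[f]:
                if visited[g]:
                    continue
                visited[g] = True
                flipped[g] = flipped[f] ^ (not consistent)
                stack.append(g)
    faces[flipped] = faces[flipped][:, ::-1]
    out = SurfaceMesh(mesh.vertices.copy(), faces, metadata=dict(mesh.metadata),
                      validate=False)
    if out.is_watertight() and out.volume() < 0:
        out = SurfaceMesh(out.vertices, out.faces[:, ::-1],
                          metadata=dict(mesh.metadata), validate=False)
    return out
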