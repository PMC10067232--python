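"""Parametric phantoms with known ground truth.

Everything here is analytic and seeded so every pipeline stage can be
tested without patient data: bone-like surfaces (sphere, torus, swept
elliptical tube as a pubic-ramus analog, flat and ridged sheets), a
two-intensity voxelizer emulating a CT acquisition, plane-cut fractures
with recorded rigid displacements, and noisy on-surface anchor sampling
emulating operator clicks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .imagevol import VoxelVolume
from .meshcore import SurfaceMesh, concatenate
from .reduction import MirrorPlane, RigidTransform

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "FractureGroundTruth",
    "make_phantom",
    "icosphere",
    "box",
    "flat_grid",
    "ridged_grid",
    "torus",
    "swept_tube",
    "voxelize_phantom",
    "fracture_phantom",
    "sample_anchors",
]

DEFAULT_BONE_HU = 1200.0
DEFAULT_BACKGROUND_HU = -100.0
DEFAULT_CT_SPACING = (0.8, 0.8, 3.0)  # mm, emulated acquisition


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom description; same spec -> bit-identical mesh."""

    kind: str  # sphere | torus_segment | swept_tube | flat_grid | ridged_grid
    size: dict = field(default_factory=dict)
    mesh_resolution: float = 2.0  # target edge length, mm
    seed: int = 0

    def __post_init__(self):
        if self.mesh_resolution <= 0:
            raise ValueError("mesh_resolution must be > 0")
        for key, val in self.size.items():
            if isinstance(val, (int, float)) and val <= 0:
                raise ValueError(f"size parameter {key} must be > 0")


@dataclass(frozen=True)
class FractureGroundTruth:
    cut_plane: MirrorPlane
    displacement: RigidTransform
    fragment_ids: tuple = (1, 2)


# ---------------------------------------------------------------------------
# primitive surfaces
# ---------------------------------------------------------------------------

def box(extents=(1.0, 1.0, 1.0), center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Axis-aligned box, 8 vertices / 12 facets, oriented outward.

    Face diagonals all pass through the two extreme corners (0 and 7), so
    those corners see two triangles on each incident face.
    """
    e = np.asarray(extents, dtype=float) / 2.0
    c = np.asarray(center, dtype=float)
    corners = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                        for sz in (-1, 1)], dtype=float)
    verts = corners * e + c
    faces = np.array([
        [0, 1, 3], [0, 3, 2],  # -x
        [4, 6, 7], [4, 7, 5],  # +x
        [0, 4, 5], [0, 5, 1],  # -y
        [2, 3, 7], [2, 7, 6],  # +y
        [0, 2, 6], [0, 6, 4],  # -z
        [1, 5, 7], [1, 7, 3],  # +z
    ])
    return SurfaceMesh(verts, faces)


def icosphere(radius: float = 1.0, subdivisions: int = 3,
              center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Subdivided icosahedron projected onto the sphere (20*4^n faces)."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
    ], dtype=float)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ])
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    for _ in range(subdivisions):
        edge_mid: dict = {}
        new_faces = []
        verts_list = list(verts)
        for f in faces:
            mids = []
            for i in range(3):
                key = tuple(sorted((f[i], f[(i + 1) % 3])))
                if key not in edge_mid:
                    m = verts_list[key[0]] + verts_list[key[1]]
                    m = m / np.linalg.norm(m)
                    edge_mid[key] = len(verts_list)
                    verts_list.append(m)
                mids.append(edge_mid[key])
            a, b, c = f
            ab, bc, ca = mids
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        verts = np.asarray(verts_list)
        faces = np.asarray(new_faces)
    return SurfaceMesh(verts * radius + np.asarray(center, dtype=float), faces)


def _sphere_subdivisions(radius: float, resolution: float) -> int:
    # icosahedron edge ~ 1.05 r; halves per subdivision
    n = int(np.ceil(np.log2(max(1.05 * radius / resolution, 1.0))))
    return int(np.clip(n, 1, 7))


def flat_grid(size_x: float = 100.0, size_y: float = 100.0,
              resolution: float = 2.0, center=(0.0, 0.0, 0.0),
              height_fn: Optional[Callable] = None) -> SurfaceMesh:
    """Open sheet in the z=0 plane (or a heightfield if ``height_fn``)."""
    nx = max(int(round(size_x / resolution)), 1)
    ny = max(int(round(size_y / resolution)), 1)
    xs = np.linspace(-size_x / 2, size_x / 2, nx + 1)
    ys = np.linspace(-size_y / 2, size_y / 2, ny + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gz = height_fn(gx, gy) if height_fn is not None else np.zeros_like(gx)
    verts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    verts += np.asarray(center, dtype=float)
    idx = np.arange((nx + 1) * (ny + 1)).reshape(nx + 1, ny + 1)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate([np.stack([a, b, c], axis=1),
                            np.stack([a, c, d], axis=1)])
    return SurfaceMesh(verts, faces)


def ridged_grid(size_x: float = 100.0, size_y: float = 100.0,
                ridge_height: float = 2.0, ridge_sigma: float = 3.0,
                resolution: float = 2.0, center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Flat sheet with a Gaussian ridge running along y at x=0."""

    def h(gx, gy):
        return ridge_height * np.exp(-0.5 * (gx / ridge_sigma) ** 2)

    return flat_grid(size_x, size_y, resolution, center, height_fn=h)


def torus(major_radius: float = 60.0, minor_radius: float = 8.0,
          resolution: float = 2.0, center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Closed torus around the z axis; analytic normals for alignment tests."""
    nu = max(int(np.ceil(2 * np.pi * major_radius / resolution)), 8)
    nv = max(int(np.ceil(2 * np.pi * minor_radius / resolution)), 8)
    us = np.arange(nu) * (2 * np.pi / nu)
    vs = np.arange(nv) * (2 * np.pi / nv)
    gu, gv = np.meshgrid(us, vs, indexing="ij")
    r = major_radius + minor_radius * np.cos(gv)
    verts = np.stack([r * np.cos(gu), r * np.sin(gu),
                      minor_radius * np.sin(gv)], axis=-1).reshape(-1, 3)
    verts += np.asarray(center, dtype=float)
    idx = np.arange(nu * nv).reshape(nu, nv)
    iu1 = np.roll(idx, -1, axis=0)
    iv1 = np.roll(idx, -1, axis=1)
    iuv = np.roll(iu1, -1, axis=1)
    a, b, c, d = idx.ravel(), iu1.ravel(), iuv.ravel(), iv1.ravel()
    faces = np.concatenate([np.stack([a, b, c], axis=1),
                            np.stack([a, c, d], axis=1)])
    return SurfaceMesh(verts, faces)


def torus_normal(point, major_radius: float, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Analytic outward normal of the torus at (a point near) its surface."""
    p = np.asarray(point, dtype=float) - np.asarray(center, dtype=float)
    axis_pt = p.copy()
    axis_pt[2] = 0.0
    rho = np.linalg.norm(axis_pt[:2])
    ring = axis_pt / rho * major_radius
    n = p - ring
    return n / np.linalg.norm(n)


def swept_tube(arc_radius: float = 60.0, arc_angle: float = 1.7,
               section_a: float = 7.5, section_b: float = 6.0,
               resolution: float = 2.0, center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Elliptical cross-section swept along a circular arc, ends capped.

    A smooth tubular analog of the superior pubic ramus: defaults give a
    ~60 mm arc radius and a 15 x 12 mm section. The arc lies in the z=0
    plane, centered on the +x direction.
    """
    arc_len = arc_radius * arc_angle
    nu = max(int(np.ceil(arc_len / resolution)), 4) + 1
    perim = 2 * np.pi * np.sqrt((section_a ** 2 + section_b ** 2) / 2)
    nv = max(int(np.ceil(perim / resolution)), 8)
    us = np.linspace(-arc_angle / 2, arc_angle / 2, nu)
    vs = np.arange(nv) * (2 * np.pi / nv)
    gu, gv = np.meshgrid(us, vs, indexing="ij")
    # frame along the arc: radial (cos u, sin u, 0), vertical (0,0,1)
    r = arc_radius + section_a * np.cos(gv)
    verts = np.stack([r * np.cos(gu), r * np.sin(gu),
                      section_b * np.sin(gv)], axis=-1).reshape(-1, 3)
    idx = np.arange(nu * nv).reshape(nu, nv)
    iv1 = np.roll(idx, -1, axis=1)
    a = idx[:-1].ravel()
    b = idx[1:].ravel()
    c = iv1[1:].ravel()
    d = iv1[:-1].ravel()
    faces = np.concatenate([np.stack([a, b, c], axis=1),
                            np.stack([a, c, d], axis=1)]).tolist()
    verts_list = list(verts)
    # cap both ends with a fan about the section center
    for end, ring in ((0, idx[0]), (1, idx[-1])):
        u = us[0] if end == 0 else us[-1]
        ctr = np.array([arc_radius * np.cos(u), arc_radius * np.sin(u), 0.0])
        ci = len(verts_list)
        verts_list.append(ctr)
        for k in range(nv):
            v0, v1 = int(ring[k]), int(ring[(k + 1) % nv])
            if end == 0:
                faces.append([ci, v0, v1])
            else:
                faces.append([ci, v1, v0])
    verts = np.asarray(verts_list) + np.asarray(center, dtype=float)
    return SurfaceMesh(verts, np.asarray(faces))


def swept_tube_arc(arc_radius: float = 60.0, arc_angle: float = 1.7,
                   section_a: float = 7.5, section_b: float = 6.0,
                   center=(0.0, 0.0, 0.0)) -> Callable[[float], np.ndarray]:
    """Parametric curve t in [0,1] along the tube's outer equator (z=0)."""
    c = np.asarray(center, dtype=float)

    def curve(t):
        u = (np.asarray(t, dtype=float) - 0.5) * arc_angle
        r = arc_radius + section_a
        return np.stack([r * np.cos(u), r * np.sin(u), np.zeros_like(u)],
                        axis=-1) + c

    return curve


def make_phantom(spec: PhantomSpec) -> SurfaceMesh:
    """Build the phantom surface described by *spec* (deterministic)."""
    s = dict(spec.size)
    res = spec.mesh_resolution
    if spec.kind == "sphere":
        radius = s.get("radius", 20.0)
        return icosphere(radius, _sphere_subdivisions(radius, res),
                         center=s.get("center", (0, 0, 0)))
    if spec.kind == "flat_grid":
        return flat_grid(s.get("size_x", 100.0), s.get("size_y", 100.0), res,
                         center=s.get("center", (0, 0, 0)))
    if spec.kind == "ridged_grid":
        return ridged_grid(s.get("size_x", 100.0), s.get("size_y", 100.0),
                           s.get("ridge_height", 2.0), s.get("ridge_sigma", 3.0),
                           res, center=s.get("center", (0, 0, 0)))
    if spec.kind == "torus_segment":
        return torus(s.get("major_radius", 60.0), s.get("minor_radius", 8.0),
                     res, center=s.get("center", (0, 0, 0)))
    if spec.kind == "swept_tube":
        return swept_tube(s.get("arc_radius", 60.0), s.get("arc_angle", 1.7),
                          s.get("section_a", 7.5), s.get("section_b", 6.0),
                          res, center=s.get("center", (0, 0, 0)))
    raise ValueError(f"unknown phantom kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def voxelize_phantom(mesh: SurfaceMesh, spacing=DEFAULT_CT_SPACING,
                     bone_hu: float = DEFAULT_BONE_HU,
                     background_hu: float = DEFAULT_BACKGROUND_HU,
                     margin: float = 5.0) -> VoxelVolume:
    """Two-intensity voxel phantom: ``bone_hu`` where the voxel center is
    inside the (watertight) mesh, ``background_hu`` elsewhere.

    Inside/outside is decided by z-ray crossing parity per voxel column.
    """
    if not mesh.is_watertight():
        raise ValueError("voxelize_phantom requires a watertight mesh")
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    lo = mesh.bounds[0] - margin
    hi = mesh.bounds[1] + margin
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    origin = lo + spacing / 2.0  # voxel centers
    nx, ny, nz = (int(v) for v in shape)
    inside = _points_inside_grid(mesh, origin, spacing, (nx, ny, nz))
    if not inside.any():
        logger.warning("mesh fell entirely between voxel centers: no bone voxels")
    arr = np.where(inside, bone_hu, background_hu)
    return VoxelVolume(arr, spacing, origin)


def _points_inside_grid(mesh, origin, spacing, shape):
    nx, ny, nz = shape
    # tiny irrational shear of the mesh breaks ray/edge degeneracies
    jit = np.array([1.2345678e-7, 2.3456789e-7, 0.0])
    tri = mesh.triangles + jit
    xs = origin[0] + np.arange(nx) * spacing[0]
    ys = origin[1] + np.arange(ny) * spacing[1]
    zs = origin[2] + np.arange(nz) * spacing[2]
    crossings: dict = {}
    for t in tri:
        txmin, tymin = t[:, 0].min(), t[:, 1].min()
        txmax, tymax = t[:, 0].max(), t[:, 1].max()
        i0 = int(np.searchsorted(xs, txmin))
        i1 = int(np.searchsorted(xs, txmax, side="right"))
        j0 = int(np.searchsorted(ys, tymin))
        j1 = int(np.searchsorted(ys, tymax, side="right"))
        if i0 >= i1 or j0 >= j1:
            continue
        gx, gy = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        p = np.stack([gx.ravel(), gy.ravel()], axis=1)
        a2, b2, c2 = t[0, :2], t[1, :2], t[2, :2]
        det = (b2[0] - a2[0]) * (c2[1] - a2[1]) - (c2[0] - a2[0]) * (b2[1] - a2[1])
        if det == 0:
            continue  # vertical triangle: zero-measure for z rays
        w0 = ((b2[0] - p[:, 0]) * (c2[1] - p[:, 1])
              - (c2[0] - p[:, 0]) * (b2[1] - p[:, 1])) / det
        w1 = ((c2[0] - p[:, 0]) * (a2[1] - p[:, 1])
              - (a2[0] - p[:, 0]) * (c2[1] - p[:, 1])) / det
        w2 = 1.0 - w0 - w1
        hit = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not hit.any():
            continue
        zhit = (w0[hit] * t[0, 2] + w1[hit] * t[1, 2] + w2[hit] * t[2, 2])
        cols_i = (np.repeat(np.arange(i0, i1), j1 - j0))[hit]
        cols_j = (np.tile(np.arange(j0, j1), i1 - i0))[hit]
        for ci, cj, z in zip(cols_i, cols_j, zhit):
            crossings.setdefault((int(ci), int(cj)), []).append(z)
    inside = np.zeros((nx, ny, nz), dtype=bool)
    for (ci, cj), zl in crossings.items():
        zl = np.sort(np.asarray(zl))
        # odd number of crossings above the voxel center => inside
        above = len(zl) - np.searchsorted(zl, zs)
        inside[ci, cj, :] = (above % 2) == 1
    return inside


# ---------------------------------------------------------------------------
# fracture simulation
# ---------------------------------------------------------------------------

def _cut_mesh_by_plane(mesh: SurfaceMesh, point, normal):
    """Split a watertight mesh by a plane; both halves capped and closed.

    Returns (mesh_neg, mesh_pos) for the d<=0 and d>=0 sides. Cap loops are
    fan-triangulated about their centroid (fine for the convex-ish sections
    the phantoms produce).
    """
    point = np.asarray(point, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    d = (mesh.vertices - point) @ normal
    # nudge exact-on-plane vertices to the positive side for determinism
    d = np.where(np.abs(d) < 1e-12, 1e-12, d)

    halves = []
    for side in (-1.0, 1.0):
        ds = d * side
        verts = list(mesh.vertices)
        faces_out = []
        cut_edges = []
        cache: dict = {}

        def split_point(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                t = ds[i] / (ds[i] - ds[j])
                cache[key] = len(verts)
                verts.append(mesh.vertices[i] + t * (mesh.vertices[j] - mesh.vertices[i]))
            return cache[key]

        for f in mesh.faces:
            keep = ds[f] > 0
            nk = int(keep.sum())
            if nk == 0:
                continue
            if nk == 3:
                faces_out.append(list(f))
                continue
            # rotate so the pattern starts at a kept vertex run
            order = [int(f[k]) for k in range(3)]
            kp = [bool(keep[k]) for k in range(3)]
            while not (kp[0] and not kp[2] if nk == 1 else kp[0] and kp[1]):
                order = order[1:] + order[:1]
                kp = kp[1:] + kp[:1]
            v0, v1, v2 = order
            if nk == 1:
                # v0 kept, v1 and v2 dropped
                p01 = split_point(v0, v1)
                p20 = split_point(v2, v0)
                faces_out.append([v0, p01, p20])
                cut_edges.append((p01, p20))
            else:
                # v0, v1 kept, v2 dropped
                p12 = split_point(v1, v2)
                p20 = split_point(v2, v0)
                faces_out.append([v0, v1, p12])
                faces_out.append([v0, p12, p20])
                cut_edges.append((p12, p20))
        if not faces_out:
            halves.append(None)
            continue
        # chain cut edges into loops and cap each with a centroid fan
        nxt = {a: b for a, b in cut_edges}
        loops = []
        seen = set()
        for start in list(nxt):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            cur = nxt.get(start)
            while cur is not None and cur != start:
                loop.append(cur)
                seen.add(cur)
                cur = nxt.get(cur)
            if cur == start and len(loop) >= 3:
                loops.append(loop)
        for loop in loops:
            ctr_idx = len(verts)
            verts.append(np.mean([verts[i] for i in loop], axis=0))
            for k in range(len(loop)):
                a, b = loop[k], loop[(k + 1) % len(loop)]
                faces_out.append([ctr_idx, b, a])
        verts_arr = np.asarray(verts)
        faces_arr = np.asarray(faces_out)
        used = np.unique(faces_arr)
        remap = np.full(len(verts_arr), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        halves.append(SurfaceMesh(verts_arr[used], remap[faces_arr],
                                  validate=False))
    return halves[0], halves[1]


def fracture_phantom(mesh: SurfaceMesh, plane: MirrorPlane,
                     displacement: RigidTransform):
    """Cut a watertight phantom by *plane* and displace the positive-side
    fragment by *displacement*; returns (fragment_a, fragment_b, truth).

    ``fragment_b`` is the displaced one; ``truth.displacement`` maps its
    anatomical (uncut) pose to the displaced pose, so applying the inverse
    reduces the fracture exactly.
    """
    neg, pos = _cut_mesh_by_plane(mesh, plane.point, plane.normal)
    if neg is None or pos is None:
        raise ValueError("cut plane does not intersect the mesh")
    moved = pos.with_vertices(displacement.apply(pos.vertices))
    truth = FractureGroundTruth(cut_plane=plane, displacement=displacement)
    return neg, moved, truth


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def sample_anchors(curve, n: int, noise_sd: float = 0.0, seed: int = 0,
                   mesh: Optional[SurfaceMesh] = None) -> np.ndarray:
    """n points at equal parameter spacing along ``curve`` (callable t->xyz
    or an (m, 3) polyline), plus seeded isotropic Gaussian click noise.

    Points are *not* projected onto any surface; pass them through
    ``plateplan.project_anchors`` (``mesh`` is accepted for convenience and,
    when given, projection is applied here).
    """
    if n < 2:
        raise ValueError("need n >= 2 anchors")
    ts = np.linspace(0.0, 1.0, n)
    if callable(curve):
        pts = np.asarray(curve(ts), dtype=float).reshape(n, 3)
    else:
        poly = np.asarray(curve, dtype=float).reshape(-1, 3)
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        cum = np.concatenate([[0], np.cumsum(seg)])
        s = ts * cum[-1]
        pts = np.stack([np.interp(s, cum, poly[:, k]) for k in range(3)], axis=1)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    if mesh is not None:
        from .plateplan import project_anchors

        pts = project_anchors(mesh, pts)
    return pts
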