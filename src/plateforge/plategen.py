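"""Plate-unit library and chained-unit template generation.

A template is a chain of rigid plate units posed along the adjusted surface
path: each unit's long axis follows the path tangent and its thickness axis
follows the bone surface normal, so the unit profile stays parallel to the
bone. A clearance threshold guards against the template penetrating the
surface: any unit found closer than the threshold is pushed out along its
normal by the smallest sufficient offset (bisection).

The shipped catalog names the four library families but its dimensions are
repository defaults for a generic 3.5 mm reconstruction plate — they are
NOT vendor data and are meant to be edited.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .meshcore import (SurfaceMesh, closest_point, concatenate,
                       interpolated_normal, min_clearance, write_stl)
from .plateplan import (PathParams, SurfacePath, arc_length, build_path,
                        match_length, point_at_arc_length, project_anchors,
                        wrap_path)

logger = logging.getLogger(__name__)

__all__ = [
    "PlateUnitSpec",
    "UnitFrame",
    "PlateTemplate",
    "PenetrationError",
    "DEFAULT_CATALOG",
    "load_unit_library",
    "save_unit_library",
    "unit_mesh",
    "compute_frames",
    "resolve_penetration",
    "assemble_template",
    "export_template",
    "plan_plate",
]


class PenetrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlateUnitSpec:
    """One screw-hole-bearing plate segment (all dimensions mm)."""

    catalog_id: str
    unit_length: float = 12.0
    width: float = 10.0
    thickness: float = 2.8
    hole_diameter: float = 3.6
    hole_segments: int = 32
    standoff: float = 0.5
    clearance_threshold: float = 0.2

    def __post_init__(self):
        for name in ("unit_length", "width", "thickness", "hole_diameter",
                     "standoff", "clearance_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.catalog_id}: {name} must be > 0")
        if self.hole_segments < 3:
            raise ValueError(f"{self.catalog_id}: hole_segments must be >= 3")
        if self.hole_diameter >= self.width:
            raise ValueError(
                f"{self.catalog_id}: hole_diameter must be < width")
        if self.clearance_threshold > self.standoff:
            raise ValueError(
                f"{self.catalog_id}: clearance_threshold must be <= standoff")

    @property
    def diagonal(self) -> float:
        return float(np.linalg.norm([self.unit_length, self.width,
                                     self.thickness]))


# Placeholder dimensions (generic 3.5 mm reconstruction plate), user-editable.
DEFAULT_CATALOG: Dict[str, PlateUnitSpec] = {
    s.catalog_id: s for s in [
        PlateUnitSpec("civic", 12.0, 10.0, 2.8, 3.6),
        PlateUnitSpec("depuy-synthes", 12.0, 10.0, 2.8, 3.6),
        PlateUnitSpec("zimmer", 13.0, 10.0, 3.0, 3.6),
        PlateUnitSpec("in-house", 11.0, 9.0, 2.5, 3.4),
    ]
}


@dataclass(frozen=True)
class UnitFrame:
    """Right-handed orthonormal frame at a unit center on the path."""

    origin: np.ndarray
    tangent: np.ndarray
    normal: np.ndarray
    binormal: np.ndarray
    on_surface: bool = True

    def __post_init__(self):
        for name in ("origin", "tangent", "normal", "binormal"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name),
                                          dtype=float).reshape(3))
        t, n, b = self.tangent, self.normal, self.binormal
        if max(abs(t @ n), abs(t @ b), abs(n @ b)) > 1e-6:
            raise ValueError("frame axes are not orthogonal")
        if np.linalg.norm(np.cross(t, n) - b) > 1e-6:
            raise ValueError("frame is not right-handed (t x n != b)")

    def pose_matrix(self) -> np.ndarray:
        """Local (x=tangent, y=binormal, z=normal) -> world, columns."""
        m = np.eye(4)
        m[:3, 0] = self.tangent
        m[:3, 1] = self.binormal
        m[:3, 2] = self.normal
        m[:3, 3] = self.origin
        return m

    def translated(self, offset: np.ndarray) -> "UnitFrame":
        return replace(self, origin=self.origin + offset)


@dataclass
class PlateTemplate:
    spec: PlateUnitSpec
    frames: List[UnitFrame]
    mesh: SurfaceMesh
    screw_axes: List[Tuple[np.ndarray, np.ndarray]]
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# catalog I/O
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = ("unit_length", "width", "thickness", "hole_diameter")


def load_unit_library(path) -> Dict[str, PlateUnitSpec]:
    """Load a YAML/JSON catalog mapping catalog_id -> unit dimensions."""
    path = Path(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text))
    if not isinstance(data, dict):
        raise ValueError(f"{path}: catalog must be a mapping of entries")
    out: Dict[str, PlateUnitSpec] = {}
    for cid, entry in data.items():
        if not isinstance(entry, dict):
            raise ValueError(f"{path}: entry {cid!r} must be a mapping")
        missing = [f for f in _REQUIRED_FIELDS if f not in entry]
        if missing:
            raise ValueError(
                f"{path}: entry {cid!r} missing field(s) {', '.join(missing)}")
        try:
            out[cid] = PlateUnitSpec(catalog_id=cid, **entry)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: entry {cid!r} invalid: {exc}") from exc
    return out


def save_unit_library(catalog: Dict[str, PlateUnitSpec], path) -> None:
    path = Path(path)
    data = {}
    for cid, spec in catalog.items():
        d = asdict(spec)
        d.pop("catalog_id")
        data[cid] = d
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# unit geometry
# ---------------------------------------------------------------------------

def unit_mesh(spec: PlateUnitSpec) -> SurfaceMesh:
    """Watertight block ``unit_length x width x thickness`` centered at the
    origin with a polygonal through-hole along the thickness (z) axis.

    Local convention: +x long axis, +y width, +z toward the *top* of the
    plate (away from bone).
    """
    L, W, T = spec.unit_length, spec.width, spec.thickness
    r = spec.hole_diameter / 2.0
    n = spec.hole_segments
    angles = (np.arange(n) + 0.5) * (2 * np.pi / n)
    hole2 = np.stack([r * np.cos(angles), r * np.sin(angles)], axis=1)

    # outer loop: rectangle perimeter points at each hole angle + corners
    def perimeter_point(theta):
        c, s = np.cos(theta), np.sin(theta)
        tx = (L / 2) / abs(c) if c != 0 else np.inf
        ty = (W / 2) / abs(s) if s != 0 else np.inf
        t = min(tx, ty)
        return np.array([t * c, t * s])

    corner_angles = [np.arctan2(sy * W / 2, sx * L / 2)
                     for sx, sy in ((1, 1), (-1, 1), (-1, -1), (1, -1))]
    outer_angles = sorted(set(np.mod(np.concatenate([angles, corner_angles]),
                                     2 * np.pi).tolist()))
    outer2 = np.array([perimeter_point(t) for t in outer_angles])

    verts: List[np.ndarray] = []

    def add_ring(pts2, z):
        start = len(verts)
        for p in pts2:
            verts.append(np.array([p[0], p[1], z]))
        return start

    ot = add_ring(outer2, T / 2)   # outer top
    ob = add_ring(outer2, -T / 2)  # outer bottom
    ht = add_ring(hole2, T / 2)    # hole top
    hb = add_ring(hole2, -T / 2)   # hole bottom
    no, nh = len(outer2), n
    faces: List[List[int]] = []

    # annulus triangulation between outer and hole loops (merge by angle)
    def annulus(outer_start, hole_start, top: bool):
        i, j = 0, 0  # indices into outer/hole angle lists
        oa = outer_angles + [outer_angles[0] + 2 * np.pi]
        ha = list(angles) + [angles[0] + 2 * np.pi]
        while i < no or j < nh:
            oi0 = outer_start + (i % no)
            hj0 = hole_start + (j % nh)
            advance_outer = (i < no) and (j >= nh or oa[i + 1] <= ha[j + 1])
            if advance_outer:
                oi1 = outer_start + ((i + 1) % no)
                tri = [oi0, oi1, hj0]
                i += 1
            else:
                hj1 = hole_start + ((j + 1) % nh)
                tri = [oi0, hj1, hj0]
                j += 1
            faces.append(tri if top else tri[::-1])

    annulus(ot, ht, top=True)
    annulus(ob, hb, top=False)
    # outer wall (outward)
    for i in range(no):
        i1 = (i + 1) % no
        faces.append([ob + i, ob + i1, ot + i1])
        faces.append([ob + i, ot + i1, ot + i])
    # hole wall (faces point into the hole)
    for j in range(nh):
        j1 = (j + 1) % nh
        faces.append([hb + j, ht + j1, hb + j1])
        faces.append([hb + j, ht + j, ht + j1])
    mesh = SurfaceMesh(np.asarray(verts), np.asarray(faces))
    # guarantee bounding box is exact despite trig round-off
    v = mesh.vertices
    v[:, 0] = np.clip(v[:, 0], -L / 2, L / 2)
    v[:, 1] = np.clip(v[:, 1], -W / 2, W / 2)
    snap = np.isclose(np.abs(v[:, 0]), L / 2, atol=1e-9)
    v[snap, 0] = np.sign(v[snap, 0]) * L / 2
    snap = np.isclose(np.abs(v[:, 1]), W / 2, atol=1e-9)
    v[snap, 1] = np.sign(v[snap, 1]) * W / 2
    return mesh


def polygon_hole_area(spec: PlateUnitSpec) -> float:
    """Exact area of the polygonal hole (regular n-gon)."""
    n = spec.hole_segments
    r = spec.hole_diameter / 2.0
    return 0.5 * n * r * r * np.sin(2 * np.pi / n)


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

def _orthonormal_frame(origin, tangent, normal, on_surface=True) -> UnitFrame:
    # orthogonalize the tangent against the normal (not vice versa): the
    # normal carries the surface-alignment guarantee, the tangent merely
    # follows the discretized path and can absorb the correction
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    t = np.asarray(tangent, dtype=float)
    t = t - (t @ n) * n
    tn = np.linalg.norm(t)
    if tn < 1e-12:
        raise ValueError("path tangent parallel to surface normal")
    t = t / tn
    b = np.cross(t, n)
    return UnitFrame(origin=np.asarray(origin, dtype=float), tangent=t,
                     normal=n, binormal=b, on_surface=on_surface)


def compute_frames(path: SurfacePath, mesh: SurfaceMesh, unit_count: int,
                   unit_length: float) -> List[UnitFrame]:
    """One frame per unit, centered at arc length ``(i + 0.5) * unit_length``.

    Tangent: central difference along the path. Normal: surface normal at
    the closest point for on-surface stations, sign-matched to the previous
    frame (no flips); bridge stations interpolate between the bounding
    on-surface normals.
    """
    S = arc_length(path)
    if abs(S - unit_count * unit_length) > 1e-6:
        raise ValueError(
            f"path length {S:.6f} != unit_count*unit_length "
            f"{unit_count * unit_length:.6f}; run match_length first")
    delta = min(unit_length / 4.0, 1.0)
    stations = []
    for i in range(unit_count):
        s = (i + 0.5) * unit_length
        origin = point_at_arc_length(path, s)
        p0 = point_at_arc_length(path, max(s - delta, 0.0))
        p1 = point_at_arc_length(path, min(s + delta, S))
        tangent = p1 - p0
        if np.linalg.norm(tangent) == 0:
            raise ValueError(f"zero-length tangent at station {i}")
        # a station is a bridge if its nearest path sample is off-surface
        k = int(np.argmin(np.linalg.norm(path.samples - origin, axis=1)))
        stations.append((origin, tangent, bool(path.on_surface_flags[k])))

    normals: List[Optional[np.ndarray]] = [None] * unit_count
    prev = None
    for i, (origin, tangent, on_surf) in enumerate(stations):
        if not on_surf:
            continue
        # interpolated vertex normals vary smoothly across facet boundaries,
        # keeping unit alignment within ~1 degree on curved surfaces
        n = interpolated_normal(mesh, closest_point(mesh, origin))
        if prev is not None and n @ prev < 0:
            n = -n
        normals[i] = n
        prev = n
    if all(v is None for v in normals):
        raise ValueError("no on-surface stations: cannot orient any frame")
    # bridge stations: interpolate between bounding on-surface normals
    known = [i for i, v in enumerate(normals) if v is not None]
    for i in range(unit_count):
        if normals[i] is not None:
            continue
        lo = max((k for k in known if k < i), default=None)
        hi = min((k for k in known if k > i), default=None)
        if lo is None:
            normals[i] = normals[hi]
        elif hi is None:
            normals[i] = normals[lo]
        else:
            w = (i - lo) / (hi - lo)
            v = (1 - w) * normals[lo] + w * normals[hi]
            normals[i] = v / np.linalg.norm(v)
    frames = [_orthonormal_frame(origin, tangent, nrm, on_surface=on_surf)
              for (origin, tangent, on_surf), nrm in zip(stations, normals)]
    # Gram-Schmidt can swing a normal that was nearly parallel to the
    # tangent; re-apply the sign agreement on the final axes (flipping n and
    # b together preserves orthonormality and handedness)
    for i in range(1, len(frames)):
        if frames[i].normal @ frames[i - 1].normal < 0:
            frames[i] = replace(frames[i], normal=-frames[i].normal,
                                binormal=-frames[i].binormal)
    for a, b in zip(frames[:-1], frames[1:]):
        if a.normal @ b.normal <= 0:
            raise ValueError("consecutive frame normals flip by >= 90 degrees")
    return frames


# ---------------------------------------------------------------------------
# posing and penetration resolution
# ---------------------------------------------------------------------------

def pose_unit(frame: UnitFrame, spec: PlateUnitSpec,
              extra_offset: float = 0.0) -> SurfaceMesh:
    """Place the unit with its bottom face ``standoff + extra_offset`` along
    +normal from the frame origin."""
    base = unit_mesh(spec)
    m = frame.pose_matrix()
    center = (frame.origin
              + frame.normal * (spec.standoff + extra_offset + spec.thickness / 2))
    verts = base.vertices @ m[:3, :3].T + center
    return SurfaceMesh(verts, base.faces, validate=False)


def resolve_penetration(frame: UnitFrame, spec: PlateUnitSpec,
                        bone: SurfaceMesh, sample_density: float = 4.0,
                        safety_margin: float = 0.02) -> UnitFrame:
    """Translate the frame along +normal until the posed unit clears the bone.

    The nominal pose (bottom face at ``standoff``) is accepted if its
    sampled clearance already meets ``clearance_threshold``; otherwise the
    smallest sufficient extra offset is found by bisection to 1e-3 mm (a
    small sampling safety margin is added to the target so an independent
    denser sampling still verifies the threshold). Orientation never
    changes. Raises :class:`PenetrationError` if even ``2 x`` the unit
    diagonal cannot achieve clearance.
    """
    target = spec.clearance_threshold + safety_margin

    def clearance(extra: float) -> float:
        return min_clearance(pose_unit(frame, spec, extra), bone,
                             sample_density=sample_density)

    c0 = clearance(0.0)
    if c0 >= target:
        return frame
    hi = 2.0 * spec.diagonal
    if clearance(hi) < target:
        raise PenetrationError(
            f"station at {np.round(frame.origin, 2).tolist()}: no clearance "
            f">= {spec.clearance_threshold} mm within offset {hi:.1f} mm "
            "(pathological geometry)")
    lo = 0.0
    while hi - lo > 1e-3:
        mid = 0.5 * (lo + hi)
        if clearance(mid) >= target:
            hi = mid
        else:
            lo = mid
    return frame.translated(frame.normal * hi)


def assemble_template(frames: Sequence[UnitFrame], spec: PlateUnitSpec,
                      bone: SurfaceMesh, sample_density: float = 4.0) -> PlateTemplate:
    """Pose every unit, resolve penetration, and merge into one template.

    Units are concatenated, not Boolean-unioned (overlapping shells slice
    fine on FDM printers and avoid CSG robustness problems). Screw axes are
    the per-unit (center, normal) pairs. Inter-unit bend angles land in the
    metadata so the operator can check that bends fall between screw holes.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("assemble_template needs at least one frame")
    resolved: List[UnitFrame] = []
    failures: List[int] = []
    for i, f in enumerate(frames):
        try:
            resolved.append(resolve_penetration(f, spec, bone, sample_density))
        except PenetrationError:
            failures.append(i)
    if failures:
        raise PenetrationError(
            f"stations {failures} could not be cleared from the bone surface")
    unit_meshes = [pose_unit(f, spec) for f in resolved]
    merged = concatenate(unit_meshes)
    screw_axes = [((f.origin + f.normal * (spec.standoff + spec.thickness / 2)),
                   f.normal) for f in resolved]
    # template clearance = min over units (the merged mesh is their union)
    clearance = min(min_clearance(u, bone, sample_density=sample_density)
                    for u in unit_meshes)
    bend_angles = [float(np.degrees(np.arccos(np.clip(
        a.tangent @ b.tangent, -1.0, 1.0))))
        for a, b in zip(resolved[:-1], resolved[1:])]
    meta = {
        "unit_count": len(resolved),
        "clearance_threshold_mm": spec.clearance_threshold,
        "min_clearance_mm": clearance,
        "clearance_ok": bool(clearance >= spec.clearance_threshold - 1e-3),
        "inter_unit_bend_angles_deg": bend_angles,
        "catalog_id": spec.catalog_id,
    }
    if not meta["clearance_ok"]:  # pragma: no cover - resolution guards this
        logger.warning("template clearance %.4f mm below threshold %.4f mm",
                       clearance, spec.clearance_threshold)
    return PlateTemplate(spec=spec, frames=resolved, mesh=merged,
                         screw_axes=screw_axes, metadata=meta)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_template(template: PlateTemplate, path) -> None:
    """Binary STL plus a ``<path>.json`` sidecar with frames, spec,
    parameters and the clearance report."""
    path = Path(path)
    write_stl(template.mesh, path, mode="binary")
    spec_dict = asdict(template.spec)
    sidecar = {
        "spec": spec_dict,
        "frames": [{
            "origin": f.origin.tolist(),
            "tangent": f.tangent.tolist(),
            "normal": f.normal.tolist(),
            "binormal": f.binormal.tolist(),
            "on_surface": bool(f.on_surface),
        } for f in template.frames],
        "screw_axes": [{"point": p.tolist(), "direction": d.tolist()}
                       for p, d in template.screw_axes],
        "metadata": template.metadata,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2,
                                                    sort_keys=True))


def load_template_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# one-call pipeline
# ---------------------------------------------------------------------------

def plan_plate(bone: SurfaceMesh, raw_anchors, spec: PlateUnitSpec,
               params: PathParams = PathParams(),
               sample_density: float = 4.0) -> PlateTemplate:
    """Full anchor-to-template pipeline on a reduced bone surface."""
    anchors = project_anchors(bone, raw_anchors)
    path = build_path(bone, anchors, params, gap_policy="flag")
    path = wrap_path(path, bone, params)
    unit_count, adjusted = match_length(path, spec.unit_length, mesh=bone,
                                        params=params)
    frames = compute_frames(adjusted, bone, unit_count, spec.unit_length)
    template = assemble_template(frames, spec, bone, sample_density)
    template.metadata["path_length_mm"] = arc_length(adjusted)
    return template
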