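"""On-surface plate path construction.

The operator's ordered anchor clicks are projected to the bone surface, an
interpolating centripetal Catmull-Rom spline is sampled between them, each
sample is pulled onto the surface, and endpoint-fixed Laplacian smoothing
(with re-projection) evens the polyline out. Regions where projection
diverges — residual fracture gaps — are bridged with straight chords
("wrap"). Finally the mid-line rule crops or lengthens the path to a whole
number of plate units: a residual shorter than half a unit is cropped,
anything from half a unit up earns one more unit.

"Mid-line of the fixation plate unit" is read here as half the unit length
(the transverse mid-line through the screw hole); this is an interpretation
and is applied consistently everywhere.

Everything in this module is deterministic: identical inputs give
bit-identical paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .meshcore import SurfaceMesh, closest_points

__all__ = [
    "SurfacePath",
    "PathParams",
    "PathProjectionError",
    "project_anchors",
    "build_path",
    "wrap_path",
    "match_length",
    "arc_length",
    "point_at_arc_length",
    "load_anchors_json",
    "save_anchors_json",
]


class PathProjectionError(RuntimeError):
    pass


@dataclass(frozen=True)
class PathParams:
    sample_spacing: float = 0.5
    smoothing_lambda: float = 0.5
    smoothing_iterations: int = 10
    wrap_distance: float = 5.0
    projection_tolerance: float = 0.1

    def __post_init__(self):
        if self.sample_spacing <= 0:
            raise ValueError("sample_spacing must be > 0")
        if not 0.0 <= self.smoothing_lambda <= 1.0:
            raise ValueError("smoothing_lambda must be in [0, 1]")
        if self.smoothing_iterations < 0:
            raise ValueError("smoothing_iterations must be >= 0")
        if self.wrap_distance <= self.projection_tolerance:
            raise ValueError("wrap_distance must exceed projection_tolerance")


@dataclass(frozen=True)
class SurfacePath:
    """Ordered polyline with arc-length table and bridge flags.

    ``on_surface_flags[i]`` is False for wrap/bridge samples;
    ``projection_distances[i]`` records how far sample i had to travel to
    reach the surface when it was projected (0 for synthetic samples).
    """

    samples: np.ndarray
    cumulative_length: np.ndarray
    on_surface_flags: np.ndarray
    source_anchor_indices: np.ndarray
    projection_distances: np.ndarray

    @staticmethod
    def from_samples(samples, on_surface_flags=None, anchor_indices=(),
                     projection_distances=None) -> "SurfacePath":
        samples = np.asarray(samples, dtype=float).reshape(-1, 3)
        if len(samples) < 2:
            raise ValueError("a path needs at least 2 samples")
        seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        flags = (np.ones(len(samples), dtype=bool) if on_surface_flags is None
                 else np.asarray(on_surface_flags, dtype=bool))
        pd = (np.zeros(len(samples)) if projection_distances is None
              else np.asarray(projection_distances, dtype=float))
        return SurfacePath(samples=samples, cumulative_length=cum,
                           on_surface_flags=flags,
                           source_anchor_indices=np.asarray(anchor_indices,
                                                            dtype=np.int64),
                           projection_distances=pd)

    @property
    def length(self) -> float:
        return float(self.cumulative_length[-1])


def arc_length(path: SurfacePath) -> float:
    """Total arc length (last entry of the cumulative table)."""
    if len(path.samples) < 2:
        raise ValueError("path needs >= 2 samples")
    return path.length


def point_at_arc_length(path: SurfacePath, s: float) -> np.ndarray:
    """Linear interpolation along the polyline at arc length ``s``."""
    cum = path.cumulative_length
    s = float(np.clip(s, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(cum) - 2)
    seg = cum[i + 1] - cum[i]
    t = 0.0 if seg == 0 else (s - cum[i]) / seg
    return path.samples[i] + t * (path.samples[i + 1] - path.samples[i])


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def project_anchors(mesh: SurfaceMesh, raw_points) -> np.ndarray:
    """Snap each raw click to its closest surface point, order preserved;
    consecutive duplicates (< 1e-6 mm apart) are collapsed."""
    raw = np.asarray(raw_points, dtype=float).reshape(-1, 3)
    if len(raw) < 2:
        raise ValueError("need at least 2 raw anchor points")
    projected = np.array([r.point for r in closest_points(mesh, raw)])
    keep = [projected[0]]
    for p in projected[1:]:
        if np.linalg.norm(p - keep[-1]) >= 1e-6:
            keep.append(p)
    if len(keep) < 2:
        raise ValueError("fewer than 2 distinct anchors after projection")
    return np.asarray(keep)


# ---------------------------------------------------------------------------
# spline
# ---------------------------------------------------------------------------

def _catmull_rom(anchors: np.ndarray, spacing: float):
    """Centripetal Catmull-Rom through all anchors, sampled at <= spacing.

    Returns (samples, anchor_sample_indices)."""
    a = anchors
    if len(a) == 2:
        n = max(int(np.ceil(np.linalg.norm(a[1] - a[0]) / spacing)), 1)
        ts = np.linspace(0.0, 1.0, n + 1)[:, None]
        return a[0] + ts * (a[1] - a[0]), np.array([0, n])
    ext = np.vstack([2 * a[0] - a[1], a, 2 * a[-1] - a[-2]])
    samples = [a[0]]
    anchor_idx = [0]
    for i in range(len(a) - 1):
        p0, p1, p2, p3 = ext[i], ext[i + 1], ext[i + 2], ext[i + 3]

        def knot(ti, pa, pb):
            d = np.sqrt(np.linalg.norm(pb - pa))
            return ti + (d if d > 0 else 1.0)

        t0 = 0.0
        t1 = knot(t0, p0, p1)
        t2 = knot(t1, p1, p2)
        t3 = knot(t2, p2, p3)
        n = max(int(np.ceil(np.linalg.norm(p2 - p1) / spacing)), 1)
        ts = np.linspace(t1, t2, n + 1)[1:]
        for t in ts:
            a01 = _lerp(p0, p1, t0, t1, t)
            a12 = _lerp(p1, p2, t1, t2, t)
            a23 = _lerp(p2, p3, t2, t3, t)
            b1 = _lerp(a01, a12, t0, t2, t)
            b2 = _lerp(a12, a23, t1, t3, t)
            samples.append(_lerp(b1, b2, t1, t2, t))
        anchor_idx.append(len(samples) - 1)
    return np.asarray(samples), np.asarray(anchor_idx)


def _lerp(pa, pb, ta, tb, t):
    if tb == ta:
        return pa
    w = (t - ta) / (tb - ta)
    return (1.0 - w) * pa + w * pb


# ---------------------------------------------------------------------------
# build / wrap
# ---------------------------------------------------------------------------

def _project_all(mesh, points):
    results = closest_points(mesh, points)
    proj = np.array([r.point for r in results])
    dist = np.array([r.distance for r in results])
    return proj, dist


def build_path(mesh: SurfaceMesh, anchors, params: PathParams = PathParams(),
               gap_policy: str = "error") -> SurfacePath:
    """Spline through the anchors, projected and smoothed onto the surface.

    Steps: (1) centripetal Catmull-Rom through the anchors sampled at
    <= ``sample_spacing``; (2) every sample projected to the mesh;
    (3) ``smoothing_iterations`` endpoint-fixed Laplacian passes
    (s <- (1-l) s + l * neighbor midpoint) with re-projection after each
    pass; anchor samples may drift at most ``2 * sample_spacing``.

    If any run of samples projects farther than ``wrap_distance`` the
    surface is discontinuous under the path: with ``gap_policy='error'``
    (default) a :class:`PathProjectionError` points the user at
    :func:`wrap_path`; ``gap_policy='flag'`` keeps going and marks the
    offending samples off-surface for wrapping.
    """
    if gap_policy not in ("error", "flag"):
        raise ValueError("gap_policy must be 'error' or 'flag'")
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 3)
    if len(anchors) < 2:
        raise ValueError("need at least 2 anchors")
    raw, anchor_idx = _catmull_rom(anchors, params.sample_spacing)
    proj, dist = _project_all(mesh, raw)

    if gap_policy == "error" and np.any(dist > params.wrap_distance):
        n_far = int(np.sum(dist > params.wrap_distance))
        raise PathProjectionError(
            f"projection diverged past wrap_distance={params.wrap_distance} mm "
            f"for {n_far} samples; the surface is discontinuous under the "
            "path — rebuild with gap_policy='flag' and bridge with wrap_path")

    pts = proj.copy()
    lam = params.smoothing_lambda
    if lam > 0 and params.smoothing_iterations > 0 and len(pts) > 2:
        anchor_ref = proj[anchor_idx].copy()
        max_drift = 2.0 * params.sample_spacing
        for _ in range(params.smoothing_iterations):
            mid = 0.5 * (pts[:-2] + pts[2:])
            pts[1:-1] = (1.0 - lam) * pts[1:-1] + lam * mid
            # anchors are soft: clamp drift from their projected positions
            for j, ai in zip(range(len(anchor_idx)), anchor_idx):
                if ai in (0, len(pts) - 1):
                    continue
                d = pts[ai] - anchor_ref[j]
                r = np.linalg.norm(d)
                if r > max_drift:
                    pts[ai] = anchor_ref[j] + d * (max_drift / r)
            pts[0] = proj[0]
            pts[-1] = proj[-1]
            # re-project; wrap detection keeps the original spline divergence
            pts, _ = _project_all(mesh, pts)
    return SurfacePath.from_samples(pts, on_surface_flags=dist <= params.wrap_distance,
                                    anchor_indices=anchor_idx,
                                    projection_distances=dist)


def wrap_path(path: SurfacePath, mesh: SurfaceMesh,
              params: PathParams = PathParams()) -> SurfacePath:
    """Bridge discontinuities: maximal runs whose recorded projection
    distance exceeds ``wrap_distance`` are replaced by a straight chord
    between the bounding on-surface samples (flagged off-surface).
    """
    off = path.projection_distances > params.wrap_distance
    if not off.any():
        return path
    if off[0] or off[-1]:
        raise PathProjectionError(
            "path must start and end on bone: first/last sample is off-surface")
    samples = []
    flags = []
    pdist = []
    anchor_pos = [path.samples[i] for i in path.source_anchor_indices]
    i = 0
    n = len(path.samples)
    while i < n:
        if not off[i]:
            samples.append(path.samples[i])
            flags.append(True)
            pdist.append(path.projection_distances[i])
            i += 1
            continue
        j = i
        while j < n and off[j]:
            j += 1
        a = samples[-1]
        b = path.samples[j]
        chord = np.linalg.norm(b - a)
        k = max(int(np.ceil(chord / params.sample_spacing)), 1)
        for step in range(1, k):
            samples.append(a + (b - a) * (step / k))
            flags.append(False)
            pdist.append(0.0)
        i = j
    # collapse consecutive duplicates (several off samples can project to
    # one rim point)
    out_s, out_f, out_d = [samples[0]], [flags[0]], [pdist[0]]
    for s, f, d in zip(samples[1:], flags[1:], pdist[1:]):
        if np.linalg.norm(s - out_s[-1]) < 1e-9:
            continue
        out_s.append(s)
        out_f.append(f)
        out_d.append(d)
    out_s = np.asarray(out_s)
    anchor_idx = [int(np.argmin(np.linalg.norm(out_s - p, axis=1)))
                  for p in anchor_pos]
    return SurfacePath.from_samples(out_s, on_surface_flags=out_f,
                                    anchor_indices=sorted(set(anchor_idx)),
                                    projection_distances=out_d)


# ---------------------------------------------------------------------------
# mid-line rule
# ---------------------------------------------------------------------------

def match_length(path: SurfacePath, unit_length: float,
                 mesh: Optional[SurfaceMesh] = None,
                 params: PathParams = PathParams()) -> Tuple[int, SurfacePath]:
    """Crop or lengthen the path to a whole number of plate units.

    With ``S = arc length`` and ``L = unit_length``, let ``r = S mod L``:
    ``r < L/2`` crops to ``floor(S/L)`` units, ``r >= L/2`` lengthens to
    ``ceil(S/L)`` (the tie goes up, never truncating fracture coverage), and
    the count is never below 1. Extension continues along the final tangent;
    when a mesh is supplied, extension samples are re-projected where they
    land within ``wrap_distance``, otherwise flagged as bridge samples.
    """
    if unit_length <= 0:
        raise ValueError("unit_length must be > 0")
    S = arc_length(path)
    if S <= 0:
        raise ValueError("path length must be > 0")
    L = float(unit_length)
    n_lo = int(np.floor(S / L))
    r = S - n_lo * L
    unit_count = n_lo if r < L / 2 else n_lo + 1
    unit_count = max(unit_count, 1)
    target = unit_count * L
    if target <= S:
        return unit_count, _crop(path, target)
    return unit_count, _extend(path, target, mesh, params)


def _crop(path: SurfacePath, target: float) -> SurfacePath:
    cum = path.cumulative_length
    if abs(target - cum[-1]) < 1e-12:
        return path
    i = int(np.searchsorted(cum, target, side="right") - 1)
    i = min(i, len(cum) - 2)
    end = point_at_arc_length(path, target)
    samples = np.vstack([path.samples[:i + 1], end])
    flags = np.concatenate([path.on_surface_flags[:i + 1],
                            [path.on_surface_flags[min(i + 1, len(cum) - 1)]]])
    pd = np.concatenate([path.projection_distances[:i + 1], [0.0]])
    anchor_idx = [a for a in path.source_anchor_indices if a <= i]
    return SurfacePath.from_samples(samples, on_surface_flags=flags,
                                    anchor_indices=anchor_idx,
                                    projection_distances=pd)


def _extend(path: SurfacePath, target: float, mesh, params: PathParams) -> SurfacePath:
    samples = list(path.samples)
    flags = list(path.on_surface_flags)
    pd = list(path.projection_distances)
    length = path.length
    spacing = params.sample_spacing
    guard = 0
    max_iter = int(np.ceil((target - length) / spacing)) * 4 + 64
    while length < target - 1e-9:
        tangent = samples[-1] - samples[-2]
        tn = np.linalg.norm(tangent)
        if tn == 0:
            samples.pop()
            flags.pop()
            pd.pop()
            continue
        tangent /= tn
        step = min(spacing, target - length)
        candidate = samples[-1] + tangent * step
        placed = None
        if mesh is not None:
            from .meshcore import closest_point

            res = closest_point(mesh, candidate)
            advance = np.linalg.norm(res.point - samples[-1])
            if res.distance <= params.wrap_distance and advance >= 0.25 * step:
                placed = (res.point, True, res.distance)
        if placed is None:
            placed = (candidate, False if mesh is not None else True, 0.0)
        samples.append(placed[0])
        flags.append(placed[1])
        pd.append(placed[2])
        length += np.linalg.norm(samples[-1] - samples[-2])
        guard += 1
        if guard > max_iter:
            raise RuntimeError("path extension failed to converge")
    out = SurfacePath.from_samples(np.asarray(samples), on_surface_flags=flags,
                                   anchor_indices=path.source_anchor_indices,
                                   projection_distances=pd)
    return _crop(out, target)  # trim the overshoot of the final step


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_anchors_json(path) -> np.ndarray:
    data = json.loads(Path(path).read_text())
    return np.array([[p["x"], p["y"], p["z"]] for p in data], dtype=float)


def save_anchors_json(points, path) -> None:
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    Path(path).write_text(json.dumps(
        [{"x": float(x), "y": float(y), "z": float(z)} for x, y, z in pts],
        indent=2))


def save_path_json(path_obj: SurfacePath, path) -> None:
    Path(path).write_text(json.dumps({
        "samples": path_obj.samples.tolist(),
        "cumulative_length": path_obj.cumulative_length.tolist(),
        "on_surface_flags": path_obj.on_surface_flags.tolist(),
        "source_anchor_indices": path_obj.source_anchor_indices.tolist(),
    }, indent=2))


def save_path_obj(path_obj: SurfacePath, path) -> None:
    """OBJ line-set export for visual inspection."""
    lines = [f"v {x:.9g} {y:.9g} {z:.9g}" for x, y, z in path_obj.samples]
    lines.append("l " + " ".join(str(i + 1) for i in range(len(path_obj.samples))))
    Path(path).write_text("\n".join(lines) + "\n")
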