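"""Virtual fracture reduction: rigid motions, mirror technique, and
landmark-driven (Kabsch) alignment composing fragments into one model.

"Manual repositioning" is realized non-interactively: the operator supplies
ordered landmark pairs and the least-squares rigid transform is solved in
closed form. An optional ICP refinement exists but is off by default so
every reduction is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from .meshcore import SurfaceMesh, closest_points, concatenate

__all__ = [
    "RigidTransform",
    "MirrorPlane",
    "mirror_mesh",
    "kabsch_align",
    "apply_transform",
    "compose_model",
    "icp_refine",
    "mid_sagittal_plane",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion v -> R v + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation",
                           np.asarray(self.rotation, dtype=float).reshape(3, 3))
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float).reshape(3))
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has det -1 (improper)")

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_axis_angle(axis, angle: float, translation=(0, 0, 0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        return RigidTransform(R, translation)

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Returns self o other (apply *other* first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @staticmethod
    def from_matrix(m) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return RigidTransform(m[:3, :3], m[:3, 3])

    def rotation_angle(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"matrix_4x4_row_major": self.to_matrix().ravel().tolist()},
            indent=2))

    @staticmethod
    def load_json(path) -> "RigidTransform":
        data = json.loads(Path(path).read_text())
        return RigidTransform.from_matrix(
            np.asarray(data["matrix_4x4_row_major"]).reshape(4, 4))


@dataclass(frozen=True)
class MirrorPlane:
    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point",
                           np.asarray(self.point, dtype=float).reshape(3))
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", n / norm)

    def reflect(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        d = (pts - self.point) @ self.normal
        return pts - 2.0 * np.outer(d, self.normal).reshape(pts.shape)


def mirror_mesh(mesh: SurfaceMesh, plane: MirrorPlane) -> SurfaceMesh:
    """Reflect across *plane*; winding reversed to keep outward orientation."""
    verts = plane.reflect(mesh.vertices)
    return SurfaceMesh(verts, mesh.faces[:, ::-1].copy(),
                       metadata=dict(mesh.metadata), validate=False)


def kabsch_align(source_points, target_points) -> Tuple[RigidTransform, float]:
    """Least-squares rigid transform mapping source -> target (SVD Kabsch).

    Returns ``(transform, rmsd)``; reflections are corrected to a proper
    rotation. Fewer than 3 correspondences or a collinear configuration
    raises ``ValueError``.
    """
    src = np.asarray(source_points, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target_points, dtype=float).reshape(-1, 3)
    if src.shape != tgt.shape:
        raise ValueError("source and target point counts differ")
    if len(src) < 3:
        raise ValueError("need at least 3 correspondences")
    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    sv = np.linalg.svd(src_c, compute_uv=False)
    scale = sv[0] if sv[0] > 0 else 1.0
    if sv[1] <= 1e-9 * scale:
        raise ValueError("degenerate (collinear) landmark configuration")
    H = src_c.T @ tgt_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tgt.mean(axis=0) - R @ src.mean(axis=0)
    transform = RigidTransform(R, t)
    resid = transform.apply(src) - tgt
    rmsd = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return transform, rmsd


def apply_transform(mesh: SurfaceMesh, t: RigidTransform) -> SurfaceMesh:
    return mesh.with_vertices(t.apply(mesh.vertices))


def compose_model(fragments: Sequence[Tuple[SurfaceMesh, RigidTransform]]) -> SurfaceMesh:
    """Transform each fragment and concatenate into one model.

    Per-fragment provenance is kept in ``metadata['fragments']`` as
    ``(face_start, face_end)`` ranges.
    """
    fragments = list(fragments)
    if not fragments:
        raise ValueError("compose_model needs at least one fragment")
    moved = [apply_transform(m, t) for m, t in fragments]
    out = concatenate(moved)
    ranges = []
    fstart = 0
    for m in moved:
        ranges.append((fstart, fstart + m.n_faces))
        fstart += m.n_faces
    out.metadata["fragments"] = ranges
    return out


def icp_refine(source: SurfaceMesh, target: SurfaceMesh,
               initial: Optional[RigidTransform] = None,
               max_iterations: int = 25, tolerance: float = 1e-6,
               max_points: int = 500) -> Tuple[RigidTransform, float]:
    """Point-to-point ICP from source vertices onto the target surface.

    Deterministic (uniform vertex subsampling). Off by default everywhere;
    intended as an optional refinement after landmark alignment.
    """
    t = initial if initial is not None else RigidTransform.identity()
    step = max(1, source.n_vertices // max_points)
    pts = source.vertices[::step]
    prev_rmsd = np.inf
    rmsd = np.inf
    for _ in range(max_iterations):
        moved = t.apply(pts)
        matches = np.array([r.point for r in closest_points(target, moved)])
        delta, rmsd = kabsch_align(moved, matches)
        t = delta.compose(t)
        if abs(prev_rmsd - rmsd) < tolerance:
            break
        prev_rmsd = rmsd
    return t, float(rmsd)


def mid_sagittal_plane(mesh: SurfaceMesh) -> MirrorPlane:
    """Default mirror plane: x = centroid_x of the surface (overridable)."""
    centroid = mesh.vertices.mean(axis=0)
    return MirrorPlane(point=[centroid[0], 0.0, 0.0], normal=[1.0, 0.0, 0.0])


def load_landmark_pairs(path) -> Tuple[np.ndarray, np.ndarray]:
    """Landmark pairs from JSON ``{"source": [[x,y,z],...], "target": [...]}``
    or CSV with columns sx,sy,sz,tx,ty,tz."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return (np.asarray(data["source"], dtype=float),
                np.asarray(data["target"], dtype=float))
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    return arr[:, 0:3], arr[:, 3:6]
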