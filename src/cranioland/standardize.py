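"""Horizontal alignment and raycast resampling onto the ray template.

A cranial surface enters as an arbitrary-pose STL mesh with three
annotated soft-tissue landmarks.  It leaves as a :class:`StandardizedSurface`:
1016 vertices in fixed correspondence across subjects, obtained by casting
rays from the supra-aural midpoint along the directions of a fixed
hemi-icosphere template and keeping the farthest intersection per ray (the
outermost skin shell, which discards any interior structure the mesh may
still contain).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from . import config as cfg
from .geometry import ray_mesh_intersections
from .meshio import LandmarkSet, SurfaceMesh

__all__ = [
    "RigidTransform",
    "RayTemplate",
    "StandardizedSurface",
    "DegenerateLandmarksError",
    "RaycastQualityError",
    "horizontal_align",
    "build_ray_template",
    "default_ray_template",
    "raycast_surface",
    "standardize_subject",
    "StandardizedSubject",
]


class DegenerateLandmarksError(ValueError):
    """Landmarks collinear or coincident; no frame can be constructed."""


class RaycastQualityError(RuntimeError):
    """Too many rays missed the mesh; likely not a closed cranial shell."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation`` (mm)."""

    rotation: np.ndarray  # (3,3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is a reflection (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class RayTemplate:
    """Fixed set of ray directions establishing vertex correspondence.

    ``directions`` are unit vectors ordered by descending z, then azimuth;
    ``faces`` is the triangulation inherited from the icosphere (used for
    normal estimation on standardized surfaces).
    """

    directions: np.ndarray  # (N, 3) unit
    faces: np.ndarray  # (M, 3) int
    subdivision: int
    cut_latitude_deg: float
    tilt_deg: tuple[float, float]

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]

    def to_mesh(self, radius: float = 100.0) -> SurfaceMesh:
        """Template as an STL-exportable fan for visual QC."""
        return SurfaceMesh(self.directions * radius, self.faces)


def horizontal_align(
    mesh: SurfaceMesh, lms: LandmarkSet
) -> tuple[SurfaceMesh, LandmarkSet, RigidTransform]:
    """Rigidly move a mesh into the canonical horizontal pose.

    After alignment the supra-aural midpoint sits at the origin, the
    left→right supra-aural axis runs along +x, and the nasion lies in the
    y > 0 half of the x–y plane.  The same transform is applied to the
    landmarks and returned for reuse (e.g. to map the ground-truth sella
    into the aligned frame).
    """
    left, right, nasion = lms.supra_aural_left, lms.supra_aural_right, lms.nasion
    mid = 0.5 * (left + right)
    x_axis = right - left
    nx = np.linalg.norm(x_axis)
    if nx < 1e-9:
        raise DegenerateLandmarksError("supra-aural landmarks coincide")
    x_axis = x_axis / nx
    y_raw = nasion - mid
    y_axis = y_raw - (y_raw @ x_axis) * x_axis
    ny = np.linalg.norm(y_axis)
    if ny < 1e-9:
        raise DegenerateLandmarksError("nasion collinear with supra-aural axis")
    y_axis = y_axis / ny
    z_axis = np.cross(x_axis, y_axis)
    R = np.vstack([x_axis, y_axis, z_axis])  # world -> canonical
    transform = RigidTransform(R, -R @ mid)
    return mesh.transformed(R, transform.translation), lms.transformed(R, transform.translation), transform


def build_ray_template(
    subdivision: int = cfg.TEMPLATE_SUBDIVISION,
    cut_latitude_deg: float = cfg.TEMPLATE_CUT_LATITUDE_DEG,
    tilt_deg: tuple[float, float] = cfg.TEMPLATE_TILT_DEG,
) -> RayTemplate:
    """Build the hemi-icosphere ray template.

    The unit icosphere at the requested subdivision is tilted by the fixed
    rotation ``tilt_deg`` (about x, then y) and cut at
    ``z >= sin(cut_latitude_deg)``.  The tilt breaks the latitude
    degeneracy of the symmetric icosphere, which is what allows a latitude
    cut to retain exactly 1016 directions at the default configuration.
    Ordering is deterministic: descending z, ties by azimuth.
    """
    if subdivision < 0:
        raise ValueError("subdivision must be >= 0")
    ico = trimesh.creation.icosphere(subdivisions=subdivision)
    directions = np.asarray(ico.vertices, dtype=float)
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    R = Rotation.from_euler("xy", tilt_deg, degrees=True).as_matrix()
    directions = directions @ R.T
    keep = directions[:, 2] >= np.sin(np.radians(cut_latitude_deg))
    if not np.any(keep):
        raise ValueError("latitude cut retains no directions")
    kept_idx = np.flatnonzero(keep)
    directions = directions[kept_idx]
    order = np.lexsort((np.arctan2(directions[:, 1], directions[:, 0]), -directions[:, 2]))
    directions = directions[order]
    # renormalize (rotation preserves norms, but pin the invariant exactly)
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)

    # remap faces whose three corners survived the cut
    old_to_new = -np.ones(len(ico.vertices), dtype=np.intp)
    old_to_new[kept_idx[order]] = np.arange(len(kept_idx))
    faces = np.asarray(ico.faces, dtype=np.intp)
    face_ok = np.all(old_to_new[faces] >= 0, axis=1)
    faces = old_to_new[faces[face_ok]]
    return RayTemplate(
        directions=directions,
        faces=faces,
        subdivision=subdivision,
        cut_latitude_deg=cut_latitude_deg,
        tilt_deg=tuple(tilt_deg),
    )


_DEFAULT_TEMPLATE: RayTemplate | None = None


def default_ray_template() -> RayTemplate:
    """The frozen default template (cached; always 1016 directions)."""
    global _DEFAULT_TEMPLATE
    if _DEFAULT_TEMPLATE is None:
        _DEFAULT_TEMPLATE = build_ray_template()
        assert _DEFAULT_TEMPLATE.n_directions == cfg.N_TEMPLATE_VERTICES
    return _DEFAULT_TEMPLATE


@dataclass(frozen=True)
class StandardizedSurface:
    """Corresponded cranial surface: one vertex per template direction.

    ``miss_mask[i]`` flags vertices whose ray had no intersection and whose
    radial distance was therefore interpolated from neighbouring rays.
    """

    vertices: np.ndarray  # (N, 3) mm, template order
    origin: np.ndarray  # (3,) supra-aural midpoint, aligned frame
    source_id: str
    miss_mask: np.ndarray  # (N,) bool

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def flattened(self) -> np.ndarray:
        return self.vertices.reshape(-1)


def raycast_surface(
    mesh: SurfaceMesh,
    lms: LandmarkSet,
    template: RayTemplate | None = None,
    source_id: str = "",
    max_miss_fraction: float = 0.10,
) -> StandardizedSurface:
    """Resample an aligned mesh by raycasting from the supra-aural midpoint.

    For each template direction the farthest intersection with the mesh is
    kept, so any interior shell (residual soft-tissue structure) is
    discarded in favour of the outermost surface.  Rays that miss are
    filled by inverse-angular-distance interpolation of the radial
    distance over the 3 nearest hit directions and flagged in the miss
    mask.  More than ``max_miss_fraction`` misses raises
    :class:`RaycastQualityError`.
    """
    template = template or default_ray_template()
    origin = lms.supra_aural_midpoint
    t, hit = ray_mesh_intersections(origin, template.directions, mesh.vertices, mesh.faces)
    n_miss = int((~hit).sum())
    if n_miss > max_miss_fraction * template.n_directions:
        raise RaycastQualityError(
            f"{n_miss}/{template.n_directions} rays missed; "
            "mesh is likely not a closed cranial shell around the origin"
        )
    if n_miss:
        dirs = template.directions
        hit_idx = np.flatnonzero(hit)
        for i in np.flatnonzero(~hit):
            # 3 nearest hit rays by angle, inverse-distance weighting
            cosang = np.clip(dirs[hit_idx] @ dirs[i], -1.0, 1.0)
            ang = np.arccos(cosang)
            near = hit_idx[np.argsort(ang)[:3]]
            w = 1.0 / np.maximum(np.arccos(np.clip(dirs[near] @ dirs[i], -1, 1)), 1e-9)
            t[i] = float(np.sum(w * t[near]) / np.sum(w))
    vertices = origin + t[:, None] * template.directions
    return StandardizedSurface(
        vertices=vertices, origin=np.asarray(origin, float), source_id=source_id, miss_mask=~hit
    )


@dataclass(frozen=True)
class StandardizedSubject:
    """A subject after alignment + raycasting, ready for modelling.

    ``sella`` (optional) and landmarks are expressed in the aligned frame.
    """

    id: str
    subtype: str
    surface: StandardizedSurface
    landmarks: LandmarkSet
    transform: RigidTransform  # original -> aligned frame
    sella: np.ndarray | None = None


def standardize_subject(record, template: RayTemplate | None = None) -> StandardizedSubject:
    """Align + raycast one :class:`~cranioland.meshio.SubjectRecord`."""
    mesh_a, lms_a, transform = horizontal_align(record.mesh, record.landmarks)
    surface = raycast_surface(mesh_a, lms_a, template, source_id=record.id)
    return StandardizedSubject(
        id=record.id,
        subtype=record.subtype,
        surface=surface,
        landmarks=lms_a,
        transform=transform,
        sella=None if lms_a.sella is None else lms_a.sella,
    )
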