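"""Sella–Nasion (S-N) reference frame construction and mesh realignment.

The S-N frame is the standard cephalometric orientation: origin at the
sella, anteroposterior axis toward the nasion.  Here it is built from the
(predicted or true) sella plus the three soft-tissue landmarks: the
sella→nasion direction is the primary (y) axis, the left→right
supra-aural direction — Gram-Schmidt-orthogonalized against y — gives x,
and z = x × y completes a right-handed triad.  Realigning a mesh with a
frame built from a *predicted* sella versus the true one isolates exactly
the effect of the prediction error on mesh orientation, which is what the
distance-map evaluation measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meshio import LandmarkSet, SurfaceMesh

__all__ = ["ReferenceFrame", "DegenerateFrameError", "build_sn_frame", "align_to_frame"]


class DegenerateFrameError(ValueError):
    """Sella–nasion direction parallel to the supra-aural axis."""


@dataclass(frozen=True)
class ReferenceFrame:
    """Origin (mm) + right-handed orthonormal axes (rows: x, y, z)."""

    origin: np.ndarray  # (3,)
    axes: np.ndarray  # (3,3), rows are the axis directions

    def __post_init__(self):
        A = np.asarray(self.axes, dtype=float)
        o = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.allclose(A @ A.T, np.eye(3), atol=1e-9):
            raise ValueError("axes not orthonormal")
        if np.linalg.det(A) < 0:
            raise ValueError("axes not right-handed")
        object.__setattr__(self, "axes", A)
        object.__setattr__(self, "origin", o)

    def to_frame_coords(self, points: np.ndarray) -> np.ndarray:
        """Express world points in frame coordinates: ``axes·(p − origin)``."""
        return (np.asarray(points) - self.origin) @ self.axes.T


def build_sn_frame(st: np.ndarray, lms: LandmarkSet) -> ReferenceFrame:
    """S-N frame from a sella estimate and the soft-tissue landmarks.

    y = unit(nasion − st); x = unit supra-aural left→right direction
    orthogonalized against y; z = x × y.  The y axis is primary, so noise
    in the supra-aural landmarks cannot bend the anteroposterior
    direction, only roll the frame about it.
    """
    st = np.asarray(st, dtype=float).reshape(3)
    y_raw = lms.nasion - st
    ny = np.linalg.norm(y_raw)
    if ny < 1e-9:
        raise DegenerateFrameError("sella coincides with nasion")
    y = y_raw / ny
    x_raw = lms.supra_aural_right - lms.supra_aural_left
    x = x_raw - (x_raw @ y) * y
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise DegenerateFrameError("sella–nasion direction parallel to supra-aural axis")
    x = x / nx
    z = np.cross(x, y)
    return ReferenceFrame(origin=st, axes=np.vstack([x, y, z]))


def align_to_frame(mesh: SurfaceMesh, frame: ReferenceFrame) -> SurfaceMesh:
    """Rigidly express a mesh in frame coordinates."""
    return SurfaceMesh(frame.to_frame_coords(mesh.vertices), mesh.faces)
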