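"""Surface-mesh and landmark I/O, and the coordinate convention.

All coordinates are in millimetres.  Axes follow the cephalometric
convention used throughout the package: +x mediolateral toward the
subject's right, +y anteroposterior toward anterior, +z craniocaudal
toward superior.  STL files carry no unit metadata; millimetres are
assumed, not detected.

Landmarks travel in a JSON sidecar with one ``[x, y, z]`` triple per named
landmark (``nasion``, ``supra_aural_left``, ``supra_aural_right`` and,
when ground truth is available, ``sella``).  Cohorts are described by a
manifest CSV with columns ``id, mesh_path, landmark_path, subtype``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .config import SUBTYPE_ORDER

__all__ = [
    "SurfaceMesh",
    "LandmarkSet",
    "SubjectRecord",
    "MeshFormatError",
    "LandmarkSchemaError",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_manifest",
    "load_cohort",
]


class MeshFormatError(ValueError):
    """Unreadable, corrupt or empty mesh file."""


class LandmarkSchemaError(ValueError):
    """Landmark sidecar violates the documented schema."""


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated 3D shell (mm).

    Invariants enforced at construction: finite coordinates, in-range face
    indices, at least 4 vertices, and no zero-area faces (degenerate faces
    are expected to have been cleaned at load time).
    """

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.intp)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 4:
            raise MeshFormatError("mesh needs at least 4 vertices of dim 3")
        if not np.all(np.isfinite(v)):
            raise MeshFormatError("non-finite vertex coordinates")
        if f.ndim != 2 or f.shape[1] != 3 or f.shape[0] == 0:
            raise MeshFormatError("mesh has no triangular faces")
        if f.min() < 0 or f.max() >= v.shape[0]:
            raise MeshFormatError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        """Return the mesh under ``v -> rotation @ v + translation``."""
        return SurfaceMesh(self.vertices @ np.asarray(rotation).T + translation, self.faces)


@dataclass(frozen=True)
class LandmarkSet:
    """Manually annotated cephalometric landmarks (mm).

    ``sella`` is the hard-tissue ground truth and is optional: it is
    present for training subjects and absent at pure prediction time.
    """

    nasion: np.ndarray
    supra_aural_left: np.ndarray
    supra_aural_right: np.ndarray
    sella: np.ndarray | None = None

    def __post_init__(self):
        for name in ("nasion", "supra_aural_left", "supra_aural_right", "sella"):
            p = getattr(self, name)
            if p is None:
                continue
            p = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise LandmarkSchemaError(f"non-finite coordinate in {name}")
            object.__setattr__(self, name, p)
        if np.allclose(self.supra_aural_left, self.supra_aural_right):
            raise LandmarkSchemaError("left and right supra-aurale coincide")

    @property
    def supra_aural_midpoint(self) -> np.ndarray:
        return 0.5 * (self.supra_aural_left + self.supra_aural_right)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        R = np.asarray(rotation)
        t = np.asarray(translation)
        return LandmarkSet(
            nasion=R @ self.nasion + t,
            supra_aural_left=R @ self.supra_aural_left + t,
            supra_aural_right=R @ self.supra_aural_right + t,
            sella=None if self.sella is None else R @ self.sella + t,
        )


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: mesh + landmarks + craniosynostosis subtype label."""

    id: str
    mesh: SurfaceMesh
    landmarks: LandmarkSet
    subtype: str

    def __post_init__(self):
        if self.subtype not in SUBTYPE_ORDER:
            raise ValueError(
                f"subtype {self.subtype!r} not one of {SUBTYPE_ORDER}"
            )


def _clean(mesh: trimesh.Trimesh, merge_tol: float = 1e-6) -> SurfaceMesh:
    """Merge near-duplicate vertices and drop degenerate faces."""
    mesh.merge_vertices(digits_vertex=int(round(-np.log10(merge_tol))))
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    if len(mesh.faces) == 0:
        raise MeshFormatError("mesh has no faces after cleaning")
    return SurfaceMesh(np.asarray(mesh.vertices, float), np.asarray(mesh.faces, np.intp))


def read_mesh(path: str | Path) -> SurfaceMesh:
    """Read a binary or ASCII STL file into a cleaned :class:`SurfaceMesh`.

    Duplicate vertices within 1e-6 mm are merged so that faces share
    indices; degenerate (zero-area) faces are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = trimesh.load_mesh(path, file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader failures
        raise MeshFormatError(f"cannot read STL {path}: {exc}") from exc
    if not isinstance(raw, trimesh.Trimesh) or len(raw.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangulated surface")
    return _clean(raw)


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a binary STL (84 + 50·n_faces bytes)."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    data = tm.export(file_type="stl")
    Path(path).write_bytes(data)


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read the JSON landmark sidecar; ``sella`` is optional."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise LandmarkSchemaError(f"invalid JSON in {path}: {exc}") from exc
    required = ("nasion", "supra_aural_left", "supra_aural_right")
    missing = [k for k in required if k not in doc]
    if missing:
        raise LandmarkSchemaError(f"{path} missing landmarks: {missing}")
    for key, val in doc.items():
        if not (isinstance(val, (list, tuple)) and len(val) == 3):
            raise LandmarkSchemaError(f"{path}: {key} is not an [x,y,z] triple")
    return LandmarkSet(
        nasion=doc["nasion"],
        supra_aural_left=doc["supra_aural_left"],
        supra_aural_right=doc["supra_aural_right"],
        sella=doc.get("sella"),
    )


def write_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    doc = {
        "nasion": lms.nasion.tolist(),
        "supra_aural_left": lms.supra_aural_left.tolist(),
        "supra_aural_right": lms.supra_aural_right.tolist(),
    }
    if lms.sella is not None:
        doc["sella"] = lms.sella.tolist()
    Path(path).write_text(json.dumps(doc, indent=1))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV (id, mesh_path, landmark_path, subtype)."""
    df = pd.read_csv(path, dtype=str)
    required = {"id", "mesh_path", "landmark_path", "subtype"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    bad = set(df["subtype"]) - set(SUBTYPE_ORDER)
    if bad:
        raise ValueError(f"unknown subtypes in manifest: {sorted(bad)}")
    return df


def load_cohort(manifest_path: str | Path) -> list[SubjectRecord]:
    """Load every subject listed in a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    root = manifest_path.parent
    subjects = []
    for row in df.itertuples(index=False):
        mesh_path = root / row.mesh_path
        lm_path = root / row.landmark_path
        if not mesh_path.exists():
            raise FileNotFoundError(f"subject {row.id}: missing mesh {mesh_path}")
        if not lm_path.exists():
            raise FileNotFoundError(f"subject {row.id}: missing landmarks {lm_path}")
        subjects.append(
            SubjectRecord(
                id=str(row.id),
                mesh=read_mesh(mesh_path),
                landmarks=read_landmarks(lm_path),
                subtype=row.subtype,
            )
        )
    return subjects
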