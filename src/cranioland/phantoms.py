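"""Seeded cranial phantom cohorts: control and three craniosynostosis
morphotypes with analytic ground truth.

Each phantom is a closed superellipsoid head shell (default semi-axes
80 × 95 × 70 mm — mediolateral, anteroposterior, craniocaudal — of an
infant-sized head) deformed by a subtype-specific field:

* scaphocephaly — anteroposterior elongation with mediolateral narrowing
  (y scaled by 1 + 0.25 m, x by 1 − 0.2 m);
* trigonocephaly — anterior wedge (x-compression growing with y for the
  anterior half);
* plagiocephaly — unilateral flattening of one posterior quadrant;
* control — no field.

Individual variation comes from per-subject log-radii jitter and a
low-order harmonic-polynomial radial perturbation ("bumps"), plus radial
vertex noise.  The true sella is an affine function of the latent shape
coefficients anchored near the shell centroid with an anterior-inferior
offset, plus isotropic noise — so it carries shape information beyond
what any constant per-class offset can capture, while remaining exactly
learnable from the latents.  Every subject is finally placed in a random
rigid pose; landmarks (nasion, both supra-aurale) are found by casting
rays along their anatomical directions onto the generated mesh, so they
lie exactly on the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial.transform import Rotation

from .config import SUBTYPE_ORDER
from .geometry import ray_mesh_intersections
from .meshio import (
    LandmarkSet,
    SubjectRecord,
    SurfaceMesh,
    write_landmarks,
    write_mesh,
)

__all__ = ["PhantomSpec", "PhantomSubject", "generate_phantom", "generate_cohort", "cephalic_index"]

#: Anchor of the true sella in the canonical (supra-aural midpoint) frame,
#: for the undeformed default shell: slightly anterior and inferior of the
#: shell centroid, i.e. roughly at the skull base.
ST_ANCHOR = np.array([0.0, 8.0, -12.0])

#: Fixed affine map from normalized latent shape coefficients to the
#: sella displacement (mm).  Ten latents: 3 log-radii jitters, the
#: deformation magnitude, 6 harmonic bump coefficients.
ST_COEFFICIENTS = np.array(
    [
        [0.9, -0.6, 0.3, 0.5, 1.1, -0.7, 0.4, -0.9, 0.6, 0.3],
        [-0.5, 1.2, -0.4, 1.4, -0.8, 0.9, -0.6, 0.5, -1.0, 0.7],
        [0.4, -0.7, 1.0, -1.1, 0.6, -0.5, 0.9, -0.4, 0.7, -1.2],
    ]
)

#: Normalization of the latent vector before the affine map (jitters in
#: units of their sd, deformation in units of its typical magnitude,
#: bumps in units of their sd).
LATENT_SCALE = np.array([0.04, 0.04, 0.04, 0.55, 0.015, 0.015, 0.015, 0.015, 0.015, 0.015])

#: Anatomical directions (canonical frame) used to place the landmarks.
_NASION_DIR = np.array([0.0, 1.0, -0.15]) / np.linalg.norm([0.0, 1.0, -0.15])
_SUPRA_LEFT_DIR = np.array([-1.0, 0.0, 0.0])
_SUPRA_RIGHT_DIR = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class PhantomSpec:
    """Generation conditions for one phantom subject."""

    subtype: str = "control"
    base_radii: tuple[float, float, float] = (80.0, 95.0, 70.0)
    deformation_magnitude: float = 0.6
    surface_noise_sd: float = 0.5  # mm, radial
    st_noise_sd: float = 1.0  # mm, isotropic
    seed: int = 0
    radii_jitter_sd: float = 0.04  # log-scale growth variation
    bump_sd: float = 0.015  # harmonic perturbation coefficients
    superellipsoid_exponent: float = 2.2
    mesh_subdivision: int = 3
    pose: bool = True  # random rigid pose vs canonical

    def __post_init__(self):
        if self.subtype not in SUBTYPE_ORDER:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if min(self.base_radii) <= 0:
            raise ValueError("radii must be positive")
        if self.surface_noise_sd < 0 or self.st_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if not (0.0 <= self.deformation_magnitude <= 1.0):
            raise ValueError("deformation magnitude must be in [0, 1]")
        if self.deformation_magnitude > 0.9:
            raise ValueError(
                "deformation magnitude > 0.9 produces self-intersecting shells; rejected"
            )


@dataclass(frozen=True)
class PhantomSubject:
    """A generated subject plus its latent shape coefficients."""

    record: SubjectRecord
    latents: np.ndarray  # (10,) raw latent vector
    spec: PhantomSpec

    @property
    def id(self) -> str:
        return self.record.id


def _superellipsoid_radius(directions: np.ndarray, radii, exponent: float) -> np.ndarray:
    """Radial distance of the superellipsoid surface along unit directions."""
    a, b, c = radii
    p = exponent
    s = (
        np.abs(directions[:, 0] / a) ** p
        + np.abs(directions[:, 1] / b) ** p
        + np.abs(directions[:, 2] / c) ** p
    )
    return s ** (-1.0 / p)


def _harmonic_basis(d: np.ndarray) -> np.ndarray:
    """Six low-order harmonic polynomials of the unit direction (smooth,
    zero-mean-ish fields used for individual shape variation)."""
    x, y, z = d[:, 0], d[:, 1], d[:, 2]
    return np.stack(
        [x * y, y * z, z * x, x**2 - y**2, 3 * z**2 - 1.0, z * (5 * z**2 - 3.0)],
        axis=1,
    )


def _subtype_fields(d: np.ndarray, subtype: str, m: float):
    """(radial multiplier, per-axis coordinate scale) of the subtype field."""
    radial = np.ones(len(d))
    scale = np.ones((len(d), 3))
    if subtype == "scaphocephaly":
        scale[:, 0] = 1.0 - 0.2 * m
        scale[:, 1] = 1.0 + 0.25 * m
    elif subtype == "trigonocephaly":
        scale[:, 0] = 1.0 - 0.4 * m * np.maximum(d[:, 1], 0.0)
    elif subtype == "plagiocephaly":
        center = np.array([-1.0, -1.0, 0.35])
        center /= np.linalg.norm(center)
        ang = np.arccos(np.clip(d @ center, -1.0, 1.0))
        radial = 1.0 - 0.3 * m * np.exp(-(ang**2) / (2 * 0.6**2))
    return radial, scale


def _surface_points(
    directions: np.ndarray, spec: PhantomSpec, jitter: np.ndarray, bumps: np.ndarray
) -> np.ndarray:
    radii = np.asarray(spec.base_radii) * np.exp(jitter)
    r = _superellipsoid_radius(directions, radii, spec.superellipsoid_exponent)
    r = r * (1.0 + _harmonic_basis(directions) @ bumps)
    radial, scale = _subtype_fields(directions, spec.subtype, spec.deformation_magnitude)
    return scale * (r * radial)[:, None] * directions


def _on_surface(point_dir: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Surface point along a direction from the canonical origin."""
    t, hit = ray_mesh_intersections(np.zeros(3), point_dir[None, :], vertices, faces)
    if not hit[0]:
        raise RuntimeError("landmark ray missed the phantom shell")
    return t[0] * point_dir


def generate_phantom(spec: PhantomSpec) -> PhantomSubject:
    """Generate one phantom subject (deterministic in ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    jitter = rng.normal(0.0, spec.radii_jitter_sd, size=3)
    bumps = rng.normal(0.0, spec.bump_sd, size=6)

    ico = trimesh.creation.icosphere(subdivisions=spec.mesh_subdivision)
    directions = np.asarray(ico.vertices, float)
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    vertices = _surface_points(directions, spec, jitter, bumps)
    if spec.surface_noise_sd > 0:
        vertices = vertices + rng.normal(0.0, spec.surface_noise_sd, len(vertices))[:, None] * directions
    faces = np.asarray(ico.faces, np.intp)

    nasion = _on_surface(_NASION_DIR, vertices, faces)
    left = _on_surface(_SUPRA_LEFT_DIR, vertices, faces)
    right = _on_surface(_SUPRA_RIGHT_DIR, vertices, faces)

    latents = np.concatenate([jitter, [spec.deformation_magnitude], bumps])
    st = ST_ANCHOR + ST_COEFFICIENTS @ (latents / LATENT_SCALE)
    if spec.st_noise_sd > 0:
        st = st + rng.normal(0.0, spec.st_noise_sd, size=3)

    if spec.pose:
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-40.0, 40.0, size=3)
    else:
        R, t = np.eye(3), np.zeros(3)
    mesh = SurfaceMesh(vertices @ R.T + t, faces)
    lms = LandmarkSet(
        nasion=R @ nasion + t,
        supra_aural_left=R @ left + t,
        supra_aural_right=R @ right + t,
        sella=R @ st + t,
    )
    record = SubjectRecord(
        id=f"{spec.subtype[:4]}-{spec.seed % 10**8:08d}",
        mesh=mesh,
        landmarks=lms,
        subtype=spec.subtype,
    )
    return PhantomSubject(record=record, latents=latents, spec=spec)


def generate_cohort(
    n_per_class: int,
    global_seed: int = 0,
    surface_noise_sd: float = 0.5,
    st_noise_sd: float = 1.0,
    deformation_range: tuple[float, float] = (0.3, 0.8),
    out_dir: str | Path | None = None,
    **spec_overrides,
) -> tuple[list[PhantomSubject], pd.DataFrame]:
    """Generate a balanced 4-class cohort with per-subject derived seeds.

    Affected subtypes draw their deformation magnitude uniformly from
    ``deformation_range``; controls have none.  When ``out_dir`` is given,
    STL meshes, landmark JSON sidecars and a manifest CSV are written
    there.  Returns the subjects and the manifest table.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    root_ss = np.random.SeedSequence(global_seed)
    children = root_ss.spawn(4 * n_per_class)
    subjects, rows = [], []
    i = 0
    for subtype in SUBTYPE_ORDER:
        for k in range(n_per_class):
            child = children[i]
            subj_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            draw_rng = np.random.default_rng(subj_seed + 1)
            if subtype == "control":
                m = 0.0
            else:
                m = float(draw_rng.uniform(*deformation_range))
            spec = PhantomSpec(
                subtype=subtype,
                deformation_magnitude=m,
                surface_noise_sd=surface_noise_sd,
                st_noise_sd=st_noise_sd,
                seed=subj_seed,
                **spec_overrides,
            )
            subj = generate_phantom(spec)
            record = SubjectRecord(
                id=f"{subtype[:4]}-{k:03d}",
                mesh=subj.record.mesh,
                landmarks=subj.record.landmarks,
                subtype=subtype,
            )
            subj = PhantomSubject(record=record, latents=subj.latents, spec=spec)
            subjects.append(subj)
            rows.append(
                {
                    "id": record.id,
                    "mesh_path": f"{record.id}.stl",
                    "landmark_path": f"{record.id}.json",
                    "subtype": subtype,
                }
            )
            i += 1
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for subj in subjects:
            write_mesh(subj.record.mesh, out_dir / f"{subj.id}.stl")
            write_landmarks(subj.record.landmarks, out_dir / f"{subj.id}.json")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return subjects, manifest


def cephalic_index(mesh: SurfaceMesh) -> float:
    """Cephalic index (max width / max length × 100) of an aligned mesh.

    Meaningful only in the canonical frame (x mediolateral, y
    anteroposterior); align first for posed meshes.
    """
    v = mesh.vertices
    width = v[:, 0].max() - v[:, 0].min()
    length = v[:, 1].max() - v[:, 1].min()
    return float(100.0 * width / length)
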