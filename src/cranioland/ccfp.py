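"""Computed Cranial Focal Point (CCFP) baseline.

The CCFP is the point where the surface normals of the cranial vault
converge in a least-squares sense: the unique minimizer of the summed
squared distances from a point to the lines spanned by each vertex normal.
With a per-subtype offset vector calibrated on training data it serves as
the conventional surface-only estimate of the sella turcica, and as the
baseline the shape-model network is compared against.  Its known weakness
— a constant offset cannot follow shape-dependent displacement of the
sella, especially for asymmetric deformations — is exactly what the
comparison probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import SUBTYPE_ORDER
from .standardize import RayTemplate, StandardizedSurface, default_ray_template

__all__ = [
    "CcfpResult",
    "CcfpOffsetModel",
    "IllConditionedNormalsError",
    "estimate_vertex_normals",
    "compute_ccfp",
    "fit_ccfp_offset",
    "predict_st_ccfp",
]


class IllConditionedNormalsError(RuntimeError):
    """Normal lines are near-parallel; no stable convergence point."""


@dataclass(frozen=True)
class CcfpResult:
    """Focal point (mm), its mean squared point-to-line residual (mm²),
    and — once an offset has been applied — the sella estimate."""

    focal_point: np.ndarray
    residual: float
    st_estimate: np.ndarray | None = None


@dataclass(frozen=True)
class CcfpOffsetModel:
    """Per-subtype constant offset (true sella − focal point), mm."""

    offsets: dict  # subtype -> (3,) array

    def offset_for(self, subtype: str) -> np.ndarray:
        if subtype not in self.offsets:
            raise KeyError(f"no offset for subtype {subtype!r}")
        return self.offsets[subtype]


def estimate_vertex_normals(
    surf: StandardizedSurface, template: RayTemplate | None = None
) -> np.ndarray:
    """Outward unit vertex normals over the template connectivity.

    Area-weighted average of incident triangle normals (the cross-product
    accumulation), re-oriented so each normal has positive dot product
    with (vertex − origin); a vertex with a degenerate neighbourhood falls
    back to the radial direction.
    """
    template = template or default_ray_template()
    v, f = surf.vertices, template.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # area-weighted
    normals = np.zeros_like(v)
    for k in range(3):
        np.add.at(normals, f[:, k], fn)
    norms = np.linalg.norm(normals, axis=1)
    degenerate = norms < 1e-12
    radial = v - surf.origin
    radial /= np.maximum(np.linalg.norm(radial, axis=1, keepdims=True), 1e-12)
    normals = np.where(degenerate[:, None], radial, normals / np.maximum(norms, 1e-12)[:, None])
    flip = np.einsum("ij,ij->i", normals, radial) < 0
    normals[flip] *= -1.0
    return normals


def compute_ccfp(
    surf: StandardizedSurface,
    template: RayTemplate | None = None,
    cond_limit: float = 1e8,
    normals: np.ndarray | None = None,
) -> CcfpResult:
    """Least-squares convergence point of the vertex normal lines.

    Solves the rank-3 normal equations ``(Σ_i (I − n_i n_iᵀ)) p =
    Σ_i (I − n_i n_iᵀ) v_i`` in closed form; the residual is the mean
    squared distance from the solution to the normal lines.  ``normals``
    overrides the estimated vertex normals (e.g. analytic ones).
    """
    if normals is None:
        normals = estimate_vertex_normals(surf, template)
    v = surf.vertices
    # A = sum(I - n n^T), b = sum((I - n n^T) v)
    nnT = np.einsum("ij,ik->jk", normals, normals)
    A = len(v) * np.eye(3) - nnT
    b = v.sum(axis=0) - np.einsum("ij,i->j", normals, np.einsum("ij,ij->i", normals, v))
    if np.linalg.cond(A) > cond_limit:
        raise IllConditionedNormalsError("normal lines are near-parallel")
    p = np.linalg.solve(A, b)
    diff = v - p
    along = np.einsum("ij,ij->i", diff, normals)
    residual = float(np.mean(np.einsum("ij,ij->i", diff, diff) - along**2))
    return CcfpResult(focal_point=p, residual=max(residual, 0.0))


def fit_ccfp_offset(subjects, template: RayTemplate | None = None) -> CcfpOffsetModel:
    """Calibrate per-subtype offsets on training subjects with known sella.

    Each offset is the mean of (true sella − focal point) over the
    training subjects of that subtype, in the aligned frame.  A subtype
    with no training subjects falls back to the pooled mean (warned).
    """
    template = template or default_ray_template()
    rows = {s: [] for s in SUBTYPE_ORDER}
    pooled = []
    for subj in subjects:
        if subj.sella is None:
            raise ValueError(f"subject {subj.id} has no ground-truth sella")
        delta = subj.sella - compute_ccfp(subj.surface, template).focal_point
        rows[subj.subtype].append(delta)
        pooled.append(delta)
    if not pooled:
        raise ValueError("no training subjects")
    pooled_mean = np.mean(pooled, axis=0)
    offsets = {}
    for subtype, deltas in rows.items():
        if deltas:
            offsets[subtype] = np.mean(deltas, axis=0)
        else:
            warnings.warn(
                f"no training subjects for subtype {subtype!r}; using pooled offset",
                stacklevel=2,
            )
            offsets[subtype] = pooled_mean
    return CcfpOffsetModel(offsets=offsets)


def predict_st_ccfp(
    surf: StandardizedSurface,
    subtype: str,
    model: CcfpOffsetModel,
    template: RayTemplate | None = None,
) -> np.ndarray:
    """Sella estimate: focal point + calibrated subtype offset."""
    result = compute_ccfp(surf, template)
    return result.focal_point + model.offset_for(subtype)
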