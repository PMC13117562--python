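"""Shared fixtures: templates, analytic surfaces and small seeded cohorts.

Everything is generated programmatically; no data files are stored.
"""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from cranioland import (
    LandmarkSet,
    SurfaceMesh,
    default_ray_template,
    generate_cohort,
    standardize_subject,
)
from cranioland.standardize import StandardizedSurface

import matplotlib

matplotlib.use("Agg")


@pytest.fixture(scope="session")
def template():
    return default_ray_template()


def template_sphere_mesh(template, radius=100.0, center=(0.0, 0.0, 0.0)):
    """Full icosphere whose vertex set contains the template directions
    exactly (same subdivision + tilt), so template rays pass through
    vertices and hit the surface at exactly ``radius``."""
    ico = trimesh.creation.icosphere(subdivisions=template.subdivision)
    v = np.asarray(ico.vertices, float)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    R = Rotation.from_euler("xy", template.tilt_deg, degrees=True).as_matrix()
    v = v @ R.T
    return SurfaceMesh(v * radius + np.asarray(center), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def sphere100(template):
    return template_sphere_mesh(template, 100.0)


@pytest.fixture(scope="session")
def canonical_landmarks():
    """Landmarks already in the canonical horizontal pose."""
    return LandmarkSet(
        nasion=[0.0, 95.0, 0.0],
        supra_aural_left=[-80.0, 0.0, 0.0],
        supra_aural_right=[80.0, 0.0, 0.0],
        sella=[0.0, 8.0, -12.0],
    )


def sphere_surface(template, radius=100.0, center=(0.0, 0.0, 0.0)):
    """Exact standardized sphere: template vertices at ``radius`` around
    ``center`` (no raycasting involved)."""
    center = np.asarray(center, float)
    return StandardizedSurface(
        vertices=center + radius * template.directions,
        origin=center,
        source_id="sphere",
        miss_mask=np.zeros(template.n_directions, bool),
    )


def ellipsoid_surface(template, radii=(100.0, 80.0, 70.0)):
    """Exact standardized ellipsoid sampled along template directions."""
    d = template.directions
    a, b, c = radii
    r = 1.0 / np.sqrt((d[:, 0] / a) ** 2 + (d[:, 1] / b) ** 2 + (d[:, 2] / c) ** 2)
    return StandardizedSurface(
        vertices=r[:, None] * d,
        origin=np.zeros(3),
        source_id="ellipsoid",
        miss_mask=np.zeros(template.n_directions, bool),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """8-per-class phantom cohort (32 subjects), standard noise settings."""
    subjects, manifest = generate_cohort(8, global_seed=11)
    return subjects, manifest


@pytest.fixture(scope="session")
def small_standardized(small_cohort, template):
    subjects, _ = small_cohort
    return [standardize_subject(s.record, template) for s in subjects]


@pytest.fixture()
def bumpy_phantom():
    """Single seeded bumpy phantom in canonical pose (no rigid motion)."""
    from cranioland import PhantomSpec, generate_phantom

    return generate_phantom(
        PhantomSpec(subtype="plagiocephaly", seed=42, pose=False, deformation_magnitude=0.5)
    )
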