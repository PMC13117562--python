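"""Ray template construction, horizontal alignment and raycast resampling."""

import numpy as np
import pytest

from cranioland import (
    LandmarkSet,
    SurfaceMesh,
    build_ray_template,
    horizontal_align,
    raycast_surface,
)
from cranioland.config import N_TEMPLATE_VERTICES
from cranioland.standardize import RaycastQualityError

from conftest import template_sphere_mesh


# --- independent icosphere-count oracle: plain midpoint subdivision ---

def _icosphere_vertex_count(subdivisions: int) -> int:
    phi = (1 + np.sqrt(5)) / 2
    verts = [
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ]
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [np.array(v, float) / np.linalg.norm(v) for v in verts]
    for _ in range(subdivisions):
        cache = {}
        new_faces = []

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts[i] + verts[j]
                verts.append(m / np.linalg.norm(m))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
        faces = new_faces
    return len(verts)


class TestRayTemplate:
    def test_default_has_exactly_1016_directions(self, template):
        assert template.n_directions == N_TEMPLATE_VERTICES == 1016

    def test_directions_unit_and_above_cut_and_distinct(self, template):
        norms = np.linalg.norm(template.directions, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)
        assert np.all(
            template.directions[:, 2] >= np.sin(np.radians(template.cut_latitude_deg)) - 1e-12
        )
        # pairwise distinct
        d = template.directions
        gram = d @ d.T
        np.fill_diagonal(gram, -1.0)
        assert gram.max() < 1.0 - 1e-9

    def test_construction_is_deterministic(self, template):
        again = build_ray_template()
        assert np.array_equal(template.directions, again.directions)
        assert np.array_equal(template.faces, again.faces)

    @pytest.mark.parametrize(
        "subdivision,expected", [(0, 12), (2, 162), (4, 2562)]
    )
    def test_full_sphere_counts_match_subdivision_oracle(self, subdivision, expected):
        t = build_ray_template(subdivision=subdivision, cut_latitude_deg=-90.0)
        assert t.n_directions == expected
        assert _icosphere_vertex_count(subdivision) == expected

    def test_ordering_is_z_descending(self, template):
        z = template.directions[:, 2]
        assert np.all(np.diff(z) <= 1e-12)

    def test_empty_cut_raises(self):
        with pytest.raises(ValueError):
            build_ray_template(subdivision=1, cut_latitude_deg=89.9)


class TestHorizontalAlign:
    def test_canonical_pose_is_fixed_point(self, sphere100, canonical_landmarks):
        mesh, lms, tr = horizontal_align(sphere100, canonical_landmarks)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tr.translation, 0.0, atol=1e-9)
        assert np.allclose(mesh.vertices, sphere100.vertices, atol=1e-9)

    def test_rigidity_preserves_pairwise_distances(self, bumpy_phantom):
        rec = bumpy_phantom.record
        mesh, _, _ = horizontal_align(rec.mesh, rec.landmarks)
        rng = np.random.default_rng(0)
        i = rng.integers(0, rec.mesh.n_vertices, 400)
        j = rng.integers(0, rec.mesh.n_vertices, 400)
        d0 = np.linalg.norm(rec.mesh.vertices[i] - rec.mesh.vertices[j], axis=1)
        d1 = np.linalg.norm(mesh.vertices[i] - mesh.vertices[j], axis=1)
        assert np.allclose(d1, d0, rtol=1e-9, atol=1e-9)

    def test_alignment_undoes_random_rotation(self, bumpy_phantom):
        # compose-and-invert oracle: aligning a rigidly moved copy must land
        # on the same canonical coordinates as aligning the original
        from scipy.spatial.transform import Rotation

        rec = bumpy_phantom.record
        base_mesh, base_lms, _ = horizontal_align(rec.mesh, rec.landmarks)
        rng = np.random.default_rng(7)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-30, 30, 3)
        moved = SurfaceMesh(rec.mesh.vertices @ R.T + t, rec.mesh.faces)
        moved_lms = rec.landmarks.transformed(R, t)
        mesh2, lms2, _ = horizontal_align(moved, moved_lms)
        assert np.allclose(mesh2.vertices, base_mesh.vertices, atol=1e-6)
        assert np.allclose(lms2.nasion, base_lms.nasion, atol=1e-6)
        assert np.allclose(lms2.sella, base_lms.sella, atol=1e-6)

    def test_degenerate_landmarks_raise(self):
        mesh = SurfaceMesh(np.eye(4, 3) * 50, [[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]])
        with pytest.raises(Exception):
            # nasion on the supra-aural axis
            lms = LandmarkSet(
                nasion=[10.0, 0, 0],
                supra_aural_left=[-80.0, 0, 0],
                supra_aural_right=[80.0, 0, 0],
            )
            horizontal_align(mesh, lms)


def _brute_force_ray_distances(origin, directions, vertices, faces):
    """Independent scalar oracle: plane intersection + inside test via
    signed areas (a different formulation than the packaged kernel)."""
    out = np.full(len(directions), np.nan)
    tris = vertices[faces]
    for k, d in enumerate(directions):
        best = np.nan
        for a, b, c in tris:
            n = np.cross(b - a, c - a)
            denom = n @ d
            if abs(denom) < 1e-14:
                continue
            t = n @ (a - origin) / denom
            if t <= 1e-12:
                continue
            p = origin + t * d
            # inside iff the three sub-triangle normals agree with n
            if (
                np.cross(b - a, p - a) @ n >= -1e-9
                and np.cross(c - b, p - b) @ n >= -1e-9
                and np.cross(a - c, p - c) @ n >= -1e-9
            ):
                if np.isnan(best) or t > best:
                    best = t
        out[k] = best
    return out


class TestRaycast:
    def test_sphere_distances_exact(self, template, sphere100, canonical_landmarks):
        surf = raycast_surface(sphere100, canonical_landmarks, template)
        r = np.linalg.norm(surf.vertices - surf.origin, axis=1)
        assert np.allclose(r, 100.0, atol=1e-6)
        assert not surf.miss_mask.any()

    def test_farthest_hit_discards_inner_shell(self, template, canonical_landmarks):
        inner = template_sphere_mesh(template, 80.0)
        outer = template_sphere_mesh(template, 100.0)
        both = SurfaceMesh(
            np.vstack([inner.vertices, outer.vertices]),
            np.vstack([inner.faces, outer.faces + inner.n_vertices]),
        )
        surf = raycast_surface(both, canonical_landmarks, template)
        r = np.linalg.norm(surf.vertices - surf.origin, axis=1)
        assert np.allclose(r, 100.0, atol=1e-6)

    def test_matches_brute_force_oracle(self, template, bumpy_phantom):
        rec = bumpy_phantom.record
        mesh, lms, _ = horizontal_align(rec.mesh, rec.landmarks)
        # subsample rays to keep the scalar oracle fast
        idx = np.arange(0, template.n_directions, 13)
        surf = raycast_surface(mesh, lms, template)
        t_pkg = np.linalg.norm(surf.vertices - surf.origin, axis=1)
        t_ref = _brute_force_ray_distances(
            lms.supra_aural_midpoint, template.directions[idx], mesh.vertices, mesh.faces
        )
        assert np.all(np.isfinite(t_ref))
        assert np.allclose(t_pkg[idx], t_ref, atol=1e-9)

    def test_face_order_permutation_invariance(self, template, bumpy_phantom):
        rec = bumpy_phantom.record
        mesh, lms, _ = horizontal_align(rec.mesh, rec.landmarks)
        rng = np.random.default_rng(3)
        perm = rng.permutation(mesh.n_faces)
        shuffled = SurfaceMesh(mesh.vertices, mesh.faces[perm])
        a = raycast_surface(mesh, lms, template)
        b = raycast_surface(shuffled, lms, template)
        assert np.allclose(a.vertices, b.vertices, atol=1e-9)

    def test_star_shaped_phantom_has_no_misses(self, template, small_standardized):
        for subj in small_standardized:
            assert not subj.surface.miss_mask.any()

    def test_open_shell_raises_quality_error(self, template, canonical_landmarks):
        # keep only a thin polar cap: most rays miss
        full = template_sphere_mesh(template, 100.0)
        keep = full.vertices[full.faces].mean(axis=1)[:, 2] > 95.0
        cap = SurfaceMesh(full.vertices, full.faces[keep])
        with pytest.raises(RaycastQualityError):
            raycast_surface(cap, canonical_landmarks, template)
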