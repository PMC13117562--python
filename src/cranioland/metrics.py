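"""Accuracy metrics: landmark deviations, signed distance maps, and the
normality-gated paired comparison of the two sella estimators.

Landmark accuracy is reported as the Euclidean distance and the signed
per-axis deviation between predicted and true sella.  Realignment quality
is reported as a signed distance map: for every vertex of the
query-aligned mesh, the distance to the closest point on the
reference-aligned mesh, signed positive outside the reference surface,
summarized by the 5th percentile, 95th percentile and mean.  Method
comparisons use a paired t-test when the paired differences pass a
Shapiro–Wilk normality check at the chosen alpha, and a Wilcoxon
signed-rank test otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .frames import build_sn_frame, align_to_frame
from .geometry import closest_points_on_mesh, face_normals
from .meshio import SurfaceMesh
from .standardize import horizontal_align

__all__ = [
    "DistanceMap",
    "ComparisonReport",
    "euclidean_error",
    "per_axis_deviation",
    "distance_map",
    "paired_compare",
    "evaluate_cohort",
]


def euclidean_error(pred: np.ndarray, truth: np.ndarray) -> float:
    """L2 distance (mm) between predicted and true landmark."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(truth))):
        raise ValueError("non-finite point")
    return float(np.linalg.norm(pred - truth))


def per_axis_deviation(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Signed componentwise deviation pred − truth (x, y, z; mm)."""
    return np.asarray(pred, dtype=float) - np.asarray(truth, dtype=float)


@dataclass(frozen=True)
class DistanceMap:
    """Per-vertex signed distances (mm) of a query mesh to a reference.

    Positive values lie outside the reference surface.  ``p5``, ``p95``
    and ``mean`` are recomputable from ``distances`` (linear-interpolation
    percentiles).
    """

    distances: np.ndarray  # (V,) signed mm

    @property
    def p5(self) -> float:
        return float(np.percentile(self.distances, 5))

    @property
    def p95(self) -> float:
        return float(np.percentile(self.distances, 95))

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    def summary(self) -> dict:
        return {"p5": self.p5, "p95": self.p95, "mean": self.mean}


def distance_map(query: SurfaceMesh, reference: SurfaceMesh) -> DistanceMap:
    """Signed closest-point distances from query vertices to the reference.

    Exact point-to-triangle closest points; the sign is the sign of the
    dot product between (vertex − closest point) and the reference face
    normal at the closest point (outward positive).  Both meshes must be
    in a common coordinate frame.
    """
    if reference.n_faces == 0:
        raise ValueError("empty reference mesh")
    cp, dist, fi = closest_points_on_mesh(query.vertices, reference.vertices, reference.faces)
    normals = face_normals(reference.vertices, reference.faces)[fi]
    sign = np.sign(np.einsum("ij,ij->i", query.vertices - cp, normals))
    sign[sign == 0] = 1.0
    signed = np.where(dist > 0, sign * dist, 0.0)
    return DistanceMap(distances=signed)


def paired_compare(a, b, alpha: float = 0.05) -> dict:
    """Paired comparison with a Shapiro–Wilk gate on the differences.

    If the differences pass normality (p >= alpha) a paired t-test is
    used, otherwise a Wilcoxon signed-rank test.  Degenerate inputs
    (constant differences) cannot be assessed for normality and are
    routed to the Wilcoxon branch; identical samples are reported as
    'no-difference'.  Returns the test name, statistic, two-sided p-value
    and the gating normality p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need equal-length paired samples of length >= 3")
    diff = a - b
    if np.allclose(diff, 0.0):
        return {"test": "no-difference", "statistic": 0.0, "p_value": 1.0, "shapiro_p": np.nan}
    if np.ptp(diff) == 0.0:
        shapiro_p = np.nan  # constant nonzero differences: normality undefined
    else:
        shapiro_p = float(stats.shapiro(diff).pvalue)
    if np.isfinite(shapiro_p) and shapiro_p >= alpha:
        res = stats.ttest_rel(a, b)
        name = "paired-t"
    else:
        res = stats.wilcoxon(a, b)
        name = "wilcoxon"
    return {
        "test": name,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "shapiro_p": shapiro_p,
    }


@dataclass
class ComparisonReport:
    """Cohort-level accuracy report for both sella estimators.

    ``subject_table`` has one row per subject and method with the
    Euclidean and per-axis deviations (and distance-map summaries when
    computed); ``summary`` aggregates mean ± SD per subtype and pooled;
    ``tests`` holds the paired comparisons with the normality p-value that
    chose each branch; ``excluded`` lists subjects dropped for missing
    predictions.
    """

    subject_table: pd.DataFrame
    summary: pd.DataFrame
    tests: dict
    excluded: list = field(default_factory=list)
    alpha: float = 0.05


def _method_rows(predictions: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    rows, excluded = [], []
    for rec in predictions.to_dict("records"):
        truth = np.array([rec["true_x"], rec["true_y"], rec["true_z"]])
        for method in ("ffnn", "ccfp"):
            pred = np.array([rec[f"{method}_x"], rec[f"{method}_y"], rec[f"{method}_z"]])
            if not np.all(np.isfinite(pred)):
                excluded.append((rec["id"], method))
                continue
            dev = per_axis_deviation(pred, truth)
            rows.append(
                {
                    "id": rec["id"],
                    "subtype": rec["subtype"],
                    "method": method,
                    "euclidean": euclidean_error(pred, truth),
                    "dev_x": dev[0],
                    "dev_y": dev[1],
                    "dev_z": dev[2],
                }
            )
    return pd.DataFrame(rows), excluded


def evaluate_cohort(
    predictions: pd.DataFrame,
    records=None,
    alpha: float = 0.05,
    compute_maps: bool = True,
) -> ComparisonReport:
    """Full two-part evaluation of cross-validation output.

    Part one compares predicted sella coordinates to ground truth
    (Euclidean + per-axis, per subtype and pooled, paired tests between
    methods).  Part two — when the original subject ``records`` are given
    and ``compute_maps`` is set — realigns every subject's full mesh into
    the S-N frame built from each method's predicted sella and from the
    true sella, and summarizes the signed distance maps between each
    method's alignment and the true alignment.
    """
    table, excluded = _method_rows(predictions)
    if table.empty:
        raise ValueError("no usable predictions")

    if compute_maps and records is not None:
        by_id = {r.id: r for r in records}
        map_rows = {}
        for rec in predictions.to_dict("records"):
            subj = by_id.get(rec["id"])
            if subj is None:
                continue
            mesh_a, lms_a, _ = horizontal_align(subj.mesh, subj.landmarks)
            truth = np.array([rec["true_x"], rec["true_y"], rec["true_z"]])
            ref_mesh = align_to_frame(mesh_a, build_sn_frame(truth, lms_a))
            for method in ("ffnn", "ccfp"):
                pred = np.array([rec[f"{method}_x"], rec[f"{method}_y"], rec[f"{method}_z"]])
                if not np.all(np.isfinite(pred)):
                    continue
                q_mesh = align_to_frame(mesh_a, build_sn_frame(pred, lms_a))
                dm = distance_map(q_mesh, ref_mesh)
                map_rows[(rec["id"], method)] = dm.summary()
        if map_rows:
            for col in ("p5", "p95", "mean"):
                table[f"map_{col}"] = [
                    map_rows.get((r.id, r.method), {}).get(col, np.nan)
                    for r in table.itertuples(index=False)
                ]

    metric_cols = [c for c in table.columns if c not in ("id", "subtype", "method")]
    pooled = table.groupby("method")[metric_cols].agg(["mean", "std"])
    pooled["subtype"] = "all"
    by_subtype = table.groupby(["method", "subtype"])[metric_cols].agg(["mean", "std"])
    summary = pd.concat(
        [pooled.set_index("subtype", append=True), by_subtype]
    ).sort_index()

    tests = {}
    wide = table.pivot(index="id", columns="method", values="euclidean").dropna()
    if len(wide) >= 3:
        tests["euclidean"] = paired_compare(wide["ffnn"], wide["ccfp"], alpha)
    for axis in ("dev_x", "dev_y", "dev_z"):
        w = table.pivot(index="id", columns="method", values=axis).dropna().abs()
        if len(w) >= 3:
            tests[axis] = paired_compare(w["ffnn"], w["ccfp"], alpha)
    if "map_mean" in table.columns:
        for col in ("map_p5", "map_p95", "map_mean"):
            w = table.pivot(index="id", columns="method", values=col).dropna().abs()
            if len(w) >= 3:
                tests[col] = paired_compare(w["ffnn"], w["ccfp"], alpha)

    return ComparisonReport(
        subject_table=table, summary=summary, tests=tests, excluded=excluded, alpha=alpha
    )
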