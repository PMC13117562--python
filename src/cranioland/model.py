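"""Top-level modelling interface.

`SellaLandmarkModel` bundles a cohort (clinical meshes from a manifest, or
synthetic phantoms) with a :class:`~cranioland.config.RunConfig`;
``fit()`` standardizes every subject, runs the subtype-stratified
cross-validation of both sella estimators (shape-model network and CCFP
baseline), and returns a :class:`SellaLandmarkResults` carrying per-subject
predictions, error tables, paired-test diagnostics and a ``summary()``
text report.  Plotting and S-N realignment evaluation hang off the
results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import RunConfig, SUBTYPE_ORDER
from .meshio import SubjectRecord, load_cohort
from .metrics import ComparisonReport, evaluate_cohort
from .network import CrossValidationOutput, cross_validate
from .standardize import build_ray_template, standardize_subject

__all__ = ["SellaLandmarkModel", "SellaLandmarkResults"]


class SellaLandmarkModel:
    """Sella-landmark prediction model over a cohort of cranial surfaces.

    Parameters
    ----------
    records : sequence of SubjectRecord
        Subjects with meshes, annotated landmarks (including ground-truth
        sella) and subtype labels.
    config : RunConfig, optional
        Pipeline constants; defaults mirror the standard configuration
        (1016-direction template, PCA 32/10, 400-epoch training).

    Examples
    --------
    >>> from cranioland import SellaLandmarkModel
    >>> model = SellaLandmarkModel.from_synthetic(n_per_class=10, seed=7)
    >>> results = model.fit()
    >>> print(results.summary())            # doctest: +SKIP
    """

    def __init__(self, records, config: RunConfig | None = None):
        self.records = list(records)
        if not self.records:
            raise ValueError("empty cohort")
        self.config = config or RunConfig()
        self.template = build_ray_template(
            self.config.template_subdivision,
            self.config.template_cut_latitude_deg,
            (self.config.template_tilt_x_deg, self.config.template_tilt_y_deg),
        )
        self._standardized = None

    @classmethod
    def from_manifest(cls, manifest_path, config: RunConfig | None = None):
        """Build from a cohort manifest CSV (id, mesh_path, landmark_path, subtype)."""
        return cls(load_cohort(manifest_path), config)

    @classmethod
    def from_synthetic(
        cls, n_per_class: int = 50, seed: int = 0, config: RunConfig | None = None, **kwargs
    ):
        """Build from a seeded phantom cohort (see :mod:`cranioland.phantoms`)."""
        from .phantoms import generate_cohort

        subjects, _ = generate_cohort(n_per_class, global_seed=seed, **kwargs)
        return cls([s.record for s in subjects], config)

    def standardize(self):
        """Align + raycast every subject (cached)."""
        if self._standardized is None:
            self._standardized = [
                standardize_subject(r, self.template) for r in self.records
            ]
        return self._standardized

    def fit(self, seed: int | None = None, compute_maps: bool = False) -> "SellaLandmarkResults":
        """Run the cross-validated estimation of both methods.

        With ``compute_maps`` the S-N realignment distance maps are also
        computed for every subject (slower; can be done later via
        :meth:`SellaLandmarkResults.evaluate_alignment`).
        """
        if seed is None:
            seed = self.config.seed
        standardized = self.standardize()
        cv = cross_validate(standardized, self.config, seed=seed, template=self.template)
        report = evaluate_cohort(
            cv.predictions,
            self.records if compute_maps else None,
            alpha=self.config.alpha,
            compute_maps=compute_maps,
        )
        return SellaLandmarkResults(model=self, cv=cv, report=report, seed=seed)


@dataclass
class SellaLandmarkResults:
    """Fitted results: out-of-fold predictions, error tables, diagnostics."""

    model: SellaLandmarkModel
    cv: CrossValidationOutput
    report: ComparisonReport
    seed: int

    @property
    def predictions(self) -> pd.DataFrame:
        """Per-subject table: fold, true sella and both predictions (mm)."""
        return self.cv.predictions

    @property
    def errors(self) -> pd.DataFrame:
        """Long-format per-subject error table (one row per method)."""
        return self.report.subject_table

    def mean_euclidean_error(self, method: str) -> float:
        t = self.report.subject_table
        return float(t.loc[t["method"] == method, "euclidean"].mean())

    def evaluate_alignment(self, alpha: float | None = None) -> ComparisonReport:
        """(Re)compute the evaluation including S-N distance maps."""
        self.report = evaluate_cohort(
            self.cv.predictions,
            self.model.records,
            alpha=alpha if alpha is not None else self.model.config.alpha,
            compute_maps=True,
        )
        return self.report

    def summary(self) -> str:
        """Human-readable report in the spirit of a regression summary."""
        t = self.report.subject_table
        n = t["id"].nunique()
        lines = [
            "Sella landmark prediction — cross-validated results",
            "=" * 57,
            f"subjects: {n}    folds: {self.model.config.folds}    seed: {self.seed}",
            f"epochs: {self.model.config.epochs}    features: "
            f"{self.model.config.n_features} PC scores + {len(SUBTYPE_ORDER)} class indicators",
            "",
            f"{'method':<10}{'Euclid mean±SD (mm)':>22}{'dx mean':>10}{'dy mean':>10}{'dz mean':>10}",
            "-" * 62,
        ]
        for method in ("ffnn", "ccfp"):
            g = t[t["method"] == method]
            lines.append(
                f"{method:<10}"
                f"{g['euclidean'].mean():>13.2f} ± {g['euclidean'].std():<5.2f}"
                f"{g['dev_x'].mean():>10.2f}{g['dev_y'].mean():>10.2f}{g['dev_z'].mean():>10.2f}"
            )
        if "map_mean" in t.columns:
            lines += ["", f"{'method':<10}{'map p5':>10}{'map p95':>10}{'map mean':>10}  (S-N realignment, mm)"]
            for method in ("ffnn", "ccfp"):
                g = t[t["method"] == method]
                lines.append(
                    f"{method:<10}{g['map_p5'].mean():>10.2f}"
                    f"{g['map_p95'].mean():>10.2f}{g['map_mean'].mean():>10.2f}"
                )
        if self.report.tests:
            lines.append("")
            for name, res in self.report.tests.items():
                lines.append(
                    f"{name:<10} {res['test']:<13} p = {res['p_value']:.4g}"
                    f"   (Shapiro p = {res['shapiro_p']:.3g})"
                )
        per_class = (
            t[t["method"] == "ffnn"].groupby("subtype")["euclidean"].agg(["mean", "std", "count"])
        )
        lines += ["", "network error by subtype (mm):"]
        for subtype, row in per_class.iterrows():
            lines.append(
                f"  {subtype:<16}{row['mean']:.2f} ± {row['std']:.2f}   (n = {int(row['count'])})"
            )
        return "\n".join(lines)

    def plot_error_distribution(self, ax=None):
        """Boxplots of per-subject Euclidean errors for both methods."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        t = self.report.subject_table
        data = [
            t.loc[t["method"] == m, "euclidean"].to_numpy() for m in ("ffnn", "ccfp")
        ]
        ax.boxplot(data, tick_labels=["PCA-FFNN", "CCFP"])
        ax.set_ylabel("Euclidean error (mm)")
        ax.set_title("Sella prediction error")
        return ax
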