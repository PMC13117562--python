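"""Deployable sella predictor: train on a full cohort, save, reload, predict.

A :class:`SellaPredictor` bundles everything a prediction needs — the ray
template parameters, the fitted PCA (mean, components, variances, score
standard deviations), the trained network parameters and the CCFP
offsets — in one documented NPZ container plus a config snapshot, so
predictions are reproducible across sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import ccfp as ccfp_mod
from . import shape as shape_mod
from .config import RunConfig, SUBTYPE_ORDER
from .meshio import LandmarkSet, SurfaceMesh
from .network import NetworkConfig, TrainConfig, TrainedModel, train
from .shape import PcaModel
from .standardize import build_ray_template, horizontal_align, raycast_surface

__all__ = ["SellaPredictor", "fit_predictor"]


@dataclass
class SellaPredictor:
    """Trained end-to-end predictor of the sella coordinate."""

    config: RunConfig
    pca: PcaModel
    network: TrainedModel
    ccfp_offsets: dict  # subtype -> (3,) array

    def _template(self):
        return build_ray_template(
            self.config.template_subdivision,
            self.config.template_cut_latitude_deg,
            (self.config.template_tilt_x_deg, self.config.template_tilt_y_deg),
        )

    def predict(
        self, mesh: SurfaceMesh, landmarks: LandmarkSet, subtype: str
    ) -> dict:
        """Predict the sella from one annotated mesh.

        Returns both estimates in the original (input) coordinate system:
        ``{"ffnn": (3,), "ccfp": (3,)}``.
        """
        template = self._template()
        mesh_a, lms_a, transform = horizontal_align(mesh, landmarks)
        surf = raycast_surface(mesh_a, lms_a, template)
        n_scores = min(self.config.n_features, self.pca.n_components)
        scores = shape_mod.project(self.pca, surf, n=n_scores)
        if n_scores < self.config.n_features:
            scores = np.r_[scores, np.zeros(self.config.n_features - n_scores)]
        feats = shape_mod.make_feature_vector(scores, subtype).combined
        st_ffnn = self.network.predict(feats)
        focal = ccfp_mod.compute_ccfp(surf, template).focal_point
        st_ccfp = focal + self.ccfp_offsets[subtype]
        inv = transform.inverse()
        return {"ffnn": inv.apply(st_ffnn), "ccfp": inv.apply(st_ccfp)}

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.config.to_file(directory / "config.txt")
        arrays = {
            "pca_mean": self.pca.mean_shape,
            "pca_components": self.pca.components,
            "pca_explained_variance": self.pca.explained_variance,
            "pca_explained_variance_ratio": self.pca.explained_variance_ratio,
            "pca_score_std": self.pca.score_std,
            "loss_history": self.network.loss_history,
        }
        for k, v in self.network.params.items():
            arrays[f"net_{k}"] = v
        for subtype, off in self.ccfp_offsets.items():
            arrays[f"offset_{subtype}"] = off
        np.savez(directory / "predictor.npz", **arrays)
        meta = {"label_order": list(SUBTYPE_ORDER), "format": "cranioland-predictor-v1"}
        (directory / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "SellaPredictor":
        directory = Path(directory)
        config = RunConfig.from_file(directory / "config.txt")
        with np.load(directory / "predictor.npz") as z:
            pca = PcaModel(
                mean_shape=z["pca_mean"],
                components=z["pca_components"],
                explained_variance=z["pca_explained_variance"],
                explained_variance_ratio=z["pca_explained_variance_ratio"],
                score_std=z["pca_score_std"],
            )
            params = {
                k[len("net_") :]: z[k] for k in z.files if k.startswith("net_")
            }
            offsets = {
                k[len("offset_") :]: z[k] for k in z.files if k.startswith("offset_")
            }
            net = TrainedModel(
                params=params,
                net_config=NetworkConfig(
                    input_dim=config.input_dim,
                    hidden_width=config.hidden_width,
                    n_identity_blocks=config.n_identity_blocks,
                    dropout_in=config.dropout_in,
                    dropout_out=config.dropout_out,
                    output_dim=config.output_dim,
                ),
                train_config=TrainConfig(
                    lr0=config.lr0,
                    decay_factor=config.decay_factor,
                    decay_every=config.decay_every,
                    epochs=config.epochs,
                    folds=config.folds,
                ),
                loss_history=z["loss_history"],
            )
        return cls(config=config, pca=pca, network=net, ccfp_offsets=offsets)


def fit_predictor(standardized, config: RunConfig | None = None, seed: int | None = None) -> SellaPredictor:
    """Train a deployable predictor on a full standardized cohort.

    Unlike cross-validation, everything is fitted on all subjects with
    known sella; use the cross-validated results for accuracy estimates.
    """
    config = config or RunConfig()
    if seed is None:
        seed = config.seed
    subjects = [s for s in standardized if s.sella is not None]
    if not subjects:
        raise ValueError("no subjects with ground-truth sella")
    template = build_ray_template(
        config.template_subdivision,
        config.template_cut_latitude_deg,
        (config.template_tilt_x_deg, config.template_tilt_y_deg),
    )
    pca = shape_mod.fit_pca([s.surface for s in subjects], config.n_components)
    n_scores = min(config.n_features, pca.n_components)

    def feats(subj):
        scores = shape_mod.project(pca, subj.surface, n=n_scores)
        if n_scores < config.n_features:
            scores = np.r_[scores, np.zeros(config.n_features - n_scores)]
        return shape_mod.make_feature_vector(scores, subj.subtype).combined

    X = np.array([feats(s) for s in subjects])
    Y = np.array([s.sella for s in subjects])
    net_cfg = NetworkConfig(
        input_dim=config.input_dim,
        hidden_width=config.hidden_width,
        n_identity_blocks=config.n_identity_blocks,
        dropout_in=config.dropout_in,
        dropout_out=config.dropout_out,
        output_dim=config.output_dim,
        seed=seed,
    )
    train_cfg = TrainConfig(
        lr0=config.lr0,
        decay_factor=config.decay_factor,
        decay_every=config.decay_every,
        epochs=config.epochs,
        folds=config.folds,
        seed=seed,
    )
    network = train(X, Y, net_cfg, train_cfg, seed=seed)
    offsets = ccfp_mod.fit_ccfp_offset(subjects, template).offsets
    return SellaPredictor(config=config, pca=pca, network=network, ccfp_offsets=offsets)
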