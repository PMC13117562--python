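"""Statistical shape model: PCA over standardized surfaces and the
14-element network feature vector.

The 1016 corresponded vertices of each subject are flattened to a
3048-vector and reduced by mean-centred PCA to 32 components.  The first
10 component scores (the components are variance-ordered, so these carry
the highest individual variances) are z-scored by their training-set
standard deviations and concatenated with a 4-element one-hot subtype
indicator to form the network input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .config import SUBTYPE_ORDER
from .standardize import StandardizedSurface

__all__ = ["PcaModel", "ShapeFeatureVector", "fit_pca", "project", "make_feature_vector"]


@dataclass(frozen=True)
class PcaModel:
    """Fitted shape model.

    Components follow a deterministic sign convention (largest-magnitude
    loading positive) and are variance-ordered; ``score_std`` holds the
    training-set standard deviation of each component score, used to
    standardize scores before they enter the network.
    """

    mean_shape: np.ndarray  # (3048,)
    components: np.ndarray  # (k, 3048) orthonormal rows
    explained_variance: np.ndarray  # (k,) non-increasing
    explained_variance_ratio: np.ndarray  # (k,)
    score_std: np.ndarray  # (k,)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def _as_matrix(surfaces) -> np.ndarray:
    rows = []
    for s in surfaces:
        rows.append(s.flattened() if isinstance(s, StandardizedSurface) else np.ravel(s))
    return np.asarray(rows, dtype=float)


def fit_pca(surfaces, n_components: int = 32) -> PcaModel:
    """Mean-centred PCA of flattened standardized surfaces.

    Retains ``n_components`` components (fewer, with a warning, when the
    training set is rank-limited).  Scores' standard deviations are
    computed on the training set itself (ddof=0) for later z-scoring.
    """
    X = _as_matrix(surfaces)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 surfaces")
    k = min(n_components, n - 1, X.shape[1])
    if k < n_components:
        warnings.warn(
            f"only {n} training surfaces; truncating to {k} components",
            stacklevel=2,
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    components = pca.components_.copy()
    # deterministic sign: largest-|loading| entry of each component positive
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(k), idx])
    signs[signs == 0] = 1.0
    components *= signs[:, None]
    scores *= signs[None, :]
    score_std = scores.std(axis=0)
    return PcaModel(
        mean_shape=pca.mean_,
        components=components,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        score_std=score_std,
    )


def project(
    model: PcaModel,
    surf: StandardizedSurface | np.ndarray,
    n: int = 10,
    standardize: bool = True,
) -> np.ndarray:
    """First ``n`` (standardized) component scores of a surface.

    Components are variance-ordered, so the first ``n`` are the ones with
    the highest individual variances.  With ``standardize`` the scores are
    divided by the training-set standard deviations (zero stds left
    unscaled).
    """
    if n > model.n_components:
        raise ValueError(f"requested {n} scores but model has {model.n_components}")
    x = surf.flattened() if isinstance(surf, StandardizedSurface) else np.ravel(surf)
    scores = model.components[:n] @ (x - model.mean_shape)
    if standardize:
        std = model.score_std[:n]
        scores = scores / np.where(std > 0, std, 1.0)
    return scores


def reconstruct(model: PcaModel, scores: np.ndarray) -> np.ndarray:
    """Inverse of :func:`project` with unstandardized scores (flattened mm)."""
    scores = np.ravel(scores)
    return model.mean_shape + scores @ model.components[: len(scores)]


@dataclass(frozen=True)
class ShapeFeatureVector:
    """10 standardized PC scores + 4 class indicators = 14 network inputs."""

    pc_scores: np.ndarray  # (10,)
    class_onehot: np.ndarray  # (4,)

    def __post_init__(self):
        onehot = np.asarray(self.class_onehot, dtype=float)
        if onehot.sum() != 1.0 or not np.all(np.isin(onehot, (0.0, 1.0))):
            raise ValueError("class indicator must be one-hot")
        object.__setattr__(self, "pc_scores", np.asarray(self.pc_scores, dtype=float))
        object.__setattr__(self, "class_onehot", onehot)

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.pc_scores, self.class_onehot])


def make_feature_vector(scores: np.ndarray, subtype: str) -> ShapeFeatureVector:
    """Concatenate PC scores with the fixed-order one-hot subtype indicator.

    Label order is (control, plagiocephaly, trigonocephaly, scaphocephaly).
    """
    if subtype not in SUBTYPE_ORDER:
        raise ValueError(f"unknown subtype {subtype!r}")
    onehot = np.zeros(len(SUBTYPE_ORDER))
    onehot[SUBTYPE_ORDER.index(subtype)] = 1.0
    return ShapeFeatureVector(pc_scores=np.ravel(scores), class_onehot=onehot)
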