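"""Feedforward landmark-regression network and cross-validation driver.

A small residual dense network maps the 14-element shape feature vector
(10 standardized PC scores + 4 subtype indicators) to the 3D sella
coordinate in the horizontally aligned frame:

    dense(14→8) → ReLU → dropout(0.5)
    → 3 × residual block [x + ReLU(dense(8→8)(x))]
    → dropout(0.1) → dense(8→3)

Training uses Adam at batch size 1 with mean-squared-error loss and a
step learning-rate schedule (halved every 100 epochs from 1e-3) for 400
epochs.  The network has under 500 parameters, so it is implemented
directly in numpy with hand-derived backpropagation; all randomness
(initialization, shuffling, dropout, fold assignment) flows from a single
seed, making runs bit-for-bit reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ccfp as ccfp_mod
from . import shape as shape_mod
from .config import RunConfig, SUBTYPE_ORDER

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "TrainedModel",
    "DivergenceError",
    "lr_at_epoch",
    "init_params",
    "forward",
    "train",
    "stratified_folds",
    "cross_validate",
    "CrossValidationOutput",
]


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class NetworkConfig:
    input_dim: int = 14
    hidden_width: int = 8
    n_identity_blocks: int = 3
    dropout_in: float = 0.5
    dropout_out: float = 0.1
    output_dim: int = 3
    seed: int = 0

    def __post_init__(self):
        if min(self.input_dim, self.hidden_width, self.output_dim) <= 0:
            raise ValueError("dimensions must be positive")
        for p in (self.dropout_in, self.dropout_out):
            if not (0.0 <= p < 1.0):
                raise ValueError("dropout rates must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 1e-3
    decay_factor: float = 0.5
    decay_every: int = 100
    batch_size: int = 1
    epochs: int = 400
    folds: int = 5
    seed: int = 0
    # optional regularizers, OFF by default (the fixed-epoch schedule governs)
    early_stopping_patience: int | None = None
    augment_sd: float = 0.0

    def __post_init__(self):
        if self.lr0 <= 0 or self.epochs < 1 or self.folds < 2:
            raise ValueError("invalid training configuration")


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Step schedule: ``lr0 · decay_factor^floor(epoch / decay_every)``."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.lr0 * cfg.decay_factor ** (epoch // cfg.decay_every)


def init_params(cfg: NetworkConfig, rng: np.random.Generator) -> dict:
    """Seeded uniform fan-in initialization (U(−1/√fan_in, 1/√fan_in))."""

    def dense(n_out, n_in):
        bound = 1.0 / np.sqrt(n_in)
        return (
            rng.uniform(-bound, bound, size=(n_out, n_in)),
            rng.uniform(-bound, bound, size=n_out),
        )

    params = {}
    params["W0"], params["b0"] = dense(cfg.hidden_width, cfg.input_dim)
    for k in range(1, cfg.n_identity_blocks + 1):
        params[f"W{k}"], params[f"b{k}"] = dense(cfg.hidden_width, cfg.hidden_width)
    params["Wh"], params["bh"] = dense(cfg.output_dim, cfg.hidden_width)
    return params


@dataclass
class TrainedModel:
    """Trained parameters + config + per-epoch mean training loss."""

    params: dict
    net_config: NetworkConfig
    train_config: TrainConfig
    loss_history: np.ndarray

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Deterministic inference (dropout off) on (14,) or (n, 14) input."""
        return forward(self.params, self.net_config, features)


def forward(
    params: dict,
    cfg: NetworkConfig,
    x: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Evaluate the network; dropout is active only with ``training``.

    Accepts a single feature vector or a stack of them.  Inference mode is
    deterministic (inverted dropout: masks scale activations at training
    time, so evaluation uses the raw weights).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != cfg.input_dim:
        raise ValueError(f"expected input dim {cfg.input_dim}, got {X.shape[1]}")
    h = np.maximum(X @ params["W0"].T + params["b0"], 0.0)
    if training and cfg.dropout_in > 0:
        mask = (rng.random(h.shape) >= cfg.dropout_in) / (1.0 - cfg.dropout_in)
        h = h * mask
    for k in range(1, cfg.n_identity_blocks + 1):
        h = h + np.maximum(h @ params[f"W{k}"].T + params[f"b{k}"], 0.0)
    if training and cfg.dropout_out > 0:
        mask = (rng.random(h.shape) >= cfg.dropout_out) / (1.0 - cfg.dropout_out)
        h = h * mask
    y = h @ params["Wh"].T + params["bh"]
    return y[0] if single else y


def _step(params, cfg, x, target, rng):
    """Forward + backward for one sample; returns (loss, grads)."""
    z0 = params["W0"] @ x + params["b0"]
    h0 = np.maximum(z0, 0.0)
    if cfg.dropout_in > 0:
        m0 = (rng.random(h0.shape) >= cfg.dropout_in) / (1.0 - cfg.dropout_in)
    else:
        m0 = 1.0
    a = h0 * m0
    acts, pres = [a], []
    for k in range(1, cfg.n_identity_blocks + 1):
        z = params[f"W{k}"] @ a + params[f"b{k}"]
        pres.append(z)
        a = a + np.maximum(z, 0.0)
        acts.append(a)
    if cfg.dropout_out > 0:
        m4 = (rng.random(a.shape) >= cfg.dropout_out) / (1.0 - cfg.dropout_out)
    else:
        m4 = 1.0
    h_out = a * m4
    y = params["Wh"] @ h_out + params["bh"]
    err = y - target
    loss = float(np.mean(err**2))

    grads = {}
    dy = (2.0 / err.size) * err
    grads["Wh"] = np.outer(dy, h_out)
    grads["bh"] = dy
    da = (params["Wh"].T @ dy) * m4
    for k in range(cfg.n_identity_blocks, 0, -1):
        dz = da * (pres[k - 1] > 0.0)
        grads[f"W{k}"] = np.outer(dz, acts[k - 1])
        grads[f"b{k}"] = dz
        da = da + params[f"W{k}"].T @ dz
    dh0 = da * m0
    dz0 = dh0 * (z0 > 0.0)
    grads["W0"] = np.outer(dz0, x)
    grads["b0"] = dz0
    return loss, grads


def train(
    features: np.ndarray,
    targets: np.ndarray,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
    seed: int | None = None,
    initial_params: dict | None = None,
) -> TrainedModel:
    """Train the network with Adam at batch size 1.

    ``features`` is (n, 14), ``targets`` is (n, 3) in mm (aligned frame).
    The sample order is reshuffled every epoch from the seeded generator;
    the learning rate follows :func:`lr_at_epoch`.  Raises
    :class:`DivergenceError` if the loss becomes non-finite.
    ``initial_params`` overrides the seeded initialization (for warm
    starts and controlled experiments).
    """
    net_cfg = net_cfg or NetworkConfig()
    train_cfg = train_cfg or TrainConfig()
    if seed is None:
        seed = net_cfg.seed
    X = np.asarray(features, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if len(X) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    if initial_params is not None:
        params = {k: np.array(v, dtype=float) for k, v in initial_params.items()}
    else:
        params = init_params(net_cfg, rng)

    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(val) for k, val in params.items()}
    t_step = 0
    history = np.empty(train_cfg.epochs)
    best = np.inf
    stale = 0
    names = list(params)
    for epoch in range(train_cfg.epochs):
        lr = lr_at_epoch(train_cfg, epoch)
        order = rng.permutation(len(X))
        total = 0.0
        for i in order:
            x = X[i]
            if train_cfg.augment_sd > 0:
                x = x + rng.normal(0.0, train_cfg.augment_sd, size=x.shape)
            loss, grads = _step(params, net_cfg, x, Y[i], rng)
            total += loss
            t_step += 1
            bc1 = 1.0 - beta1**t_step
            bc2 = 1.0 - beta2**t_step
            for name in names:
                g = grads[name]
                m[name] = beta1 * m[name] + (1 - beta1) * g
                v[name] = beta2 * v[name] + (1 - beta2) * g * g
                params[name] = params[name] - lr * (m[name] / bc1) / (
                    np.sqrt(v[name] / bc2) + eps
                )
        mean_loss = total / len(X)
        if not np.isfinite(mean_loss):
            raise DivergenceError(epoch)
        history[epoch] = mean_loss
        if train_cfg.early_stopping_patience is not None:
            if mean_loss < best - 1e-12:
                best, stale = mean_loss, 0
            else:
                stale += 1
                if stale >= train_cfg.early_stopping_patience:
                    history = history[: epoch + 1]
                    break
    return TrainedModel(
        params=params, net_config=net_cfg, train_config=train_cfg, loss_history=history
    )


def stratified_folds(subtypes, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Subtype-stratified fold assignment with overall sizes differing ≤1.

    Within each subtype the (shuffled) members are dealt round-robin; the
    dealing position carries over between subtypes so the global fold
    sizes stay balanced.  Subtypes with fewer members than folds are
    handled by the same dealing, which is then effectively unstratified
    for that subtype (warned).
    """
    subtypes = np.asarray(subtypes)
    n = len(subtypes)
    if n < n_folds:
        raise ValueError("fewer subjects than folds")
    assignment = np.empty(n, dtype=int)
    pos = int(rng.integers(n_folds))
    for subtype in SUBTYPE_ORDER:
        idx = np.flatnonzero(subtypes == subtype)
        if len(idx) == 0:
            continue
        if 0 < len(idx) < n_folds:
            warnings.warn(
                f"subtype {subtype!r} has {len(idx)} subjects (< {n_folds} folds); "
                "stratification is incomplete for this subtype",
                stacklevel=2,
            )
        idx = rng.permutation(idx)
        for i in idx:
            assignment[i] = pos % n_folds
            pos += 1
    return assignment


@dataclass
class CrossValidationOutput:
    """Per-subject out-of-fold predictions plus per-fold artifacts."""

    predictions: pd.DataFrame
    fold_models: list  # TrainedModel per fold
    fold_pcas: list  # PcaModel per fold
    fold_offsets: list  # CcfpOffsetModel per fold


def cross_validate(
    subjects,
    config: RunConfig | None = None,
    seed: int | None = None,
    template=None,
) -> CrossValidationOutput:
    """K-fold cross-validation of both sella estimators.

    Per fold, everything with trainable state — the PCA (components and
    score standard deviations), the network, and the CCFP subtype offsets
    — is fitted on the training split only; the held-out subjects are
    predicted once each.  Returns a tidy table with one row per subject:
    fold, subtype, true sella and both methods' predictions (aligned
    frame, mm).
    """
    config = config or RunConfig()
    if seed is None:
        seed = config.seed
    subjects = list(subjects)
    for s in subjects:
        if s.sella is None:
            raise ValueError(f"subject {s.id} lacks ground-truth sella")
    rng = np.random.default_rng(seed)
    folds = stratified_folds([s.subtype for s in subjects], config.folds, rng)

    focal_points = {
        s.id: ccfp_mod.compute_ccfp(s.surface, template).focal_point for s in subjects
    }

    rows = []
    fold_models, fold_pcas, fold_offsets = [], [], []
    for fold in range(config.folds):
        train_subj = [s for s, f in zip(subjects, folds) if f != fold]
        test_subj = [s for s, f in zip(subjects, folds) if f == fold]
        pca = shape_mod.fit_pca([s.surface for s in train_subj], config.n_components)

        n_scores = min(config.n_features, pca.n_components)

        def feats(subj):
            scores = shape_mod.project(pca, subj.surface, n=n_scores)
            if n_scores < config.n_features:  # rank-limited: pad zero-variance scores
                scores = np.r_[scores, np.zeros(config.n_features - n_scores)]
            return shape_mod.make_feature_vector(scores, subj.subtype).combined

        X_train = np.array([feats(s) for s in train_subj])
        Y_train = np.array([s.sella for s in train_subj])
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
            batch_size=config.batch_size,
            epochs=config.epochs,
            folds=config.folds,
            seed=seed,
        )
        model = train(X_train, Y_train, net_cfg, train_cfg, seed=seed + fold + 1)
        offsets = ccfp_mod.fit_ccfp_offset(train_subj, template)

        for subj in test_subj:
            pred_ffnn = model.predict(feats(subj))
            pred_ccfp = focal_points[subj.id] + offsets.offset_for(subj.subtype)
            rows.append(
                {
                    "id": subj.id,
                    "subtype": subj.subtype,
                    "fold": fold,
                    **dict(zip(("true_x", "true_y", "true_z"), subj.sella)),
                    **dict(zip(("ffnn_x", "ffnn_y", "ffnn_z"), pred_ffnn)),
                    **dict(zip(("ccfp_x", "ccfp_y", "ccfp_z"), pred_ccfp)),
                }
            )
        fold_models.append(model)
        fold_pcas.append(pca)
        fold_offsets.append(offsets)
    predictions = pd.DataFrame(rows).sort_values("id", kind="stable").reset_index(drop=True)
    return CrossValidationOutput(
        predictions=predictions,
        fold_models=fold_models,
        fold_pcas=fold_pcas,
        fold_offsets=fold_offsets,
    )
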