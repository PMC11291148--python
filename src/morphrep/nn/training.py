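"""Autoencoder training: Adam, seeded stratified splits, jitter
augmentation, loss history and checkpoints.

Two dataset flavours are supported. Folding models train on a list of
:class:`LabeledPointCloud` (reconstruction with EMD or chamfer loss);
implicit SDF models train on items exposing ``surface_points`` and
``query_points`` (surface cloud in, L1 loss on SDF values at the query
points).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ..io import split_indices
from ..types import InvalidInputError, LabeledPointCloud
from .autodiff import Parameter, Tensor
from .losses import chamfer_loss, emd_loss, l1_loss
from .models import ModelConfig, PointCloudAutoencoder, build_model

__all__ = ["TrainConfig", "Adam", "train_autoencoder", "TrainingDiverged"]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite; carries diagnostics."""

    def __init__(self, epoch: int, batch: int, loss: float):
        super().__init__(
            f"non-finite loss {loss!r} at epoch {epoch}, batch {batch}; "
            "reduce the learning rate or inspect the inputs"
        )
        self.epoch = epoch
        self.batch = batch


@dataclass
class TrainConfig:
    epochs: int = 50
    lr: float = 1e-3
    batch_size: int = 8
    loss: str = "emd"  # folding: emd | chamfer; implicit_sdf always L1
    fractions: tuple = (0.70, 0.15, 0.15)
    jitter_sd: float = 0.0  # 0 disables augmentation; units of scaled coords
    jitter_clip: float = 0.2
    seed: int = 0
    checkpoint_dir: Optional[str] = None
    queries_per_step: int = 512  # implicit models: SDF queries per sample


class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _labels_of(dataset) -> np.ndarray:
    labels = []
    for item in dataset:
        meta = item.meta if isinstance(item, LabeledPointCloud) else getattr(item, "meta", {})
        labels.append(meta.get("rule", meta.get("label", "_")))
    return np.asarray(labels, dtype=object)


def _jitter(points: np.ndarray, sd: float, clip: float, rng) -> np.ndarray:
    if sd <= 0:
        return points
    noise = np.clip(rng.normal(0.0, sd, size=points.shape), -clip, clip)
    return points + noise


def train_autoencoder(dataset, cfg: ModelConfig, train_cfg: Optional[TrainConfig] = None):
    """Train an autoencoder; returns ``(model, history)``.

    ``history`` is a dict with per-epoch train/val losses and the split
    assignment. Deterministic given ``train_cfg.seed`` (splits, batch
    order, jitter and model init all derive from it).
    """
    train_cfg = train_cfg or TrainConfig()
    if len(dataset) < 10:
        raise InvalidInputError("training requires at least 10 samples")
    labels = _labels_of(dataset)
    # drop stratification when any class is too small to split
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 3:
        labels = np.zeros(len(dataset), dtype=int)
    split = split_indices(labels, fractions=train_cfg.fractions, seed=train_cfg.seed)
    train_idx = np.flatnonzero(split == "train")
    val_idx = np.flatnonzero(split == "val")

    if cfg.input_scale == 1.0:
        cfg = replace(cfg, input_scale=_dataset_scale(dataset, train_idx, cfg))

    model = build_model(cfg)
    opt = Adam(model.parameters(), lr=train_cfg.lr)
    rng = np.random.default_rng(train_cfg.seed + 1)
    history = {"epochs": [], "split": split.tolist()}

    implicit = cfg.decoder == "implicit_sdf"
    for epoch in range(train_cfg.epochs):
        order = train_idx[rng.permutation(len(train_idx))]
        losses = []
        for bstart in range(0, len(order), train_cfg.batch_size):
            batch_ids = order[bstart : bstart + train_cfg.batch_size]
            loss = _batch_loss(model, dataset, batch_ids, cfg, train_cfg, rng, train=True)
            val = float(loss.data)
            if not np.isfinite(val):
                raise TrainingDiverged(epoch, bstart // train_cfg.batch_size, val)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(val)
        val_loss = None
        if len(val_idx):
            vl = [
                float(
                    _batch_loss(
                        model, dataset, val_idx[s : s + train_cfg.batch_size],
                        cfg, train_cfg, rng, train=False,
                    ).data
                )
                for s in range(0, len(val_idx), train_cfg.batch_size)
            ]
            val_loss = float(np.mean(vl))
        history["epochs"].append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss}
        )
        if train_cfg.checkpoint_dir:
            _save_checkpoint(model, cfg, train_cfg, history)
    _ = implicit
    return model, history


def _dataset_scale(dataset, train_idx, cfg: ModelConfig) -> float:
    """Common coordinate divisor so scaled clouds have mean radius 0.5,
    matching the unit-scale folding templates. Computed on the training
    split only and frozen into the model config."""
    pts_src = (
        (lambda i: dataset[i].surface_points.points)
        if cfg.decoder == "implicit_sdf" and hasattr(dataset[0], "surface_points")
        else (lambda i: dataset[i].points)
    )
    radii = [
        float(np.linalg.norm(np.asarray(pts_src(i), dtype=float), axis=1).mean())
        for i in train_idx
    ]
    r = float(np.mean(radii))
    return 2.0 * r if r > 0 else 1.0


def _batch_loss(model: PointCloudAutoencoder, dataset, ids, cfg: ModelConfig,
                train_cfg: TrainConfig, rng, train: bool) -> Tensor:
    if cfg.decoder == "folding":
        pts = np.stack([np.asarray(dataset[i].points, dtype=float) for i in ids])
        pts = pts / cfg.input_scale
        target = pts
        if train and train_cfg.jitter_sd > 0:
            pts = _jitter(pts, train_cfg.jitter_sd, train_cfg.jitter_clip, rng)
        scal = (
            np.stack([dataset[i].scalars for i in ids])
            if cfg.has_scalar_channel
            else None
        )
        V = model.encoder.forward_batch(pts, scal)
        if cfg.encoder == "vn_dgcnn":
            z = V.norm(axis=-1)
            R = np.stack(
                [_rotation_np(V.data[b]) for b in range(V.shape[0])]
            )
        else:
            z = V
            R = None
        recon = model.decoder.forward_batch(z, R)
        if train_cfg.loss == "emd":
            return emd_loss(recon, target)
        return chamfer_loss(recon, target)

    # implicit SDF: items expose surface_points / query_points
    s = cfg.input_scale
    surf = np.stack(
        [np.asarray(dataset[i].surface_points.points, dtype=float) for i in ids]
    ) / s
    nq = train_cfg.queries_per_step
    qpts, qval = [], []
    for i in ids:
        qp = dataset[i].query_points
        sel = rng.choice(len(qp.points), size=min(nq, len(qp.points)), replace=False)
        qpts.append(qp.points[sel] / s)
        qval.append(qp.scalars[sel] / s)
    V = model.encoder.forward_batch(surf)
    pred = model.decoder.forward_batch(V, np.stack(qpts))
    return l1_loss(pred, np.stack(qval))


def _rotation_np(V: np.ndarray) -> np.ndarray:
    from ..types import VectorEmbedding

    return VectorEmbedding(V).rotation()


def _save_checkpoint(model, cfg: ModelConfig, train_cfg: TrainConfig, history) -> None:
    out = Path(train_cfg.checkpoint_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        out / "weights.npz", **{f"p{i}": p.data for i, p in enumerate(model.parameters())}
    )
    (out / "config.json").write_text(
        json.dumps({"model": cfg.__dict__, "train": _train_cfg_dict(train_cfg)}, indent=2)
    )
    (out / "history.json").write_text(json.dumps(history, indent=2))


def _train_cfg_dict(tc: TrainConfig) -> dict:
    d = dict(tc.__dict__)
    d["fractions"] = list(d["fractions"])
    return d


def load_checkpoint(cfg: ModelConfig, path) -> PointCloudAutoencoder:
    """Rebuild a model from a checkpoint directory written during training."""
    model = build_model(cfg)
    with np.load(Path(path) / "weights.npz") as z:
        arrays = [z[f"p{i}"] for i in range(len(z.files))]
    model.load_state_arrays(arrays)
    return model


def load_checkpoint_dir(path) -> PointCloudAutoencoder:
    """Rebuild a model from a checkpoint directory using its own
    recorded model configuration."""
    saved = json.loads((Path(path) / "config.json").read_text())
    cfg = ModelConfig(**saved["model"])
    return load_checkpoint(cfg, path)
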