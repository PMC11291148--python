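"""Point-cloud autoencoders: rotation-equivariant vector-neuron DGCNN
encoder, a classical DGCNN control, the folding decoder for punctate
structures and the inner-product implicit SDF decoder for polymorphic
structures.

Conventions. Input rotation acts on point rows as ``x -> x @ Q.T``.
The equivariant encoder output ``V`` (latent_dim x 3) then transforms
as ``V -> V @ Q.T``, so the row norms ``z`` are exactly invariant and a
rotation matrix recovered from designated rows is left-multiplied by
``Q``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..types import InvalidInputError, LabeledPointCloud, VectorEmbedding
from .autodiff import Parameter, Tensor, concatenate
from .layers import (
    Linear,
    Module,
    VNLeakyReLU,
    VNLinear,
    edge_features_scalar,
    edge_features_vn,
    knn_indices,
)

__all__ = [
    "ModelConfig",
    "VNDGCNNEncoder",
    "DGCNNEncoder",
    "FoldingDecoder",
    "ImplicitSDFDecoder",
    "PointCloudAutoencoder",
    "build_model",
    "knn_graph",
    "vn_encode",
    "invariant_representation",
    "rotation_from_vectors",
    "folding_decode",
    "implicit_decode",
    "plane_template",
    "sphere_template",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the full-scale setup: k=20 neighbor graphs, 6
    edge-convolution blocks, latent 256 for punctate / 512 for
    polymorphic structures (use the constructors). ``hidden_dim`` is the
    vector-channel width per block; desk-scale experiments shrink it
    together with ``latent_dim``.
    """

    encoder: str = "vn_dgcnn"  # or "dgcnn"
    decoder: str = "folding"  # or "implicit_sdf"
    latent_dim: int = 256
    k_neighbors: int = 20
    n_blocks: int = 6
    hidden_dim: int = 64
    template: str = "plane"  # or "sphere"
    template_points: int = 2048
    has_scalar_channel: bool = False
    decoder_hidden: int = 128
    seed: int = 0
    # Global divisor applied to input coordinates (and, for SDF models,
    # to query points and predicted distances). The trainer sets it from
    # the training split so clouds and the unit-scale folding templates
    # live on a common scale. One constant for the whole dataset, so
    # relative size differences between samples remain informative.
    input_scale: float = 1.0

    def __post_init__(self):
        if self.encoder not in ("vn_dgcnn", "dgcnn"):
            raise InvalidInputError(f"unknown encoder {self.encoder!r}")
        if self.decoder not in ("folding", "implicit_sdf"):
            raise InvalidInputError(f"unknown decoder {self.decoder!r}")
        if self.template not in ("plane", "sphere"):
            raise InvalidInputError(f"unknown template {self.template!r}")
        if self.latent_dim <= 0:
            raise InvalidInputError("latent_dim must be positive")
        if self.input_scale <= 0:
            raise InvalidInputError("input_scale must be positive")

    @classmethod
    def punctate(cls, **kw) -> "ModelConfig":
        kw.setdefault("latent_dim", 256)
        kw.setdefault("decoder", "folding")
        return cls(**kw)

    @classmethod
    def polymorphic(cls, **kw) -> "ModelConfig":
        kw.setdefault("latent_dim", 512)
        kw.setdefault("decoder", "implicit_sdf")
        kw.setdefault("has_scalar_channel", False)
        return cls(**kw)


def knn_graph(points: np.ndarray, k: int) -> np.ndarray:
    """k-nearest-neighbor index table for an (N, 3) point array.

    Neighbors ordered by increasing distance, ties broken by ascending
    index, self excluded. N must exceed k.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise InvalidInputError("knn_graph expects an (N, D) array")
    try:
        return knn_indices(points, int(k))
    except ValueError as e:
        raise InvalidInputError(str(e)) from None


class VNDGCNNEncoder(Module):
    """Rotation-equivariant DGCNN built from vector-neuron edge blocks.

    Each block gathers k-NN edge features (neighbor difference, cross
    product with the input points, and the points themselves), mixes
    channels with a VN linear layer, applies a VN leaky ReLU, and mean-
    pools over the neighborhood. The graph is recomputed per block from
    the rotation-invariant channel norms, so graph construction never
    breaks equivariance. Intermediate outputs are collated before a
    final channel-mixing layer; mean pooling over points yields the
    (latent_dim x 3) vector embedding.

    An optional scalar channel (intensity or SDF) runs through a
    parallel invariant edge-convolution stream whose features gate the
    vector channels multiplicatively — an invariant gain, so exact
    equivariance is preserved.
    """

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        c = cfg.hidden_dim
        self.blocks_lin: list[VNLinear] = []
        self.blocks_act: list[VNLeakyReLU] = []
        self.scalar_lin: list[Linear] = []
        self.gate_lin: list[Linear] = []
        c_in = 1
        s_in = 1
        for _ in range(cfg.n_blocks):
            # edge features: [f_i, f_j - f_i, cross(f_j, x_i), x_i]
            self.blocks_lin.append(VNLinear(3 * c_in + 1, c, rng))
            self.blocks_act.append(VNLeakyReLU(c, rng))
            if cfg.has_scalar_channel:
                # scalar edge features [s_i, s_j - s_i] plus the norms of
                # the block's pooled vector channels (width c)
                self.scalar_lin.append(Linear(2 * s_in + c, c, rng))
                self.gate_lin.append(Linear(c, c, rng))
                s_in = c
            c_in = c
        self.final = VNLinear(cfg.n_blocks * c, cfg.latent_dim, rng)

    def forward_batch(self, points: np.ndarray, scalars: Optional[np.ndarray] = None) -> Tensor:
        """Encode a (B, N, 3) batch; returns V as a (B, latent, 3) tensor."""
        points = np.asarray(points, dtype=float)
        if not np.all(np.isfinite(points)):
            raise InvalidInputError("non-finite values in input point cloud")
        if points.ndim == 2:
            points = points[None]
        B, N, _ = points.shape
        cfg = self.cfg
        if N < cfg.k_neighbors + 1:
            raise InvalidInputError(
                f"need at least k+1={cfg.k_neighbors + 1} points, got {N}"
            )
        x = Tensor(points[:, :, :, None])  # (B, N, 3, 1)
        f = x
        s = None
        if cfg.has_scalar_channel:
            if scalars is None:
                raise InvalidInputError("config expects a scalar channel")
            if not np.all(np.isfinite(scalars)):
                raise InvalidInputError("non-finite values in scalar channel")
            s = Tensor(np.asarray(scalars, dtype=float).reshape(B, N, 1))
        collected = []
        for i in range(cfg.n_blocks):
            if i == 0:
                idx = knn_indices(points, cfg.k_neighbors)
            else:
                # invariant descriptor: channel norms of current features
                desc = np.linalg.norm(f.data, axis=-2)
                idx = knn_indices(desc, cfg.k_neighbors)
            ef = edge_features_vn(f, x, idx)  # neighborhood-pooled
            f = self.blocks_act[i](self.blocks_lin[i](ef))  # (B, N, 3, C)
            if cfg.has_scalar_channel:
                norms = f.norm(axis=-2)  # (B, N, C) invariant
                es = edge_features_scalar(s, idx)  # (B, N, 2 s_in)
                s = self.scalar_lin[i](concatenate([es, norms], axis=-1)).leaky_relu(0.2)
                gate = 1.0 + self.gate_lin[i](s).tanh()  # (B, N, C)
                f = f * gate.reshape(B, N, 1, -1)
            collected.append(f)
        h = concatenate(collected, axis=-1)
        v = self.final(h)  # (B, N, 3, latent)
        # Pooling: averaging raw vectors over points cancels incoherent
        # per-point directions, so the row norms would shrink toward the
        # few globally coherent modes and lose density information.
        # Instead, keep the mean direction but rescale each latent row to
        # the mean of the per-point channel norms — an invariant gain, so
        # equivariance is exact and z carries non-cancelling statistics.
        mean_v = v.mean(axis=1)  # (B, 3, latent)
        mean_norm = v.norm(axis=-2).mean(axis=1)  # (B, latent) invariant
        gain = mean_norm / (mean_v.norm(axis=-2) + 1e-8)
        v = mean_v * gain.reshape(B, 1, -1)
        return v.swapaxes(-1, -2)  # (B, latent, 3)


class DGCNNEncoder(Module):
    """Classical (non-equivariant) DGCNN control.

    Standard edge convolutions on raw coordinates; its embedding is the
    channel vector after pooling, and is *not* rotation invariant — used
    as the control in the invariance benchmark.
    """

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        c = cfg.hidden_dim
        self.lins: list[Linear] = []
        c_in = 3 + (1 if cfg.has_scalar_channel else 0)
        for _ in range(cfg.n_blocks):
            self.lins.append(Linear(2 * c_in, c, rng))
            c_in = c
        self.final = Linear(cfg.n_blocks * c, cfg.latent_dim, rng)

    def forward_batch(self, points: np.ndarray, scalars: Optional[np.ndarray] = None) -> Tensor:
        points = np.asarray(points, dtype=float)
        if points.ndim == 2:
            points = points[None]
        if not np.all(np.isfinite(points)):
            raise InvalidInputError("non-finite values in input point cloud")
        B, N, _ = points.shape
        cfg = self.cfg
        feats = points
        if cfg.has_scalar_channel:
            feats = np.concatenate(
                [points, np.asarray(scalars, dtype=float).reshape(B, N, 1)], axis=-1
            )
        f = Tensor(feats)
        collected = []
        for i in range(cfg.n_blocks):
            desc = points if i == 0 else f.data
            idx = knn_indices(desc, cfg.k_neighbors)
            ef = edge_features_scalar(f, idx)  # pooled [f_i, mean f_j - f_i]
            f = self.lins[i](ef).leaky_relu(0.2)
            collected.append(f)
        h = concatenate(collected, axis=-1)
        return self.final(h).mean(axis=1)  # (B, latent)


def plane_template(n: int) -> np.ndarray:
    """Uniform grid on [-0.5, 0.5]^2 lifted to z=0, trimmed to n points.

    Grid resolution: rows = floor(sqrt(n)), cols = ceil(n / rows); the
    default n=2048 gives a 45x46 grid trimmed to 2048.
    """
    rows = int(np.floor(np.sqrt(n)))
    cols = int(np.ceil(n / rows))
    u = np.linspace(-0.5, 0.5, rows)
    v = np.linspace(-0.5, 0.5, cols)
    g = np.stack(np.meshgrid(u, v, indexing="ij"), axis=-1).reshape(-1, 2)[:n]
    return np.concatenate([g, np.zeros((n, 1))], axis=1)


def sphere_template(n: int, radius: float = 0.5) -> np.ndarray:
    """Fibonacci lattice on a sphere of the given radius."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + np.sqrt(5.0))
    theta = golden * i
    return radius * np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


class FoldingDecoder(Module):
    """Residual folding decoder.

    Concatenates the invariant latent code with template points and
    applies two folding MLPs with ReLU activations; each fold is a
    residual added to the previous point estimate, so zero fold weights
    return the template unchanged. The canonical reconstruction is
    re-oriented by the rotation matrix recovered from the vector
    embedding.
    """

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed + 1)
        d, h = cfg.latent_dim, cfg.decoder_hidden
        self.cfg = cfg
        self.f1a = Linear(d + 3, h, rng)
        self.f1b = Linear(h, 3, rng)
        self.f2a = Linear(d + 3, h, rng)
        self.f2b = Linear(h, 3, rng)
        tmpl = (
            plane_template(cfg.template_points)
            if cfg.template == "plane"
            else sphere_template(cfg.template_points)
        )
        self.template = tmpl  # constant, not a parameter

    def forward_batch(self, z: Tensor, R: Optional[np.ndarray] = None) -> Tensor:
        """z: (B, d) tensor; R: (B, 3, 3) rotations (optional). Returns
        (B, M, 3) reconstructed points."""
        B = z.shape[0]
        M = self.template.shape[0]
        t = Tensor(np.broadcast_to(self.template, (B, M, 3)).copy())
        zr = z.reshape(B, 1, -1) + Tensor(np.zeros((B, M, 1)))  # repeat along M
        p = t + self.f1b(self.f1a(concatenate([zr, t], axis=-1)).relu())
        p = p + self.f2b(self.f2a(concatenate([zr, p], axis=-1)).relu())
        if R is not None:
            p = p @ Tensor(np.swapaxes(np.asarray(R, dtype=float), -1, -2))
        return p


class ImplicitSDFDecoder(Module):
    """Inner-product implicit decoder for signed distance values.

    Query features are the inner products of the equivariant latent
    vectors with the query point, plus the query norm and the invariant
    code z; all are invariant under joint rotation of shape and query,
    so predictions are too. A small ReLU MLP maps them to one SDF value.
    """

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed + 2)
        d, h = cfg.latent_dim, cfg.decoder_hidden
        self.l1 = Linear(2 * d + 1, h, rng)
        self.l2 = Linear(h, h, rng)
        self.l3 = Linear(h, 1, rng)

    def forward_batch(self, V: Tensor, query: np.ndarray) -> Tensor:
        """V: (B, d, 3) tensor; query: (B, M, 3). Returns (B, M) SDF."""
        q = np.asarray(query, dtype=float)
        if q.ndim == 2:
            q = q[None]
        if not np.all(np.isfinite(q)):
            raise InvalidInputError("non-finite query points")
        qt = Tensor(q)
        inner = qt @ V.swapaxes(-1, -2)  # (B, M, d)
        z = V.norm(axis=-1)  # (B, d)
        B, M = inner.shape[0], inner.shape[1]
        zr = z.reshape(B, 1, -1) + Tensor(np.zeros((B, M, 1)))
        qn = qt.norm(axis=-1, keepdims=True)  # (B, M, 1)
        h = concatenate([inner, zr, qn], axis=-1)
        out = self.l3(self.l2(self.l1(h).relu()).relu())
        return out.reshape(B, M)


class PointCloudAutoencoder(Module):
    """Encoder + decoder pair assembled from a :class:`ModelConfig`."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.encoder = (
            VNDGCNNEncoder(cfg) if cfg.encoder == "vn_dgcnn" else DGCNNEncoder(cfg)
        )
        self.decoder = (
            FoldingDecoder(cfg) if cfg.decoder == "folding" else ImplicitSDFDecoder(cfg)
        )

    # --- numpy-facing inference helpers -----------------------------
    def encode(self, pc: LabeledPointCloud) -> VectorEmbedding:
        scal = pc.scalars if self.cfg.has_scalar_channel else None
        pts = pc.points / self.cfg.input_scale
        out = self.encoder.forward_batch(pts[None], None if scal is None else scal[None])
        if self.cfg.encoder == "vn_dgcnn":
            return VectorEmbedding(out.data[0])
        # classical control has no vector structure; place the plain
        # embedding on the x-axis so row norms recover |z| entries
        return VectorEmbedding(_scalar_to_rows(out.data[0]))

    def embed(self, pc: LabeledPointCloud) -> np.ndarray:
        """Rotation-invariant representation of a single cloud."""
        scal = pc.scalars if self.cfg.has_scalar_channel else None
        pts = pc.points / self.cfg.input_scale
        out = self.encoder.forward_batch(pts[None], None if scal is None else scal[None])
        if self.cfg.encoder == "vn_dgcnn":
            return np.linalg.norm(out.data[0], axis=-1)
        return out.data[0].copy()

    def embed_many(self, clouds, batch_size: int = 16) -> np.ndarray:
        """Stack invariant representations for a list of equally sized clouds."""
        zs = []
        for s in range(0, len(clouds), batch_size):
            batch = clouds[s : s + batch_size]
            pts = np.stack([c.points for c in batch]) / self.cfg.input_scale
            scal = (
                np.stack([c.scalars for c in batch])
                if self.cfg.has_scalar_channel
                else None
            )
            out = self.encoder.forward_batch(pts, scal)
            if self.cfg.encoder == "vn_dgcnn":
                zs.append(np.linalg.norm(out.data, axis=-1))
            else:
                zs.append(out.data.copy())
        return np.concatenate(zs, axis=0)

    def reconstruct(self, pc: LabeledPointCloud) -> LabeledPointCloud:
        if self.cfg.decoder != "folding":
            raise InvalidInputError("reconstruct() requires the folding decoder")
        emb = self.encode(pc)
        z = Tensor(emb.z[None])
        R = emb.rotation()[None]
        out = self.decoder.forward_batch(z, R)
        return LabeledPointCloud(
            out.data[0] * self.cfg.input_scale,
            meta={"reconstruction_of": pc.meta},
        )

    def predict_sdf(self, pc: LabeledPointCloud, query: np.ndarray) -> np.ndarray:
        if self.cfg.decoder != "implicit_sdf":
            raise InvalidInputError("predict_sdf() requires the implicit decoder")
        scal = pc.scalars if self.cfg.has_scalar_channel else None
        s = self.cfg.input_scale
        pts = pc.points / s
        V = self.encoder.forward_batch(pts[None], None if scal is None else scal[None])
        out = self.decoder.forward_batch(V, np.asarray(query)[None] / s)
        return out.data[0].copy() * s


def _scalar_to_rows(z: np.ndarray) -> np.ndarray:
    """Embed a plain d-vector as (d, 3) rows so downstream code that
    expects a VectorEmbedding still works; norms recover |z| entries."""
    d = z.shape[0]
    V = np.zeros((d, 3))
    V[:, 0] = z
    return V


def build_model(cfg: ModelConfig) -> PointCloudAutoencoder:
    return PointCloudAutoencoder(cfg)


# ----- functional surface (spec-level operations) -------------------


def vn_encode(pc: LabeledPointCloud, cfg: ModelConfig, model: Optional[PointCloudAutoencoder] = None) -> VectorEmbedding:
    """Equivariant encoding of one point cloud.

    When ``model`` is omitted a freshly initialized (seeded) model is
    used — useful for architectural property checks with fixed random
    weights.
    """
    model = model or build_model(cfg)
    return model.encode(pc)


def invariant_representation(emb: VectorEmbedding) -> np.ndarray:
    """Row norms of the vector embedding (exactly rotation invariant)."""
    return emb.z


def rotation_from_vectors(emb: VectorEmbedding) -> np.ndarray:
    """Rotation matrix from the two designated latent vectors."""
    return emb.rotation()


def folding_decode(
    z: np.ndarray,
    R: Optional[np.ndarray],
    cfg: ModelConfig,
    model: Optional[PointCloudAutoencoder] = None,
) -> LabeledPointCloud:
    model = model or build_model(cfg)
    out = model.decoder.forward_batch(
        Tensor(np.asarray(z, dtype=float)[None]),
        None if R is None else np.asarray(R, dtype=float)[None],
    )
    return LabeledPointCloud(out.data[0])


def implicit_decode(
    emb: VectorEmbedding,
    query: np.ndarray,
    cfg: ModelConfig,
    model: Optional[PointCloudAutoencoder] = None,
) -> np.ndarray:
    model = model or build_model(cfg)
    V = Tensor(emb.V[None])
    out = model.decoder.forward_batch(V, np.asarray(query)[None])
    return out.data[0].copy()
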