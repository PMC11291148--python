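"""Vector-neuron building blocks and plain scalar layers.

Vector features are stored as ``(..., 3, C)`` arrays: 3-vectors along
axis -2, channels last, so a channel-mixing linear map is a plain
matmul on the last axis and commutes with any rotation applied to axis
-2 — the source of the architecture's exact equivariance.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, concatenate, cross, neighbor_mean

__all__ = [
    "Module",
    "VNLinear",
    "VNLeakyReLU",
    "Linear",
    "knn_indices",
    "edge_features_vn",
    "edge_features_scalar",
]


class Module:
    """Minimal parameter container with recursive collection."""

    def parameters(self) -> list[Parameter]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


def _init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    scale = np.sqrt(2.0 / max(fan_in, 1))
    return rng.standard_normal(shape) * scale


class VNLinear(Module):
    """Channel-mixing linear map on vector features: (..., 3, C) -> (..., 3, C')."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = Parameter(_init(rng, c_in, (c_in, c_out)))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W


class VNLeakyReLU(Module):
    """Vector-neuron leaky ReLU (Deng et al. style).

    A learned direction ``d`` (another channel mix) splits each vector's
    half-space: vectors with negative projection on ``d`` keep only a
    fraction ``alpha`` of that projection, removed along ``d``.
    """

    def __init__(self, c: int, rng: np.random.Generator, alpha: float = 0.2):
        self.D = Parameter(_init(rng, c, (c, c)))
        self.alpha = alpha

    def __call__(self, x: Tensor) -> Tensor:
        d = x @ self.D  # (..., 3, C)
        dot = (x * d).sum(axis=-2, keepdims=True)
        dsq = (d * d).sum(axis=-2, keepdims=True) + 1e-9
        neg = (dot.data < 0).astype(float)  # constant half-space mask
        coeff = Tensor(neg) * dot / dsq
        return x - (1.0 - self.alpha) * coeff * d


class Linear(Module):
    """Plain affine layer for scalar (invariant) pathways."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, bias=True):
        self.W = Parameter(_init(rng, c_in, (c_in, c_out)))
        self.b = Parameter(np.zeros(c_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


def knn_indices(x: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbors per point from a descriptor array.

    x: (N, D) or (B, N, D). Neighbors are ordered by increasing
    distance, ties broken by ascending index, self excluded. Raises when
    N <= k.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    B, N, _ = x.shape
    if N <= k:
        raise ValueError(f"k-NN graph needs more points than k (N={N}, k={k})")
    out = np.empty((B, N, k), dtype=np.int64)
    for b in range(B):
        sq = np.sum(x[b] ** 2, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (x[b] @ x[b].T)
        np.fill_diagonal(d2, np.inf)
        # lexsort: primary key distance, secondary ascending index
        idx = np.lexsort((np.broadcast_to(np.arange(N), (N, N)), d2), axis=1)
        out[b] = idx[:, :k]
    return out[0] if single else out


def edge_features_vn(f: Tensor, points: Tensor, idx: np.ndarray) -> Tensor:
    """Neighborhood-pooled equivariant edge features for one block.

    f: (B, N, 3, C) vector features; points: (B, N, 3, 1) input points.
    Per edge (i, j) the features are [f_i, f_j - f_i, cross(f_j, x_i),
    x_i]; every term is linear in f_j with x_i fixed, so the mean over
    the k neighbors collapses onto the neighbor mean of f_j and the
    (B, N, k, ...) block never enters the graph. Returns
    (B, N, 3, 3C + 1).
    """
    fbar = neighbor_mean(f, idx)  # (B, N, 3, C)
    return concatenate(
        [f, fbar - f, cross(fbar, points, axis=-2), points], axis=-1
    )


def edge_features_scalar(s: Tensor, idx: np.ndarray) -> Tensor:
    """Pooled edge features for scalar pathways: [s_i, mean_j s_j - s_i]."""
    sbar = neighbor_mean(s, idx)
    return concatenate([s, sbar - s], axis=-1)
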