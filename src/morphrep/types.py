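"""Core containers shared across the pipeline.

The package moves data between three canonical forms: voxel grids
(:class:`VolumeImage`), point sets with an optional scalar channel
(:class:`LabeledPointCloud`), and triangle meshes (plain
:class:`trimesh.Trimesh`). Model outputs live in
:class:`VectorEmbedding`, a stack of latent 3-vectors whose row norms
form the rotation-invariant representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh

__all__ = [
    "VolumeImage",
    "LabeledPointCloud",
    "VectorEmbedding",
    "InvalidInputError",
    "PackingCapacityError",
    "PlacementError",
]


class InvalidInputError(ValueError):
    """Raised when an operation receives input violating its contract."""


class PackingCapacityError(RuntimeError):
    """Raised when sphere packing cannot place the requested count.

    Attributes
    ----------
    placed : int
        Number of spheres successfully placed before giving up.
    """

    def __init__(self, message: str, placed: int):
        super().__init__(message)
        self.placed = placed


class PlacementError(RuntimeError):
    """Raised when multi-piece blob placement cannot satisfy spacing."""


VOLUME_ROLES = ("intensity", "mask", "sdf", "density")


@dataclass
class VolumeImage:
    """A 3D scalar grid with voxel spacing and a semantic role.

    Roles: ``intensity`` (raw fluorescence-like values), ``mask``
    (binary 0/1), ``sdf`` (signed distance, positive outside), and
    ``density`` (nonnegative, sums to 1 over the grid).
    """

    data: np.ndarray
    role: str = "intensity"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidInputError(
                f"VolumeImage requires a 3D array, got shape {self.data.shape}"
            )
        if self.role not in VOLUME_ROLES:
            raise InvalidInputError(f"unknown volume role {self.role!r}")
        if self.role == "mask":
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise InvalidInputError(
                    "mask volumes must be binary with values in {0, 1}"
                )
            self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def centroid(self) -> np.ndarray:
        """Center of mass of the grid values (voxel coordinates)."""
        w = np.abs(self.data).astype(float)
        total = w.sum()
        if total == 0:
            raise InvalidInputError("cannot compute centroid of an all-zero volume")
        idx = np.indices(self.data.shape).reshape(3, -1)
        return (idx * w.reshape(1, -1)).sum(axis=1) / total


@dataclass
class LabeledPointCloud:
    """N points in 3D with an optional scalar channel and metadata.

    ``points`` is (N, 3); ``scalars`` is (N,) carrying intensity or SDF
    values when present. ``meta`` records provenance such as the packing
    rule and the seed that produced the cloud.
    """

    points: np.ndarray
    scalars: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.scalars is not None:
            self.scalars = np.asarray(self.scalars, dtype=float).reshape(-1)
            if self.scalars.shape[0] != self.points.shape[0]:
                raise InvalidInputError("scalars length must match point count")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def n_channels(self) -> int:
        return 3 if self.scalars is None else 4

    def as_array(self) -> np.ndarray:
        """Return an (N, 3) or (N, 4) array (scalar channel last)."""
        if self.scalars is None:
            return self.points.copy()
        return np.concatenate([self.points, self.scalars[:, None]], axis=1)

    @classmethod
    def from_array(cls, arr: np.ndarray, meta: Optional[dict] = None) -> "LabeledPointCloud":
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[1] not in (3, 4):
            raise InvalidInputError(f"expected (N,3) or (N,4) array, got {arr.shape}")
        scal = arr[:, 3] if arr.shape[1] == 4 else None
        return cls(points=arr[:, :3], scalars=scal, meta=dict(meta or {}))

    def transformed(self, rotation: np.ndarray) -> "LabeledPointCloud":
        """Rotate the spatial channels; the scalar channel is untouched."""
        R = np.asarray(rotation, dtype=float)
        return LabeledPointCloud(
            points=self.points @ R.T,
            scalars=None if self.scalars is None else self.scalars.copy(),
            meta=dict(self.meta),
        )


@dataclass
class VectorEmbedding:
    """Equivariant latent: d latent 3-vectors stacked as a (d, 3) array.

    Under an input rotation ``Q`` (points ``x -> x @ Q.T``) the rows
    transform as ``V -> V @ Q.T``, so the row norms ``z`` are invariant
    and a rotation matrix can be recovered from designated rows.
    """

    V: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        if self.V.ndim != 2 or self.V.shape[1] != 3:
            raise InvalidInputError(f"V must be (d, 3), got {self.V.shape}")

    @property
    def z(self) -> np.ndarray:
        """Rotation-invariant representation: Euclidean norm of each row."""
        return np.linalg.norm(self.V, axis=1)

    @property
    def d(self) -> int:
        return self.V.shape[0]

    def rotation(self) -> np.ndarray:
        """Orthonormal frame estimated from the first two latent vectors.

        Gram–Schmidt on rows 0 and 1 plus a cross product; falls back to
        the identity (and sets ``meta['rotation_fallback']``) when the two
        vectors are near-parallel (angle < 1e-3 rad) or degenerate.
        """
        a, b = self.V[0], self.V[1]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-12 or nb < 1e-12:
            self.meta["rotation_fallback"] = True
            return np.eye(3)
        e1 = a / na
        b_perp = b - (b @ e1) * e1
        nperp = np.linalg.norm(b_perp)
        # sin(angle) between a and b; below ~1e-3 rad the frame is unstable
        if nperp / nb < 1e-3:
            self.meta["rotation_fallback"] = True
            return np.eye(3)
        e2 = b_perp / nperp
        e3 = np.cross(e1, e2)
        return np.stack([e1, e2, e3], axis=1)


def as_mesh(obj) -> trimesh.Trimesh:
    """Coerce to a trimesh.Trimesh, validating emptiness."""
    if isinstance(obj, trimesh.Trimesh):
        return obj
    raise InvalidInputError(f"expected a trimesh.Trimesh, got {type(obj)!r}")
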