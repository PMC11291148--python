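"""Punctate preprocessing: masked intensity volumes to 4D (XYZ +
intensity) point clouds.

The sampling density is the skewness-weighted exponential
``exp(lambda * skew * I)`` over masked, [0, 1]-rescaled intensities,
normalized to a probability density; points are drawn per voxel with
sub-voxel uniform placement, centered on the mask centroid, and carry
the voxel intensity scaled by 0.1 as a fourth channel. Jitter
augmentation adds clipped Gaussian noise to the spatial channels and
can also upsample sparse clouds by concatenating jittered copies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import InvalidInputError, LabeledPointCloud, VolumeImage

__all__ = [
    "PointSamplingConfig",
    "JitterConfig",
    "intensity_to_density",
    "sample_intensity_pointcloud",
    "jitter_augment",
]


@dataclass
class PointSamplingConfig:
    """Sampling parameters.

    ``lam`` is the structure-specific exponential scale (100 for nuclear
    structures such as replication foci, 500 for cytoplasmic punctate
    structures); 20,480 dense / 2,048 sparse points; intensity channel
    scaled by 0.1 to match the magnitude of spatial coordinates.
    """

    lam: float = 100.0
    n_dense: int = 20480
    n_sparse: int = 2048
    intensity_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.lam <= 0:
            raise InvalidInputError("lam must be positive")
        if self.n_sparse > self.n_dense:
            raise InvalidInputError("n_sparse must not exceed n_dense")


@dataclass
class JitterConfig:
    """Clipped Gaussian jitter: sd 0.1 clipped at 0.2 (point units)."""

    sd: float = 0.1
    clip: float = 0.2
    repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.sd < 0 or self.clip < 0:
            raise InvalidInputError("sd and clip must be nonnegative")
        if self.repeats < 1:
            raise InvalidInputError("repeats must be >= 1")


def _masked_skewness(values: np.ndarray) -> float:
    """Fisher-Pearson sample skewness (bias-uncorrected); 0 when
    degenerate (constant input)."""
    if values.size < 2 or np.ptp(values) == 0:
        return 0.0
    s = stats.skew(values, bias=True)
    return float(0.0 if not np.isfinite(s) else s)


def _exponential_density(
    intensity: np.ndarray, mask: np.ndarray, coeff: float
) -> np.ndarray:
    """Normalized density ``exp(coeff * I)`` over the mask.

    ``I`` is the masked intensity rescaled to [0, 1]; the exponent is
    shifted by its max for numerical stability (invariant under
    normalization). Exposed for direct evaluation with a hand-chosen
    combined coefficient lambda * skew.
    """
    m = mask.astype(bool)
    vals = intensity[m].astype(float)
    lo, hi = vals.min(), vals.max()
    scaled = np.zeros_like(vals) if hi == lo else (vals - lo) / (hi - lo)
    expo = coeff * scaled
    expo -= expo.max()
    w = np.exp(expo)
    density = np.zeros(intensity.shape, dtype=float)
    density[m] = w / w.sum()
    return density


def intensity_to_density(
    volume: VolumeImage, mask: VolumeImage, lam: float = 100.0
) -> VolumeImage:
    """Skewness-weighted exponential sampling density over the mask.

    The masked intensities are rescaled to [0, 1]; the density is
    ``exp(lam * skew * I)`` normalized to sum 1, zero outside the mask.
    Constant or symmetric (zero-skew) intensities give a uniform density
    over the mask.
    """
    if volume.shape != mask.shape:
        raise InvalidInputError("volume and mask must share a grid")
    m = mask.data.astype(bool)
    if not m.any():
        raise InvalidInputError("mask is empty")
    vals = volume.data[m].astype(float)
    lo, hi = vals.min(), vals.max()
    scaled = np.zeros_like(vals) if hi == lo else (vals - lo) / (hi - lo)
    skew = _masked_skewness(scaled)
    density = _exponential_density(volume.data, mask.data, lam * skew)
    return VolumeImage(density, role="density",
                       meta={"lam": float(lam), "skewness": skew})


def sample_intensity_pointcloud(
    density: VolumeImage,
    volume: VolumeImage,
    mask: VolumeImage,
    cfg: PointSamplingConfig,
    sparse: bool = False,
) -> LabeledPointCloud:
    """Sample a 4D point cloud from the density.

    Voxels are drawn multinomially with the density as weights; each
    point is placed uniformly at random within its voxel cell (avoids
    lattice artifacts in neighbor graphs). Spatial coordinates are
    centered on the mask centroid; the fourth channel is the source
    voxel's intensity times ``intensity_scale``. With ``sparse=True``
    the dense cloud is subsampled to ``n_sparse`` points.
    """
    d = density.data
    if d.shape != volume.shape or d.shape != mask.shape:
        raise InvalidInputError("density, volume and mask must share a grid")
    flat = d.reshape(-1)
    support = np.flatnonzero(flat > 0)
    if len(support) < 1:
        raise InvalidInputError("density has no support")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_dense
    choice = rng.choice(support, size=n, replace=True, p=flat[support] / flat[support].sum())
    coords = np.stack(np.unravel_index(choice, d.shape), axis=1).astype(float)
    coords += rng.uniform(-0.5, 0.5, size=coords.shape)
    centroid = mask.centroid()
    pts = coords - centroid[None, :]
    intens = volume.data.reshape(-1)[choice].astype(float) * cfg.intensity_scale
    pc = LabeledPointCloud(points=pts, scalars=intens,
                           meta={"seed": int(cfg.seed), "lam": density.meta.get("lam")})
    if sparse:
        sel = rng.choice(n, size=cfg.n_sparse, replace=False)
        pc = LabeledPointCloud(points=pc.points[sel], scalars=pc.scalars[sel],
                               meta=dict(pc.meta))
    return pc


def jitter_augment(
    pc: LabeledPointCloud, cfg: JitterConfig, expand: bool = False
):
    """Jittered copies of a point cloud.

    Returns ``cfg.repeats`` clouds whose spatial channels carry clipped
    Gaussian noise; the scalar channel is untouched. With
    ``expand=True`` the copies are concatenated into one upsampled cloud
    (e.g. 256 points x 8 repeats -> 2,048 points).
    """
    if len(pc) == 0:
        raise InvalidInputError("cannot jitter an empty point cloud")
    rng = np.random.default_rng(cfg.seed)
    copies = []
    for _ in range(cfg.repeats):
        noise = (
            np.clip(rng.normal(0.0, cfg.sd, size=pc.points.shape), -cfg.clip, cfg.clip)
            if cfg.sd > 0
            else np.zeros_like(pc.points)
        )
        copies.append(
            LabeledPointCloud(
                points=pc.points + noise,
                scalars=None if pc.scalars is None else pc.scalars.copy(),
                meta=dict(pc.meta),
            )
        )
    if not expand:
        return copies
    pts = np.concatenate([c.points for c in copies], axis=0)
    scal = (
        None
        if pc.scalars is None
        else np.concatenate([c.scalars for c in copies], axis=0)
    )
    return LabeledPointCloud(points=pts, scalars=scal, meta=dict(pc.meta))
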