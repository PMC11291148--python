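"""Multi-metric evaluation of learned shape representations.

Metrics: rotation-invariance error, reconstruction error (chamfer for
punctate clouds, zero-level-set Jaccard for SDF models), evolution
energy and interpolation distance of latent interpolations,
Levina-Bickel intrinsic dimensionality, probe classification and
regression, segmentation piece features, and a z-scored cross-model
report.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import label as cc_label
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import RepeatedKFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .types import InvalidInputError, LabeledPointCloud

__all__ = [
    "PieceFeatureRow",
    "ProbeResult",
    "BenchmarkReport",
    "rotation_invariance_error",
    "reconstruction_error",
    "evolution_energy",
    "interpolation_distance",
    "compactness",
    "probe_classification",
    "probe_regression",
    "piece_features",
    "benchmark_report",
    "jaccard_similarity",
    "inference_time",
]

QUARTER_TURNS_DEG = (90.0, 180.0, 270.0, 360.0)

# probe metrics measure downstream usefulness directly, so larger is
# already better and their sign is never flipped in the report
UNFLIPPED_METRICS = frozenset({
    "classification_accuracy",
    "classification_top2_accuracy",
    "regression_r2",
    "jaccard",
    "reconstruction_jaccard",
})


def rotation_z(angle_deg: float) -> np.ndarray:
    """Rotation matrix about the z axis (the imaging axis)."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_invariance_error(
    embed_fn,
    clouds,
    rotations_deg=QUARTER_TURNS_DEG,
) -> float:
    """Mean relative embedding shift under in-plane quarter turns.

    Per sample and rotation angle, the error is
    ``||z_rot - z_0|| / (||z_rot|| + ||z_0||)``; the result averages over
    the four quarter turns and over samples and lies in [0, 1]. Pairs
    where both embeddings are zero are skipped with a warning.
    """
    errs = []
    for pc in clouds:
        pts = pc.points if isinstance(pc, LabeledPointCloud) else np.asarray(pc)
        scal = pc.scalars if isinstance(pc, LabeledPointCloud) else None
        z0 = np.asarray(embed_fn(pts, scal), dtype=float).ravel()
        for ang in rotations_deg:
            q = rotation_z(ang)
            zr = np.asarray(embed_fn(pts @ q.T, scal), dtype=float).ravel()
            denom = np.linalg.norm(zr) + np.linalg.norm(z0)
            if denom == 0:
                warnings.warn("both embeddings zero; pair skipped")
                continue
            errs.append(np.linalg.norm(zr - z0) / denom)
    if not errs:
        raise InvalidInputError("no valid embedding pairs")
    return float(np.mean(errs))


def jaccard_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks (1.0 for two empties)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def reconstruction_error(
    model,
    dataset,
    modality: str,
    return_per_sample: bool = False,
):
    """Test-set reconstruction quality.

    ``modality='punctate'``: ``dataset`` is a sequence of point clouds;
    returns the mean chamfer distance between each cloud and its
    autoencoder reconstruction. ``modality='sdf'``: ``dataset`` is a
    sequence of ``(surface_cloud, ground_truth_mask)`` pairs; the model's
    predicted SDF on the mask grid is meshed at the zero level,
    voxelized, and scored by Jaccard similarity against the mask
    (reported as similarity; the report layer handles orientation).
    Samples whose predicted level set is empty score 0 and are flagged.
    """
    if modality not in ("punctate", "sdf"):
        raise InvalidInputError(f"unknown modality {modality!r}")
    if len(dataset) == 0:
        raise InvalidInputError("empty evaluation set")
    per_sample = []
    if modality == "punctate":
        from .nn.losses import pointcloud_distance

        for pc in dataset:
            recon = model.reconstruct(pc)
            ref = pc.points if isinstance(pc, LabeledPointCloud) else np.asarray(pc)
            per_sample.append(
                (pointcloud_distance(ref, recon, kind="chamfer"), False)
            )
    else:
        from .polymorphic import reconstruct_mask_from_sdf

        for surface, gt_mask in dataset:
            gt = np.asarray(gt_mask, dtype=bool)
            g = gt.shape[0]
            origin = -np.full(3, (g - 1) / 2.0)
            grid = np.indices(gt.shape).reshape(3, -1).T.astype(float) + origin
            pred = model.predict_sdf(surface, grid).reshape(gt.shape)
            rec = reconstruct_mask_from_sdf(pred, gt.shape)
            if rec.sum() == 0:
                per_sample.append((0.0, True))
            else:
                per_sample.append((jaccard_similarity(rec, gt), False))
    mean = float(np.mean([v for v, _ in per_sample]))
    if return_per_sample:
        return mean, per_sample
    return mean


def evolution_energy(
    decode_fn,
    embeddings: np.ndarray,
    metric_fn,
    n_pairs: int = 10,
    n_interp: int = 10,
    seed: int = 0,
    max_resample: int = 50,
) -> float:
    """Smoothness of decoded latent interpolations.

    For each sampled pair, decode x_0 and x_1 from their embeddings and
    the interpolants x_t at the ``n_interp`` points t = k/n_interp,
    k = 1..n_interp. Each point contributes
    ``e_t = [d(x_t, x_0) + d(x_t, x_1)] / d(x_0, x_1)``; pair energy is
    the mean over t (comparable across n_interp choices) and the result
    the mean over pairs. Pairs with coincident endpoint reconstructions
    are resampled; energy >= 1 whenever the metric obeys the triangle
    inequality.
    """
    z = np.asarray(embeddings, dtype=float)
    if len(z) < 2:
        raise InvalidInputError("need at least two embeddings")
    rng = np.random.default_rng(seed)
    ts = (np.arange(n_interp) + 1) / n_interp
    energies = []
    for _ in range(n_pairs):
        for _attempt in range(max_resample):
            i, j = rng.choice(len(z), size=2, replace=False)
            x0 = decode_fn(z[i])
            x1 = decode_fn(z[j])
            d01 = metric_fn(x0, x1)
            if d01 > 0:
                break
        else:
            raise InvalidInputError(
                "could not sample a pair with distinct reconstructions"
            )
        es = []
        for t in ts:
            xt = decode_fn((1.0 - t) * z[i] + t * z[j])
            es.append((metric_fn(xt, x0) + metric_fn(xt, x1)) / d01)
        energies.append(np.mean(es))
    return float(np.mean(energies))


def interpolation_distance(
    embeddings: np.ndarray,
    n_pairs: int = 10,
    n_interp: int = 10,
    seed: int = 0,
) -> float:
    """Mean distance from latent interpolants to the nearest real
    embedding.

    Pairs are sampled at random; each contributes ``n_interp`` equally
    spaced points on the segment (endpoints included, which sit at
    distance zero by construction). Small values indicate interpolations
    stay close to the data manifold.
    """
    z = np.asarray(embeddings, dtype=float)
    if len(z) < 2:
        raise InvalidInputError("need at least two embeddings")
    rng = np.random.default_rng(seed)
    ts = np.linspace(0.0, 1.0, n_interp)
    dists = []
    for _ in range(n_pairs):
        i, j = rng.choice(len(z), size=2, replace=False)
        interp = (1.0 - ts[:, None]) * z[i][None, :] + ts[:, None] * z[j][None, :]
        d = np.linalg.norm(interp[:, None, :] - z[None, :, :], axis=-1)
        dists.append(d.min(axis=1))
    return float(np.mean(np.concatenate(dists)))


def compactness(embeddings: np.ndarray, k_range=range(5, 21)) -> float:
    """Levina-Bickel maximum-likelihood intrinsic dimension, averaged
    over neighborhood sizes k.

    Duplicate embeddings (which yield zero neighbor distances and an
    undefined likelihood) are removed with a warning.
    """
    from scipy.spatial import cKDTree

    z = np.asarray(embeddings, dtype=float)
    uniq = np.unique(z, axis=0)
    if len(uniq) < len(z):
        warnings.warn(f"removed {len(z) - len(uniq)} duplicate embeddings")
        z = uniq
    ks = list(k_range)
    kmax = max(ks)
    if len(z) <= kmax + 1:
        raise InvalidInputError(
            f"need more than {kmax + 1} distinct samples for k up to {kmax}"
        )
    tree = cKDTree(z)
    # distances to the kmax nearest neighbors, self excluded
    d, _ = tree.query(z, k=kmax + 1, workers=-1)
    d = d[:, 1:]
    logd = np.log(d)
    estimates = []
    for k in ks:
        # m_k(x) = [ (1/(k-1)) * sum_{j<k} log(T_k/T_j) ]^{-1}
        s = logd[:, k - 1][:, None] - logd[:, : k - 1]
        inv = s.sum(axis=1) / (k - 1)
        estimates.append(np.mean(1.0 / inv))
    return float(np.mean(estimates))


@dataclass
class ProbeResult:
    """Cross-validated probe score with per-fold values."""

    mean: float
    per_fold: list

    def __float__(self):
        return self.mean


def probe_classification(
    embeddings: np.ndarray,
    labels,
    top_k: int = 1,
    n_splits: int = 5,
    seed: int = 0,
) -> ProbeResult:
    """Logistic-regression probe accuracy under stratified k-fold CV.

    Features are standardized inside each fold; classes are reweighted
    inversely to frequency. ``top_k > 1`` scores a prediction correct
    when the true class is among the k most probable.
    """
    z = np.asarray(embeddings, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InvalidInputError("need at least two classes")
    small = classes[counts < n_splits]
    if len(small):
        raise InvalidInputError(
            f"class {small[0]!r} has fewer than {n_splits} members"
        )
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = []
    for tr, te in cv.split(z, y):
        clf = make_pipeline(
            StandardScaler(),
            LogisticRegression(class_weight="balanced", max_iter=2000),
        )
        clf.fit(z[tr], y[tr])
        if top_k == 1:
            scores.append(float(np.mean(clf.predict(z[te]) == y[te])))
        else:
            proba = clf.predict_proba(z[te])
            order = np.argsort(proba, axis=1)[:, ::-1][:, :top_k]
            cls = clf.classes_[order]
            scores.append(float(np.mean([yt in row for yt, row in zip(y[te], cls)])))
    return ProbeResult(mean=float(np.mean(scores)), per_fold=scores)


def probe_regression(
    embeddings: np.ndarray,
    targets: np.ndarray,
    n_splits: int = 5,
    n_repeats: int = 20,
    seed: int = 0,
) -> ProbeResult:
    """Linear-regression probe R^2 under repeated k-fold CV (5 x 20)."""
    z = np.asarray(embeddings, dtype=float)
    t = np.asarray(targets, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidInputError("targets must be finite")
    if np.ptp(t) == 0:
        raise InvalidInputError("constant target: R^2 undefined")
    cv = RepeatedKFold(n_splits=n_splits, n_repeats=n_repeats, random_state=seed)
    scores = []
    for tr, te in cv.split(z):
        reg = make_pipeline(StandardScaler(), LinearRegression())
        reg.fit(z[tr], t[tr])
        scores.append(float(reg.score(z[te], t[te])))
    return ProbeResult(mean=float(np.mean(scores)), per_fold=scores)


@dataclass
class PieceFeatureRow:
    """Shape features of one multi-piece segmentation."""

    piece_count: int
    volume_mean: float
    volume_sd: float
    area_mean: float
    area_sd: float
    centroid_distance_mean: float
    centroid_distance_sd: float
    piece_class: str
    distances_valid: bool


def _piece_class(n: int) -> str:
    return str(n) if n < 5 else ">=5"


def piece_features(seg: np.ndarray) -> PieceFeatureRow:
    """Per-sample piece statistics of a binary segmentation.

    Pieces are 26-connected components; surface area comes from a
    marching-cubes mesh of each piece. Single-piece samples carry
    distance features 0 with ``distances_valid=False``.
    """
    import trimesh
    from skimage.measure import marching_cubes

    data = np.asarray(seg).astype(bool)
    if not data.any():
        raise InvalidInputError("empty segmentation")
    lab, n = cc_label(data, structure=np.ones((3, 3, 3)))
    vols, areas, cents = [], [], []
    for i in range(1, n + 1):
        piece = lab == i
        vols.append(float(piece.sum()))
        cents.append(np.argwhere(piece).mean(axis=0))
        verts, faces, _, _ = marching_cubes(np.pad(piece, 1).astype(float), level=0.5)
        areas.append(float(trimesh.Trimesh(verts, faces, process=False).area))
    vols = np.array(vols)
    areas = np.array(areas)
    cents = np.array(cents)
    if n >= 2:
        iu = np.triu_indices(n, k=1)
        dists = np.linalg.norm(cents[iu[0]] - cents[iu[1]], axis=1)
        dmean, dsd, valid = float(dists.mean()), float(dists.std()), True
    else:
        dmean, dsd, valid = 0.0, 0.0, False
    return PieceFeatureRow(
        piece_count=int(n),
        volume_mean=float(vols.mean()),
        volume_sd=float(vols.std()),
        area_mean=float(areas.mean()),
        area_sd=float(areas.std()),
        centroid_distance_mean=dmean,
        centroid_distance_sd=dsd,
        piece_class=_piece_class(n),
        distances_valid=valid,
    )


def inference_time(embed_fn, clouds, n_repeats: int = 3) -> float:
    """Median wall-clock seconds per sample for one embedding pass."""
    times = []
    for _ in range(n_repeats):
        t0 = time.perf_counter()
        for pc in clouds:
            pts = pc.points if isinstance(pc, LabeledPointCloud) else np.asarray(pc)
            scal = pc.scalars if isinstance(pc, LabeledPointCloud) else None
            embed_fn(pts, scal)
        times.append((time.perf_counter() - t0) / max(1, len(clouds)))
    return float(np.median(times))


@dataclass
class BenchmarkReport:
    """Raw and z-scored cross-model metric tables.

    The z-scored view standardizes each metric across models
    (population standard deviation) and flips signs so larger is better
    for every metric except the probe scores; the flip set is recorded.
    """

    raw: pd.DataFrame
    zscored: pd.DataFrame | None
    flipped_metrics: list
    message: str = ""
    metadata: dict = field(default_factory=dict)

    def to_long(self) -> pd.DataFrame:
        """Long-format (model, metric, value) table of the z-scored
        view, ready for polar plotting."""
        if self.zscored is None:
            raise InvalidInputError("z-scored view unavailable: " + self.message)
        long = self.zscored.reset_index().melt(
            id_vars="model", var_name="metric", value_name="value"
        )
        return long

    def save(self, prefix: str):
        """Write <prefix>_raw.csv, <prefix>_zscored.csv (when present)
        and <prefix>.json."""
        import json
        from pathlib import Path

        self.raw.to_csv(f"{prefix}_raw.csv")
        payload = {
            "flipped_metrics": list(self.flipped_metrics),
            "message": self.message,
            "metadata": self.metadata,
            "raw": self.raw.to_dict(orient="index"),
        }
        if self.zscored is not None:
            self.zscored.to_csv(f"{prefix}_zscored.csv")
            payload["zscored"] = self.zscored.to_dict(orient="index")
        Path(f"{prefix}.json").write_text(json.dumps(payload, indent=2))


def benchmark_report(
    metrics_by_model: dict,
    unflipped=UNFLIPPED_METRICS,
    metadata: dict | None = None,
) -> BenchmarkReport:
    """Assemble the cross-model report.

    ``metrics_by_model`` maps model name to a {metric: value} dict
    (include parameter counts and inference times as ordinary columns).
    With a single model only the raw table is produced and the z-scored
    view is refused with a message.
    """
    if not metrics_by_model:
        raise InvalidInputError("no models")
    raw = pd.DataFrame.from_dict(metrics_by_model, orient="index")
    raw.index.name = "model"
    meta = dict(metadata or {})
    if len(raw) < 2:
        return BenchmarkReport(
            raw=raw,
            zscored=None,
            flipped_metrics=[],
            message="z-scoring requires at least two models",
            metadata=meta,
        )
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=0)
    z = (raw - mu) / sd.replace(0.0, 1.0)
    flipped = [c for c in raw.columns if c not in unflipped]
    z[flipped] = -z[flipped]
    meta["zscore_convention"] = "population sd; larger is better after flips"
    return BenchmarkReport(
        raw=raw, zscored=z, flipped_metrics=flipped, metadata=meta
    )
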