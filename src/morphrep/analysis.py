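"""Downstream interpretation of learned representations: PCA latent
walks, archetype analysis, nearest-real-example retrieval,
nuclear-volume binning, and perturbation statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import average_precision_score

from .types import InvalidInputError

__all__ = [
    "LatentWalkResult",
    "ArchetypeResult",
    "VolumeBinProfile",
    "PerturbationStats",
    "DEFAULT_MAP_POINTS",
    "VOLUME_BIN_EDGES",
    "pca_latent_walk",
    "closest_real_example",
    "archetypes",
    "volume_bin_profile",
    "perturbation_stats",
]

DEFAULT_MAP_POINTS = (-2.0, 0.0, 2.0)

# nuclear-volume bin interior edges in cubic micrometers; with the
# 2.5/97.5 percentile clip these give the five reported bins
# <390, 390-533, 533-676, 676-818, >818
VOLUME_BIN_EDGES = (390.0, 533.0, 676.0, 818.0)


@dataclass
class LatentWalkResult:
    """Shapes decoded along principal components of the embedding cloud.

    ``walk_vectors[c][m]`` is the embedding-space point for component
    ``c`` at map point ``map_points[m]`` (in units of that component's
    standard deviation). ``decoded`` holds decoder outputs when a
    decoder is supplied, else ``nearest_ids`` holds retrieved sample
    indices.
    """

    components: list
    map_points: tuple
    walk_vectors: np.ndarray  # (n_components, n_map_points, dim)
    explained_variance_ratio: np.ndarray
    decoded: list | None = None
    nearest_ids: np.ndarray | None = None


def pca_latent_walk(
    embeddings: np.ndarray,
    n_components: int = 2,
    map_points=DEFAULT_MAP_POINTS,
    decode_fn=None,
) -> LatentWalkResult:
    """Walk each principal component at the given map points.

    The walk point for component c at map point m is
    ``mean + m * sd_c * component_c`` where sd_c is the standard
    deviation of the scores along that component. With ``decode_fn``
    the walk vectors are decoded to shapes; otherwise they are routed
    to :func:`closest_real_example` and sample indices returned.
    """
    z = np.asarray(embeddings, dtype=float)
    rank = min(z.shape[0] - 1, z.shape[1])
    if n_components > rank:
        raise InvalidInputError(
            f"requested {n_components} components but data rank is at most {rank}"
        )
    pca = PCA(n_components=n_components)
    pca.fit(z)
    sds = np.sqrt(pca.explained_variance_)
    mp = tuple(float(m) for m in map_points)
    walks = np.empty((n_components, len(mp), z.shape[1]))
    for c in range(n_components):
        for k, m in enumerate(mp):
            walks[c, k] = pca.mean_ + m * sds[c] * pca.components_[c]
    result = LatentWalkResult(
        components=list(range(n_components)),
        map_points=mp,
        walk_vectors=walks,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )
    if decode_fn is not None:
        result.decoded = [
            [decode_fn(walks[c, k]) for k in range(len(mp))]
            for c in range(n_components)
        ]
    else:
        result.nearest_ids = np.array(
            [
                [closest_real_example(z, walks[c, k]) for k in range(len(mp))]
                for c in range(n_components)
            ]
        )
    return result


def closest_real_example(embeddings: np.ndarray, query: np.ndarray) -> int:
    """Index of the Euclidean nearest embedding; ties break to the
    lowest index."""
    z = np.asarray(embeddings, dtype=float)
    if len(z) == 0:
        raise InvalidInputError("no embeddings")
    d = np.linalg.norm(z - np.asarray(query, dtype=float)[None, :], axis=1)
    return int(np.argmin(d))


@dataclass
class ArchetypeResult:
    """Archetypal decomposition X ~ A Z with Z = B X.

    Rows of ``weights`` (A) and ``archetype_coefficients`` (B) are
    convex: nonnegative, summing to 1.
    """

    archetypes: np.ndarray  # (k, dim)
    weights: np.ndarray  # (n, k) convex combination of archetypes per sample
    archetype_coefficients: np.ndarray  # (k, n) convex combination of samples
    rss: float
    converged: bool
    n_iterations: int


def _fw_direction(W, grad):
    """Frank-Wolfe direction per row over the probability simplex: step
    toward the vertex with the most negative gradient."""
    verts = np.argmin(grad, axis=1)
    S = np.zeros_like(W)
    S[np.arange(len(W)), verts] = 1.0
    return S - W


def archetypes(
    embeddings: np.ndarray,
    n_archetypes: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> ArchetypeResult:
    """Archetype analysis by alternating Frank-Wolfe updates.

    Archetypes are convex combinations of data points that approximate
    the convex hull; each sample is approximated by a convex combination
    of archetypes. Minimizes ``||X - A B X||_F^2`` with A, B rows on the
    simplex using Frank-Wolfe steps with exact line search. Deterministic
    given ``seed``; if the relative residual change stays above ``tol``
    after ``max_iter`` alternations the result is returned with
    ``converged=False``.
    """
    X = np.asarray(embeddings, dtype=float)
    n = len(X)
    k = int(n_archetypes)
    if k > n:
        raise InvalidInputError("more archetypes than samples")
    rng = np.random.default_rng(seed)
    # FurthestSum initialization: greedily pick mutually distant
    # samples, then drop and replace the arbitrary starting pick
    start = int(rng.integers(n))
    chosen = [start]
    dist_sum = np.linalg.norm(X - X[start], axis=1)
    for _ in range(k):
        if len(chosen) > k - 1:
            dist_sum -= np.linalg.norm(X - X[chosen.pop(0)], axis=1)
        masked = dist_sum.copy()
        masked[chosen] = -np.inf
        nxt = int(np.argmax(masked))
        chosen.append(nxt)
        dist_sum += np.linalg.norm(X - X[nxt], axis=1)
    B = np.zeros((k, n))
    B[np.arange(k), chosen] = 1.0
    A = np.full((n, k), 1.0 / k)
    prev = None
    converged = False
    it = 0
    n_inner = 10
    for it in range(1, max_iter + 1):
        # A-subproblem: quadratic in A for fixed Z; inner Frank-Wolfe
        # steps with exact line search
        Z = B @ X
        for _ in range(n_inner):
            R = A @ Z - X
            D = _fw_direction(A, 2.0 * R @ Z.T)
            DZ = D @ Z
            den = float(np.sum(DZ * DZ))
            if den <= 0:
                break
            gamma = float(np.clip(-np.sum(R * DZ) / den, 0.0, 1.0))
            if gamma <= 0:
                break
            A = A + gamma * D
        # B-subproblem: quadratic in B for fixed A
        for _ in range(n_inner):
            R = A @ (B @ X) - X
            D = _fw_direction(B, 2.0 * (A.T @ R) @ X.T)
            ADX = A @ (D @ X)
            den = float(np.sum(ADX * ADX))
            if den <= 0:
                break
            gamma = float(np.clip(-np.sum(R * ADX) / den, 0.0, 1.0))
            if gamma <= 0:
                break
            B = B + gamma * D
        rss = float(np.sum((X - A @ B @ X) ** 2))
        if prev is not None and prev - rss <= tol * max(prev, 1e-12):
            converged = True
            prev = rss
            break
        prev = rss
    return ArchetypeResult(
        archetypes=B @ X,
        weights=A,
        archetype_coefficients=B,
        rss=prev,
        converged=converged,
        n_iterations=it,
    )


@dataclass
class VolumeBinProfile:
    """Per-bin embedding summary along the nuclear-volume axis."""

    bin_labels: list
    bin_edges: tuple
    counts: np.ndarray
    bin_assignment: np.ndarray  # per retained sample, bin index
    retained_idx: np.ndarray  # indices into the original arrays
    mean_embeddings: list  # per bin: (dim,) array or None when empty
    representatives: list  # per bin: decoded shape / sample id / None
    clip_range: tuple


def volume_bin_profile(
    embeddings: np.ndarray,
    nuclear_volumes: np.ndarray,
    edges=VOLUME_BIN_EDGES,
    clip_percentiles=(2.5, 97.5),
    decode_fn=None,
) -> VolumeBinProfile:
    """Bin samples by nuclear volume and summarize embeddings per bin.

    Volumes outside the percentile clip are dropped; the remaining
    samples are partitioned by the interior ``edges`` (default bins
    <390, 390-533, 533-676, 676-818, >818 cubic micrometers). Each
    populated bin gets the mean embedding and a representative (decoded
    from the mean with ``decode_fn``, else the nearest real sample's
    index); empty bins report count 0 and no representative.
    """
    z = np.asarray(embeddings, dtype=float)
    v = np.asarray(nuclear_volumes, dtype=float)
    if np.any(v <= 0):
        raise InvalidInputError("nuclear volumes must be positive")
    if len(v) != len(z):
        raise InvalidInputError("embeddings and volumes must align")
    lo, hi = np.percentile(v, clip_percentiles)
    keep = np.nonzero((v >= lo) & (v <= hi))[0]
    vk = v[keep]
    e = tuple(float(x) for x in edges)
    labels = (
        [f"<{e[0]:g}"]
        + [f"{a:g}-{b:g}" for a, b in zip(e[:-1], e[1:])]
        + [f">{e[-1]:g}"]
    )
    assign = np.digitize(vk, e)
    n_bins = len(e) + 1
    counts = np.bincount(assign, minlength=n_bins)
    means, reps = [], []
    for b in range(n_bins):
        members = keep[assign == b]
        if len(members) == 0:
            means.append(None)
            reps.append(None)
            continue
        mu = z[members].mean(axis=0)
        means.append(mu)
        reps.append(decode_fn(mu) if decode_fn is not None
                    else int(members[closest_real_example(z[members], mu)]))
    return VolumeBinProfile(
        bin_labels=labels,
        bin_edges=e,
        counts=counts,
        bin_assignment=assign,
        retained_idx=keep,
        mean_embeddings=means,
        representatives=reps,
        clip_range=(float(lo), float(hi)),
    )


@dataclass
class PerturbationStats:
    """Per-condition retrieval statistics against the control group."""

    conditions: list
    map_scores: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    n_treated: np.ndarray
    n_control: int
    n_permutations: int
    meta: dict = field(default_factory=dict)


def _condition_map(z_pool: np.ndarray, is_treated: np.ndarray) -> float:
    """Mean average precision of retrieving treated cells.

    For each treated cell, the remaining pooled cells are ranked by
    cosine similarity and scored by average precision of the treated
    label; the condition score is the mean over treated cells.
    """
    norms = np.linalg.norm(z_pool, axis=1)
    norms[norms == 0] = 1.0
    u = z_pool / norms[:, None]
    sim = u @ u.T
    aps = []
    idx = np.nonzero(is_treated)[0]
    for i in idx:
        mask = np.ones(len(z_pool), dtype=bool)
        mask[i] = False
        aps.append(average_precision_score(is_treated[mask], sim[i][mask]))
    return float(np.mean(aps))


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def perturbation_stats(
    embeddings: np.ndarray,
    condition_labels,
    control_label,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PerturbationStats:
    """How distinguishable each condition's cells are from control.

    Per condition, treated and control cells are pooled; each treated
    cell ranks the others by cosine similarity in embedding space and is
    scored by average precision of retrieving its own condition; the
    condition mAP is the mean over treated cells. The null distribution
    permutes treated/control labels within the pool; the one-sided
    p-value uses add-one smoothing, ``p = (1 + #{null >= observed}) /
    (1 + n_permutations)``, and q-values are Benjamini-Hochberg adjusted
    across conditions.
    """
    z = np.asarray(embeddings, dtype=float)
    y = np.asarray(condition_labels)
    if n_permutations < 100:
        warnings.warn("n_permutations < 100: p-value resolution is limited")
    ctrl = np.nonzero(y == control_label)[0]
    if len(ctrl) == 0:
        raise InvalidInputError("control group is empty")
    conditions = [c for c in np.unique(y) if c != control_label]
    if not conditions:
        raise InvalidInputError("no treated conditions")
    rng = np.random.default_rng(seed)
    maps, ps, ns = [], [], []
    for cond in conditions:
        treated = np.nonzero(y == cond)[0]
        if len(treated) < 2:
            raise InvalidInputError(f"condition {cond!r} has fewer than 2 cells")
        pool = np.concatenate([treated, ctrl])
        zp = z[pool]
        flag = np.zeros(len(pool), dtype=bool)
        flag[: len(treated)] = True
        obs = _condition_map(zp, flag)
        null_ge = 0
        for _ in range(n_permutations):
            null_ge += _condition_map(zp, rng.permutation(flag)) >= obs
        ps.append((1 + null_ge) / (1 + n_permutations))
        maps.append(obs)
        ns.append(len(treated))
    p = np.array(ps)
    return PerturbationStats(
        conditions=list(conditions),
        map_scores=np.array(maps),
        p_values=p,
        q_values=_bh_adjust(p),
        n_treated=np.array(ns),
        n_control=int(len(ctrl)),
        n_permutations=int(n_permutations),
        meta={"similarity": "cosine", "p_convention": "one-sided, add-one"},
    )
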