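"""Synthetic study data: nuclei-shaped containers, rule-based sphere
packing, rendered punctate intensity volumes and multi-piece blob
segmentations.

The packing rules mirror gradient-based packing of spheres inside a
nuclear mesh: ``random`` places points uniformly; ``planar`` biases
points away from a plane through the centroid (normal at 0°, 45° or 90°
about the z-axis); ``radial`` biases toward the centroid; ``surface``
biases toward the nuclear boundary. Containers are star-convex
"nucleus-like" meshes: triaxial ellipsoids with a seeded low-order
radial perturbation. All coordinates are voxel units with the origin at
the nucleus centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh

from .geometry import point_mesh_distance, voxelize_mesh
from .types import (
    InvalidInputError,
    LabeledPointCloud,
    PackingCapacityError,
    PlacementError,
    VolumeImage,
)

__all__ = [
    "NuclearShape",
    "PackingRuleSpec",
    "PolymorphicShapeSpec",
    "make_synthetic_nucleus",
    "pack_spheres",
    "render_punctate_volume",
    "make_multipiece_volume",
    "generate_rule_dataset",
    "RULES",
    "PLANE_NORMALS",
]

RULES = ("random", "planar", "radial", "surface")

# plane normals for the planar rule; the container's longest axis is y
PLANE_NORMALS = {
    0: np.array([0.0, 0.0, 1.0]),
    45: np.array([0.0, 1.0 / np.sqrt(2.0), 1.0 / np.sqrt(2.0)]),
    90: np.array([0.0, 1.0, 0.0]),
}


@dataclass
class NuclearShape:
    """A star-convex nuclear container.

    The mesh is watertight and centered on the origin; ``mask`` is its
    voxelization on a grid whose center voxel is the origin;
    ``centroid`` is that grid center in voxel indices. The analytic
    radial function (``radius_of``) makes inside tests and radial
    statistics cheap and exact for the generated family.
    """

    mesh: trimesh.Trimesh
    mask: VolumeImage
    centroid: np.ndarray
    principal_axes: np.ndarray
    meta: dict = field(default_factory=dict)
    _radial: Optional[dict] = None

    def radius_of(self, directions: np.ndarray) -> np.ndarray:
        """Boundary distance from the centroid along unit directions."""
        if self._radial is None:
            raise InvalidInputError("nucleus lacks an analytic radial function")
        u = np.atleast_2d(directions)
        p = self._radial
        if "rotation" in p:
            u = u @ p["rotation"]  # evaluate the base shape in its own frame
        ell = 1.0 / np.sqrt(np.sum((u / p["axes"]) ** 2, axis=1))
        return ell * (1.0 + p["bumpiness"] * _bump(u, p["dirs"], p["coeffs"]))

    def rotated(self, R: np.ndarray) -> "NuclearShape":
        """The same container rigidly rotated by ``R`` (mesh, analytic
        radial function and mask all consistent with the new frame)."""
        if self._radial is None:
            raise InvalidInputError("nucleus lacks an analytic radial function")
        R = np.asarray(R, dtype=float)
        p = dict(self._radial)
        p["rotation"] = R @ p.get("rotation", np.eye(3))
        mesh = trimesh.Trimesh(
            vertices=np.asarray(self.mesh.vertices) @ R.T,
            faces=self.mesh.faces.copy(),
            process=False,
        )
        out = NuclearShape(
            mesh=mesh,
            mask=self.mask,  # replaced below
            centroid=self.centroid.copy(),
            principal_axes=R @ self.principal_axes,
            meta=dict(self.meta),
            _radial=p,
        )
        g = self.mask.data.shape[0]
        center = np.full(3, (g - 1) / 2.0)
        idx = np.indices((g, g, g)).reshape(3, -1).T - center
        rho = np.linalg.norm(idx, axis=1)
        udir = idx / np.maximum(rho[:, None], 1e-12)
        udir[rho < 1e-9] = (1.0, 0.0, 0.0)
        mask = (rho <= out.radius_of(udir)).reshape(g, g, g).astype(np.uint8)
        out.mask = VolumeImage(mask, role="mask")
        return out

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Inside test with a radial safety margin (voxel units)."""
        pts = np.atleast_2d(points)
        r = np.linalg.norm(pts, axis=1)
        u = pts / np.maximum(r[:, None], 1e-12)
        return r <= self.radius_of(u) - margin


def _bump(u: np.ndarray, dirs: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Smooth seeded radial perturbation, normalized to max |.| = 1.

    Sum of second-order Legendre terms P2(u . d_j) over a few random
    directions; the normalizer is stored in coeffs (pre-divided).
    """
    t = u @ dirs.T  # (P, J)
    p2 = 0.5 * (3.0 * t**2 - 1.0)
    return p2 @ coeffs


def make_synthetic_nucleus(
    seed: int,
    mean_radius: float = 16.0,
    bumpiness: float = 0.15,
    anisotropy=(1.0, 1.25, 0.85),
    subdivisions: int = 3,
    grid: Optional[int] = None,
) -> NuclearShape:
    """Generate a watertight, star-convex synthetic nucleus.

    ``anisotropy`` scales the three semi-axes (y longest by default, a
    flattened-ellipsoid habit); ``bumpiness`` in [0, 1) adds a seeded
    low-order radial perturbation. ``bumpiness=0`` gives an exact
    triaxial ellipsoid. Deterministic given ``seed``.
    """
    if mean_radius <= 0:
        raise InvalidInputError("mean_radius must be positive")
    if not (0.0 <= bumpiness < 1.0):
        raise InvalidInputError("bumpiness must be in [0, 1)")
    anisotropy = np.asarray(anisotropy, dtype=float)
    if anisotropy.shape != (3,) or np.any(anisotropy <= 0):
        raise InvalidInputError("anisotropy must be three positive scales")

    rng = np.random.default_rng(seed)
    axes = mean_radius * anisotropy
    n_terms = 4
    dirs = rng.standard_normal((n_terms, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    coeffs = rng.standard_normal(n_terms)

    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = np.asarray(base.vertices, dtype=float)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    # normalize the perturbation so its max magnitude over directions is 1
    raw = _bump(u, dirs, coeffs)
    scale = np.abs(raw).max()
    coeffs = coeffs / scale if scale > 0 else coeffs

    radial = {"axes": axes, "bumpiness": float(bumpiness), "dirs": dirs, "coeffs": coeffs}
    ell = 1.0 / np.sqrt(np.sum((u / axes) ** 2, axis=1))
    r = ell * (1.0 + bumpiness * _bump(u, dirs, coeffs))
    mesh = trimesh.Trimesh(vertices=u * r[:, None], faces=base.faces, process=False)

    max_r = axes.max() * (1.0 + bumpiness)
    g = int(grid) if grid is not None else 2 * int(np.ceil(max_r)) + 9
    center = np.full(3, (g - 1) / 2.0)
    idx = np.indices((g, g, g)).reshape(3, -1).T - center
    rho = np.linalg.norm(idx, axis=1)
    udir = idx / np.maximum(rho[:, None], 1e-12)
    udir[rho < 1e-9] = (1.0, 0.0, 0.0)  # grid center: any direction works
    ell_g = 1.0 / np.sqrt(np.sum((udir / axes) ** 2, axis=1))
    rg = ell_g * (1.0 + bumpiness * _bump(udir, dirs, coeffs))
    mask = (rho <= rg).reshape(g, g, g).astype(np.uint8)

    cov = np.cov(mesh.vertices.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    principal_axes = evecs[:, order]

    return NuclearShape(
        mesh=mesh,
        mask=VolumeImage(mask, role="mask"),
        centroid=center,
        principal_axes=principal_axes,
        meta={"seed": int(seed), "mean_radius": float(mean_radius),
              "bumpiness": float(bumpiness), "anisotropy": anisotropy.tolist()},
        _radial=radial,
    )


@dataclass
class PackingRuleSpec:
    """Parameters of one packing rule.

    ``bias_strength`` is the single tunable knob of the gradient rules:
    acceptance weight (d/d_max)^bias for planar, exp(-bias r/r_max) for
    radial, exp(-bias d_surf/r_max) for surface.
    """

    rule: str
    plane_angle: Optional[int] = None
    n_spheres: int = 256
    sphere_radius: float = 1.0
    bias_strength: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.rule not in RULES:
            raise InvalidInputError(f"unknown rule {self.rule!r}; expected {RULES}")
        if self.rule == "planar":
            if self.plane_angle not in PLANE_NORMALS:
                raise InvalidInputError(
                    "planar rule requires plane_angle in {0, 45, 90}"
                )
        elif self.plane_angle is not None:
            raise InvalidInputError("plane_angle only applies to the planar rule")
        if self.n_spheres < 0:
            raise InvalidInputError("n_spheres must be >= 0")
        if self.bias_strength <= 0:
            raise InvalidInputError("bias_strength must be positive")

    @property
    def label(self) -> str:
        if self.rule == "planar":
            return f"planar{self.plane_angle}"
        return self.rule

    def plane_normal(self) -> Optional[np.ndarray]:
        if self.rule != "planar":
            return None
        return PLANE_NORMALS[self.plane_angle].copy()


def pack_spheres(nucleus: NuclearShape, spec: PackingRuleSpec) -> LabeledPointCloud:
    """Pack non-overlapping spheres inside a nucleus under one rule.

    Dart throwing with a minimum center distance of two sphere radii;
    candidates are drawn uniformly inside the container and thinned by
    the rule's acceptance weight. Every returned centroid is strictly
    inside the mesh with exact clearance >= sphere_radius, verified with
    exact point-mesh distances. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    meta = {"rule": spec.label, "seed": int(spec.seed),
            "sphere_radius": float(spec.sphere_radius)}
    normal = spec.plane_normal()
    if normal is not None:
        meta["plane_normal"] = normal.tolist()
    if spec.n_spheres == 0:
        return LabeledPointCloud(points=np.empty((0, 3)), meta=meta)

    axes = nucleus._radial["axes"] if nucleus._radial else None
    max_r = (
        float(axes.max()) * (1.0 + nucleus._radial["bumpiness"])
        if axes is not None
        else float(np.abs(nucleus.mesh.vertices).max())
    )
    verts = np.asarray(nucleus.mesh.vertices)
    d_plane_max = float(np.abs(verts @ normal).max()) if normal is not None else None
    # conservative radial margin: radial gap >= radius / cos(max tilt)
    normals = np.asarray(nucleus.mesh.vertex_normals)
    udir = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    gamma = float(np.clip(np.einsum("ij,ij->i", normals, udir).min(), 0.2, 1.0))
    margin = spec.sphere_radius / gamma

    placed = np.empty((0, 3))
    attempts = 0
    max_attempts = max(10 * spec.n_spheres, 100)
    batch = max(4 * spec.n_spheres, 256)
    while len(placed) < spec.n_spheres and attempts < max_attempts:
        cand = rng.uniform(-max_r, max_r, size=(batch, 3))
        rho = np.linalg.norm(cand, axis=1)
        u = cand / np.maximum(rho[:, None], 1e-12)
        rb = nucleus.radius_of(u)
        cand = cand[rho <= rb - margin]
        rho = np.linalg.norm(cand, axis=1)
        if len(cand) == 0:
            attempts += 1
            continue
        w = _rule_weights(spec, cand, rho, nucleus, max_r, d_plane_max)
        keep = rng.uniform(size=len(cand)) < w
        cand = cand[keep]
        if len(cand) == 0:
            attempts += batch // 64  # burned proposals still count a little
            continue
        # exact clearance for the thinned candidates (cheap at this stage)
        clear = point_mesh_distance(nucleus.mesh, cand) >= spec.sphere_radius
        inside = nucleus.contains(cand)
        cand = cand[clear & inside]
        for p in cand:
            attempts += 1
            if len(placed) >= spec.n_spheres or attempts >= max_attempts:
                break
            if len(placed) and np.min(np.linalg.norm(placed - p, axis=1)) < 2 * spec.sphere_radius:
                continue
            placed = np.vstack([placed, p])
    if len(placed) < spec.n_spheres:
        raise PackingCapacityError(
            f"placed only {len(placed)} of {spec.n_spheres} spheres "
            f"after {attempts} attempts (rule={spec.label})",
            placed=len(placed),
        )
    return LabeledPointCloud(points=placed, meta=meta)


def _rule_weights(spec, cand, rho, nucleus, max_r, d_plane_max) -> np.ndarray:
    if spec.rule == "random":
        return np.ones(len(cand))
    if spec.rule == "planar":
        d = np.abs(cand @ spec.plane_normal())
        return (d / d_plane_max) ** spec.bias_strength
    if spec.rule == "radial":
        return np.exp(-spec.bias_strength * rho / max_r)
    # surface: radial gap to the boundary as the distance proxy
    u = cand / np.maximum(rho[:, None], 1e-12)
    gap = nucleus.radius_of(u) - rho
    return np.exp(-spec.bias_strength * gap / max_r)


def render_punctate_volume(
    points: LabeledPointCloud,
    nucleus: NuclearShape,
    spot_sigma: float = 1.0,
    noise_sd: float = 0.0,
    amplitude: float = 1.0,
    seed: int = 0,
) -> VolumeImage:
    """Render a punctate intensity volume on the nucleus mask grid.

    Each point becomes an isotropic Gaussian spot (discrete kernel
    normalized to total mass ``amplitude``); Gaussian background noise
    of ``noise_sd`` is added and the result is masked by the nucleus.
    An empty point set yields a background-only volume.
    """
    mask = nucleus.mask.data.astype(float)
    g = mask.shape[0]
    vol = np.zeros_like(mask)
    center = nucleus.centroid
    pts = np.atleast_2d(points.points) + center if len(points) else np.empty((0, 3))
    if len(pts) and not np.all((pts >= 0) & (pts <= g - 1)):
        raise InvalidInputError("points fall outside the nucleus grid")
    half = max(int(np.ceil(4 * spot_sigma)), 1)
    offs = np.arange(-half, half + 1)
    for p in pts:
        v0 = np.round(p).astype(int)
        ix = np.clip(v0[0] + offs, 0, g - 1)
        iy = np.clip(v0[1] + offs, 0, g - 1)
        iz = np.clip(v0[2] + offs, 0, g - 1)
        if spot_sigma > 0:
            dx = (v0[0] + offs - p[0])[:, None, None]
            dy = (v0[1] + offs - p[1])[None, :, None]
            dz = (v0[2] + offs - p[2])[None, None, :]
            k = np.exp(-(dx**2 + dy**2 + dz**2) / (2 * spot_sigma**2))
        else:
            k = np.zeros((len(offs),) * 3)
            k[half, half, half] = 1.0
        k = k / k.sum() * amplitude
        vol[np.ix_(ix, iy, iz)] += k
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
    vol *= mask
    return VolumeImage(vol, role="intensity", meta={"spot_sigma": spot_sigma,
                                                    "noise_sd": noise_sd,
                                                    "seed": int(seed)})


@dataclass
class PolymorphicShapeSpec:
    """Multi-piece blob layout: ellipsoidal pieces with controlled
    count, size range, spacing and elongation."""

    n_pieces: int = 3
    piece_scale_range: tuple = (3.0, 6.0)
    spacing: float = 3.0
    elongation: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_pieces < 1:
            raise InvalidInputError("n_pieces must be >= 1")
        lo, hi = self.piece_scale_range
        if lo <= 0 or hi < lo:
            raise InvalidInputError("piece_scale_range must be positive and ordered")
        if self.spacing < 0:
            raise InvalidInputError("spacing must be >= 0")


def make_multipiece_volume(spec: PolymorphicShapeSpec, grid=(64, 64, 64)) -> VolumeImage:
    """Binary union of ``n_pieces`` ellipsoidal blobs on a voxel grid.

    Piece centers are dart-thrown so that center separations exceed the
    sum of the pieces' largest semi-axes plus ``spacing``, which keeps
    the 26-connected component count equal to ``n_pieces`` (verified
    before returning). Deterministic given ``spec.seed``.
    """
    from scipy.ndimage import label

    grid = tuple(int(x) for x in grid)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.piece_scale_range
    max_semi = hi * spec.elongation
    if any(2 * max_semi >= gdim for gdim in grid):
        raise InvalidInputError("pieces cannot fit inside the grid")

    for _ in range(50):  # full restarts if labelling disagrees
        semis = []
        rots = []
        for _ in range(spec.n_pieces):
            a = rng.uniform(lo, hi)
            semi = np.array([a * spec.elongation, a, a * rng.uniform(0.7, 1.0)])
            semis.append(semi)
            rots.append(_random_rotation(rng))
        radii = [s.max() for s in semis]
        centers = _place_centers(rng, grid, radii, spec.spacing)
        if centers is None:
            continue
        vol = np.zeros(grid, dtype=np.uint8)
        idx = np.indices(grid).reshape(3, -1).T.astype(float)
        for c, semi, R in zip(centers, semis, rots):
            d = (idx - c) @ R
            inside = np.sum((d / semi) ** 2, axis=1) <= 1.0
            vol.reshape(-1)[inside] = 1
        n_comp = label(vol, structure=np.ones((3, 3, 3)))[1]
        if n_comp == spec.n_pieces:
            return VolumeImage(vol, role="mask", meta={"seed": int(spec.seed),
                                                       "n_pieces": spec.n_pieces})
    raise PlacementError(
        f"could not place {spec.n_pieces} pieces with spacing {spec.spacing} "
        f"in grid {grid}"
    )


def _place_centers(rng, grid, radii, spacing):
    centers = []
    for r in radii:
        ok = False
        for _ in range(200):
            c = np.array([rng.uniform(r + 1, g - r - 2) for g in grid])
            if all(
                np.linalg.norm(c - c2) >= r + r2 + spacing
                for c2, r2 in zip(centers, radii)
            ):
                centers.append(c)
                ok = True
                break
        if not ok:
            return None
    return centers


def _random_rotation(rng) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


ALL_RULE_SPECS = (
    ("random", None),
    ("planar", 0),
    ("planar", 45),
    ("planar", 90),
    ("radial", None),
    ("surface", None),
)


def generate_rule_dataset(
    n_nuclei: int,
    rules=ALL_RULE_SPECS,
    n_spheres: int = 256,
    seed: int = 0,
    mean_radius: float = 16.0,
    bumpiness: float = 0.15,
) -> list[LabeledPointCloud]:
    """The six-rule study dataset: each nucleus packed under every rule.

    Returns ``n_nuclei * len(rules)`` clouds; each cloud's ``meta``
    carries its rule label, nucleus index and seed.
    """
    out = []
    for i in range(n_nuclei):
        nuc = make_synthetic_nucleus(seed=seed + i, mean_radius=mean_radius,
                                     bumpiness=bumpiness)
        for j, (rule, angle) in enumerate(rules):
            spec = PackingRuleSpec(
                rule=rule, plane_angle=angle, n_spheres=n_spheres,
                seed=seed * 100003 + i * 101 + j,
            )
            pc = pack_spheres(nuc, spec)
            pc.meta["nucleus"] = i
            out.append(pc)
    return out
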