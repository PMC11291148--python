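"""Volumes, point-cloud tables, dataset manifests, splits and run
directories.

Formats: TIFF for volumes (32-bit float for intensity/SDF, 8-bit for
masks), CSV for point clouds (columns x, y, z[, s] plus metadata
columns) and manifests, JSON/YAML for configs, ``.npz`` for embeddings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import InvalidInputError, LabeledPointCloud, VolumeImage

__all__ = [
    "read_volume",
    "write_volume",
    "write_pointcloud_csv",
    "read_pointcloud_csv",
    "DatasetManifest",
    "split_indices",
    "make_splits",
    "RunDirectory",
]

SPLITS = ("train", "val", "test")


def read_volume(path, role: str = "intensity") -> VolumeImage:
    """Read a 3D single-channel TIFF volume with the given semantic role.

    Voxel spacing is taken from TIFF resolution metadata when present,
    else unit spacing (recorded in ``meta['spacing_assumed']``). Masks
    with values {0, 255} (or any two-level coding) are normalized to
    {0, 1} and the normalization noted in ``meta``.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"volume file not found: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        spacing = _spacing_from_tiff(tf)
    if data.ndim != 3:
        raise InvalidInputError(
            f"unsupported axis layout: expected 3D single-channel volume, "
            f"got shape {data.shape} from {path}"
        )
    meta = {"path": str(path)}
    if spacing is None:
        spacing = (1.0, 1.0, 1.0)
        meta["spacing_assumed"] = True
    if role == "mask":
        vals = np.unique(data)
        if len(vals) > 2:
            raise InvalidInputError(f"mask volume {path} has {len(vals)} levels")
        if not np.all(np.isin(vals, (0, 1))):
            data = (data == vals.max()).astype(np.uint8)
            meta["binarized_from"] = [float(v) for v in vals]
    return VolumeImage(data=data, role=role, spacing=tuple(spacing), meta=meta)


def _spacing_from_tiff(tf) -> tuple | None:
    try:
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres and yres and xres.value[0]:
            sx = xres.value[1] / xres.value[0]
            sy = yres.value[1] / yres.value[0]
            return (1.0, sy, sx)
    except Exception:
        pass
    return None


def write_volume(path, vol: VolumeImage) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.data
    dtype = np.uint8 if vol.role == "mask" else np.float32
    tifffile.imwrite(str(path), data.astype(dtype))


def write_pointcloud_csv(path, pc: LabeledPointCloud) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = {"x": pc.points[:, 0], "y": pc.points[:, 1], "z": pc.points[:, 2]}
    if pc.scalars is not None:
        cols["s"] = pc.scalars
    df = pd.DataFrame(cols)
    for key in ("rule", "seed"):
        if key in pc.meta:
            df[key] = pc.meta[key]
    # %.17g guarantees float64 values survive the text round trip bitwise
    df.to_csv(path, index=False, float_format="%.17g")


def read_pointcloud_csv(path) -> LabeledPointCloud:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"point cloud file not found: {path}")
    # round_trip parsing: exact float64 recovery of %.17g-formatted values
    df = pd.read_csv(path, float_precision="round_trip")
    for c in ("x", "y", "z"):
        if c not in df:
            raise InvalidInputError(f"{path} lacks required column {c!r}")
    pts = df[["x", "y", "z"]].to_numpy(float)
    scal = df["s"].to_numpy(float) if "s" in df else None
    meta = {}
    for key in ("rule", "seed"):
        if key in df:
            vals = df[key].unique()
            if len(vals) == 1:
                meta[key] = vals[0].item() if hasattr(vals[0], "item") else vals[0]
    return LabeledPointCloud(points=pts, scalars=scal, meta=meta)


@dataclass
class DatasetManifest:
    """Sample table: id, file paths, labels, split assignment, volumes.

    A thin wrapper over a pandas DataFrame with an ``id`` column
    (unique) and whatever path/label columns the pipeline stage
    produced.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if len(self.table):
            if "id" not in self.table.columns:
                raise InvalidInputError("manifest requires an 'id' column")
            if self.table["id"].duplicated().any():
                raise InvalidInputError("manifest ids must be unique")

    def __len__(self):
        return len(self.table)

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False)

    @classmethod
    def load(cls, path, check_paths: bool = True) -> "DatasetManifest":
        path = Path(path)
        if not path.exists():
            raise InvalidInputError(f"manifest not found: {path}")
        table = pd.read_csv(path)
        m = cls(table=table)
        if check_paths:
            for col in table.columns:
                if not col.endswith("_path"):
                    continue
                for p in table[col].dropna():
                    if not Path(p).exists():
                        raise InvalidInputError(f"manifest references missing file {p}")
        return m


def split_indices(
    labels, fractions=(0.70, 0.15, 0.15), seed: int = 0
) -> np.ndarray:
    """Assign each sample to train/val/test, stratified by ``labels``.

    Per stratum the counts use largest-remainder rounding, so every
    stratum's fractions are within one sample of the targets. Labels may
    be any array; pass a constant array for unstratified splits.
    Returns an array of strings in {train, val, test}.
    """
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InvalidInputError("split fractions must sum to 1")
    labels = np.asarray(labels)
    n = len(labels)
    rng = np.random.default_rng(seed)
    out = np.empty(n, dtype=object)
    for stratum in np.unique(labels):
        idx = np.flatnonzero(labels == stratum)
        if len(idx) < 3:
            raise InvalidInputError(
                f"stratum {stratum!r} has only {len(idx)} samples (< 3)"
            )
        idx = idx[rng.permutation(len(idx))]
        raw = np.array(fractions) * len(idx)
        counts = np.floor(raw).astype(int)
        rem = len(idx) - counts.sum()
        order = np.argsort(-(raw - counts), kind="stable")
        for j in range(rem):
            counts[order[j]] += 1
        pos = 0
        for split, c in zip(SPLITS, counts):
            out[idx[pos : pos + c]] = split
            pos += c
    return out.astype(str)


def make_splits(
    manifest: DatasetManifest,
    fractions=(0.70, 0.15, 0.15),
    stratify_by: str | None = None,
    seed: int = 0,
) -> DatasetManifest:
    """Return a manifest copy with a ``split`` column added."""
    table = manifest.table.copy()
    if stratify_by is not None:
        if stratify_by not in table.columns:
            raise InvalidInputError(f"stratify key {stratify_by!r} not in manifest")
        labels = table[stratify_by].to_numpy()
    else:
        labels = np.zeros(len(table), dtype=int)
    table["split"] = split_indices(labels, fractions=fractions, seed=seed)
    return DatasetManifest(table=table)


class RunDirectory:
    """A self-contained, reproducible run: resolved config, master seed,
    package version and a line-oriented log. Per-operation seeds derive
    from the master seed by stable hashing of the operation name."""

    def __init__(self, path, config: dict | None = None, seed: int = 0):
        self.path = Path(path)
        self.path.mkdir(parents=True, exist_ok=True)
        self.seed = int(seed)
        self.config = dict(config or {})
        from . import __version__

        resolved = {"seed": self.seed, "version": __version__, "config": self.config}
        (self.path / "run.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunDirectory":
        path = Path(path)
        resolved = yaml.safe_load((path / "run.yaml").read_text())
        run = cls.__new__(cls)
        run.path = path
        run.seed = int(resolved["seed"])
        run.config = resolved.get("config", {})
        return run

    def op_seed(self, op_name: str) -> int:
        """Deterministic per-operation seed below 2**31."""
        h = 2166136261
        for ch in f"{self.seed}:{op_name}".encode():
            h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
        return h % (2**31)

    def log(self, message: str) -> None:
        with open(self.path / "run.log", "a") as fh:
            fh.write(message.rstrip() + "\n")

    def save_json(self, name: str, obj) -> None:
        (self.path / name).write_text(json.dumps(obj, indent=2, default=float))
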