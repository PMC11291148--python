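"""From a multi-piece segmentation to SDF training data.

Builds a 3-piece synthetic structure, meshes it, scales it into the
32-voxel working cube, computes the clipped signed-distance volume, and
samples the surface/query clouds an implicit SDF decoder trains on.
Also shows the piece features used as probe targets.
"""

from morphrep.benchmark import piece_features
from morphrep.polymorphic import (
    mesh_to_sdf_volume,
    sample_shape_pointclouds,
    segmentation_to_mesh,
)
from morphrep.synth import PolymorphicShapeSpec, make_multipiece_volume

seg = make_multipiece_volume(PolymorphicShapeSpec(n_pieces=3, seed=7))
print(f"segmentation {seg.shape}, {int(seg.data.sum())} occupied voxels")

row = piece_features(seg.data)
print(f"pieces: {row.piece_count} (class {row.piece_class}), "
      f"mean volume {row.volume_mean:.0f} voxels^3, "
      f"mean centroid distance {row.centroid_distance_mean:.1f} voxels")

mesh, scale = segmentation_to_mesh(seg, scale_mode="per_cell")
print(f"mesh: {len(mesh.faces)} faces, watertight={mesh.is_watertight}, "
      f"scale factor {scale:.3f} into the 32-voxel cube")

sdf = mesh_to_sdf_volume(mesh)
inside = (sdf.data < 0).mean()
print(f"SDF grid {sdf.shape}, clipped to [-2, 2], {inside:.1%} of voxels inside")

samples = sample_shape_pointclouds(mesh, sdf, seed=11)
print(f"surface cloud {samples.surface_points.points.shape}, "
      f"query cloud {samples.query_points.points.shape} "
      f"carrying SDF values in "
      f"[{samples.query_points.scalars.min():.1f}, "
      f"{samples.query_points.scalars.max():.1f}]")
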