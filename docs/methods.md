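# Methods

This document records what the package computes, the modelling
assumptions behind each stage, the default parameters and why they were
chosen, and the numerical decisions that matter for reproducing
results. The API reference lives in the docstrings; this is the
narrative layer above them.

## Problem setting

Subcellular structures imaged in 3D come in two broad morphologies.
*Punctate* structures (centrioles, speckle-like bodies, foci) are well
described as a set of points with optional per-point intensities.
*Polymorphic* structures (nucleoli, granular bodies) have genuine
shape, best described by a surface and its signed-distance field (SDF).
The package learns compact vector representations of both, with a hard
architectural guarantee: the representation of a structure must not
depend on how the cell happened to be oriented under the microscope.

Because real microscopy volumes are large and annotation-free ground
truth is scarce, the package ships a synthetic data generator whose
packing rules play the role of known biological ground truth: if a
representation cannot recover rules it was never shown, it has lost the
relevant spatial signal. The generator's defaults are the study
conditions used by the tests and the acceptance script.

## Synthetic data (`morphrep.synth`)

**Nuclear shapes.** `make_synthetic_nucleus` builds a star-convex
nuclear envelope: a unit sphere whose radius is modulated by a small
number of smooth directional bumps (mean radius 16 voxel units). Star
convexity keeps inside/outside tests and centroid-relative statistics
cheap and exact; it does not attempt to model lobulated or toroidal
nuclei.

**Packing rules.** `pack_spheres` places `n_spheres` unit spheres
inside the envelope by rejection sampling against rule-specific
weights:

- `random` — uniform in the nuclear volume;
- `radial` — density decreasing with distance from the centroid;
- `surface` — density increasing toward the envelope;
- `planar` (at 0°, 45°, 90°) — depleted near a central plane.

Placement enforces non-overlap; the attempt budget is `10 × n_spheres`,
after which `PackingCapacityError` reports the achieved count. The six
specs in `ALL_RULE_SPECS` define the rule-recovery study;
`generate_rule_dataset(n)` yields `n` nuclei per rule.

What the generator does emulate: centroid- and surface-referenced
density gradients, anisotropic depletion, per-cell shape variability,
rendering noise. What it does not: chromatin texture, rule mixtures
within one cell, imaging point-spread anisotropy along z, or
inter-structure interactions.

**Polymorphic shapes.** `make_multipiece_volume` draws 1–N
non-touching ellipsoidal pieces in a 64³ voxel grid, giving
segmentations with a known piece count and piece geometry — the probe
targets for shape representations.

## Preprocessing

**Punctate (`morphrep.punctate`).** Intensity volumes are converted to
sampling densities by an exponential reweighting
`exp(λ·skewness · intensity)` inside the nuclear mask: high-skewness
(focus-dominated) images concentrate sampling mass on foci, flat images
sample almost uniformly. Point clouds are drawn from that density
(defaults: 20 480-point dense clouds, 2 048-point sparse clouds, each
point carrying its source intensity as a scalar channel); clouds
smaller than the target size are upsampled by Gaussian jitter of
existing points.

**Polymorphic (`morphrep.polymorphic`).** Segmentation → marching-cubes
mesh → scaled into a 32-voxel working cube → clipped SDF grid (positive
outside, negative inside, clipped to ±2 voxel units so the loss budget
concentrates near the surface) → surface point clouds
(area-proportional sampling) plus SDF-labelled query points for
implicit decoder training. Inside/outside classification uses
generalized winding numbers and exact point–triangle distances
(`morphrep.geometry`), which are robust for the watertight meshes
marching cubes produces.

## Models (`morphrep.nn`)

**Encoder.** A dynamic graph CNN over k-nearest-neighbor graphs whose
features are *vector neurons*: each channel is a 3-vector, and every
layer (linear maps, the vector analogue of ReLU, neighborhood pooling)
commutes with rotation. Consequently the latent `V ∈ R^{d×3}` satisfies
`V(Rx) = V(x) Rᵀ` to machine precision by construction, not by
augmentation. The invariant embedding is `z = ||V||` row-wise; a
rotation frame is recovered from `V` by Gram–Schmidt on two latent rows
plus a cross product. A classical scalar DGCNN with the same topology
is provided as the non-equivariant control.

*Pooling.* Point-wise vector features are pooled to one latent by
taking the mean vector per channel and rescaling it to the mean of the
per-point channel norms. Averaging raw vectors alone cancels
incoherently oriented contributions and discards density information;
the rescaling is an invariant gain, so equivariance is unaffected while
`z` retains non-cancelling per-point statistics.

*Scalar channel.* Optional per-point scalars are processed in a
parallel invariant stream and fused as per-channel gains on the vector
features — a scalar has no orientation, so this is the only fusion that
preserves exact equivariance.

**Decoders.** For punctate clouds, a folding decoder: a fixed template
(2 048-point plane by default, sphere optional) is deformed by two MLP
folds conditioned on `z`; folds are residual, so zero fold weights
return the template unchanged, and the canonical reconstruction is
re-oriented by the recovered rotation frame. For polymorphic shapes, an
implicit decoder maps rotation-invariant query features (inner products
`⟨V, q⟩`, the query norm, and `z`) to an SDF value.

**Input scale.** Clouds are divided by a single dataset-wide constant,
`ModelConfig.input_scale`, set by the trainer to twice the mean
point-norm of the training split so that scaled clouds have mean radius
0.5 — the scale of the folding templates. One constant serves the whole
dataset, so relative size differences between samples remain
informative; reconstructions and predicted SDF values are mapped back
to original units. Without this the decoder must learn a large
amplification out of its unit-scale template, which dominates early
training.

**Losses.** Chamfer distance, or earth mover's distance (EMD): exact
Hungarian assignment up to 512 points, log-domain Sinkhorn with
ε = 0.01 above (relative error versus the exact value is on the order
of 10 % at that regularization; the study clouds stay within the exact
regime). EMD is the study loss for rule recovery: chamfer's
many-to-one matching under-constrains point density, which is exactly
the signal the packing rules carry. Implicit models train with L1 loss
on clipped SDF values.

**Optimization.** The gradients come from a compact reverse-mode
automatic-differentiation engine written for these models
(`morphrep.nn.autodiff`); Adam with the standard moment defaults.
Training is deterministic given the config seeds: splits, batch order,
jitter, and weight initialization all derive from them.

## Study configuration

The desk-scale rule-recovery study (also the heart of
`scripts/acceptance.py`) uses: 6 rules × 60 nuclei × 256 points,
latent 32, hidden width 32, 3 edge-conv blocks, k = 10, 256-point
template, EMD loss, Adam at 1e-3, batch 8, 20 epochs, stratified
70/15/15 splits. On one CPU this trains in about six minutes and the
linear probe recovers the three rotation-independent rules at ≈0.99 and
all six rules at ≈0.93 (chance 1/6; the three planar rules differ only
by plane orientation, which a rotation-invariant embedding deliberately
cannot fully separate). Full-scale defaults (latent 256/512,
k = 20, 6 blocks) are the `ModelConfig` constructors' defaults.

## Benchmarks (`morphrep.benchmark`)

- `rotation_invariance_error` — mean normalized embedding displacement
  under the four quarter-turns about z (the fourth is the identity and
  contributes zero; it only rescales the average uniformly).
- `reconstruction_error` — chamfer for folding models; Jaccard overlap
  of the reconstructed mask for implicit models.
- `evolution_energy` / `interpolation_distance` — smoothness of the
  latent space along pairwise interpolations; with a metric obeying the
  triangle inequality the energy is ≥ 1 by construction.
- `compactness` — intrinsic dimension via the two-NN maximum-likelihood
  estimator over a k-range.
- `probe_classification` / `probe_regression` — cross-validated linear
  probes (logistic / ridge) of labels and piece features.
- `benchmark_report` — multi-model table with a z-scored view where
  error-like columns are sign-flipped so larger is always better.

## Analysis (`morphrep.analysis`)

- PCA latent walks with decoding or nearest-real-example mapping.
- Archetypal analysis by alternating Frank–Wolfe updates (furthest-sum
  initialization). The iterate converges sublinearly toward interior
  simplex weights, so residuals plateau around 1e-4 relative even when
  the planted vertices themselves are recovered to high accuracy;
  tolerance choices in callers should be relative to the total sum of
  squares.
- Volume-binned profiles with fixed published edges
  (390/533/676/818 μm³) and 2.5–97.5 % volume clipping.
- Perturbation statistics: per-condition retrieval mAP of treated cells
  against pooled controls under cosine similarity, permutation p-values
  with the add-one convention `p = (1 + #{null ≥ obs}) / (1 + n_perm)`,
  Benjamini–Hochberg q-values. Note that cosine retrieval saturates
  (mAP = 1) only when conditions are *angularly* disjoint, which is a
  stronger requirement than Euclidean separation.

## Reproducibility

Pipelines run inside a `RunDirectory`: the resolved config, package
version and master seed are written to `run.yaml`, and every operation
derives its own seed from the master seed by stable string hashing
(FNV-1a, reduced below 2³¹). Point-cloud CSVs are written with
`%.17g` formatting and read back with round-trip float parsing, so text
artifacts reproduce float64 values bitwise; volumes round-trip through
TIFF losslessly. Re-running a saved run directory therefore reproduces
its artifacts byte-for-byte.

## Limitations

- The synthetic generator is a rule-based caricature; none of the
  claims here transfer automatically to real microscopy data.
- The autodiff engine is minimal and CPU-only; study scales are sized
  for a single CPU, and full-scale configs are untested at their
  full size in this environment.
- Sinkhorn EMD above 512 points is a biased approximation; comparisons
  should not mix exact and regularized regimes.
- Rotation invariance is exact about any axis through the origin;
  clouds are assumed centered (the generator centers them), and
  translation invariance is not architectural.
- The planar packing rules are only partially identifiable from a
  rotation-invariant embedding, by design.
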