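# Methods

`plcpd` registers two 3D ultrasound acquisitions of the fetal head by
aligning weighted point clouds extracted from the cranium. This note
documents the models and procedures in each stage, the defaults and why
they were chosen, and what the synthetic phantom does and does not show.

## Problem setting

Second/third-trimester fetal ultrasound suffers from multiplicative
speckle and acoustic occlusion: once the cranium calcifies it reflects and
absorbs the beam non-uniformly, so each acquisition (axial, coronal, …)
sees a different, incomplete part of the skull. Registering such pairs
enables growth monitoring, atlas-based segmentation and multi-view
compounding, but intensity-based registration fails on the non-shared
shadowed regions. The approach here is geometric: segment the cranium,
sample its inner and outer shell surfaces into a point cloud, attach to
every point the classifier's confidence that it really is cranium, and use
those confidences as non-uniform membership priors of a Gaussian-mixture
point-set registration (a weighted variant of coherent point drift).

## Confidence maps

Per-voxel signal reliability is modelled by a closed-form per-beam-line
recurrence: confidence starts at 1 at the transducer face and decays as

```
c(z) = c(z-1) · exp(-Δz · (μ + γ·ĝ(z)))
```

with `Δz` the voxel size along the beam (mm), `μ` the baseline attenuation
rate (default 0.02/mm), `γ` the shadow gain (default 0.5) and `ĝ` the
beam-direction gradient magnitude normalized to [0, 1] over the volume.
The normalization makes the map invariant to global affine intensity
rescaling. The model reproduces the two behaviours the pipeline needs —
monotone depth attenuation and darkening behind strong reflectors — and a
full random-walk confidence formulation could replace it behind the same
interface. The beam axis defaults to the volume's last axis. Weighting
multiplies intensities by confidence; the feature bank is computed on the
weighted volume with the raw intensity restored as the first feature plane,
so the classifier sees both.

## Cranium classification

Eight features per voxel: raw intensity; local variance, rank, entropy,
median and a Wiener-filtered intensity over a 9×9×9 window; a slice-wise 2D
Canny edge map (hysteresis thresholds at 0.1/0.2 of each slice's maximum
gradient magnitude, stored as 0/1); and the 6-neighbour discrete Laplacian.
Rank is the fraction of window voxels below the centre value (ties counted
half); rank and entropy are computed from 32-bin local intensity
histograms so the 9³ window stays tractable on full volumes.

The classifier is a random forest of T = 50 entropy-split trees
(max depth 12, minimum leaf 5). Each internal node draws a fresh candidate
set of ⌈√d⌉ = 3 feature indices crossed with 10 quantile thresholds of the
node's samples and keeps the candidate with the largest information gain
(base-2 entropy; the base does not affect the argmax). Leaves store the
empirical class histogram; the voxel posterior is the plain average of the
reached leaves' positive-class frequencies. Trees are grown on bootstrap
resamples; training voxels are a class-balanced random subsample of at
most 50 000 voxels per volume. None of these hyperparameters are intrinsic
to the method; tests cross-check held-out behaviour against an independent
random-forest implementation. Models serialize losslessly to JSON.

The posterior is binarized at 0.5 (ties to cranium) and reduced to the
largest 26-connected component, since the cranium is a single shell.

## Weighted point clouds

The cloud samples the segmented shell's surfaces: boundary voxels (mask
minus its one-voxel erosion) become vertices at their world-mm centres,
farthest-point subsampling reduces them to ~2000 points, and the classifier
posterior is sampled trilinearly at each vertex as its weight. Boundary
voxels of a shell mask cover both the inner and the outer cranial surface,
so vertex radii are bimodal by construction. A meshing backend could
replace the boundary-voxel realization behind the same contract.

## Registration model

Moving cloud Y = {y_m} (M centroids) is fit to fixed cloud X = {x_n} by EM
under an isotropic Gaussian mixture with an extra uniform outlier
component of mass w. The membership priors are the normalized classifier
posteriors at the centroids,

```
P(m)* = P(c=+1 | y_m) / Σ_k P(c=+1 | y_k) ,
```

so low-confidence points contribute little to the correspondence posterior
and hence to the transform update; uniform weights recover standard CPD
exactly (to machine precision, verified by test). The E-step posterior is

```
P(m|x_n) = P(m)* exp(-‖x_n - 𝒯(y_m)‖²/2σ²)
           / [Σ_k P(k)* exp(-‖x_n - 𝒯(y_k)‖²/2σ²) + (w/(1-w))(2πσ²)^{3/2}/N]
```

computed in log space with per-column max subtraction (the outlier
constant participates in the max, so far outliers cannot overflow). The
M-step is the closed-form posterior-weighted Procrustes update: weighted
centroids, SVD of the weighted cross-covariance with the
determinant-correcting diagonal (det R = +1 always), scale from tr(ΣC)
over the weighted spread of Y (similarity mode; clamped to [0.5, 2] to
prevent collapse, or fixed at 1 in rigid mode), and σ² from the weighted
residual, floored at 10⁻⁸ mm². The transform family is similarity
(rotation, isotropic scale, translation) with a rigid option. Defaults:
w = 0.1, tol 10⁻⁶ on the relative change of the EM objective Q, 150
iterations maximum. The fixed cloud's weights are ignored by the model —
only the GMM centroids carry priors — so the caller decides which
acquisition supplies Y.

Both clouds are centred and scaled to unit RMS radius before EM and the
result is mapped back to mm. Q and its prior-augmented variant Q* (which
adds Σ P(m|x_n) log P(m)*) are recorded per iteration.

### Initialization, annealing and safeguards

Plain centred-identity initialization is provably inadequate for
cranium-like data: a thin near-ellipsoidal shell is almost invariant under
180° rotations about its principal axes, and when the two acquisitions
carry complementary occlusion sectors the pose that overlays the two
missing sectors can have *better* mixture likelihood at coarse σ than the
true pose. Four measures address this; all are data-driven and contain no
shape- or test-specific constants:

1. **Ellipsoid-fit initialization** (`init="auto"`, the default). A
   weighted least-squares general-quadric fit to each cloud recovers its
   centre and principal axes; unlike raw second moments, the fit is driven
   by surface curvature and degrades only mildly under 90° missing
   sectors. The moving cloud's fit is weighted by the membership priors,
   so low-weight outliers barely influence it. Axis correspondence leaves
   a four-fold proper-flip ambiguity; the candidates differ pairwise by
   180°, so at most one lies within 90° of the identity, and that
   smallest-rotation candidate is chosen — encoding the assumption that
   the acquisitions are oriented within a quarter turn of each other. The
   init falls back to the identity when the quadric fit is degenerate or
   either cloud has fewer than 16 points.
2. **Resolution-matched start scale.** After a coarse init, σ² starts at
   the median squared nearest-neighbour residual (median, so points facing
   the other acquisition's missing sector cannot inflate it); with the
   identity init the classical mean-pairwise-distance σ²₀ is used.
3. **Monotone σ².** σ² is treated as an annealing resolution: the M-step
   may shrink it but never re-inflate it, which would re-open the
   misleading coarse correspondence basins.
4. **Best-likelihood iterate and Q safeguard.** The E-step yields the
   exact negative log-likelihood of the mixture at no extra cost; the
   returned solution is the iterate with the best likelihood visited, and
   a step that raises Q by more than 10⁻⁸ (relative) is rejected and stops
   the iteration. The recorded Q trajectory is therefore non-increasing.

With these in place, ground-truth similarity transforms (rotations to 40°,
translations to 20 mm, scale 0.9–1.1) are recovered to machine precision
on noiseless corresponding clouds and to ~1–3 mm TRE on voxel-quantized,
complementarily occluded phantom pairs.

Optional **partial-overlap trimming** (`trim=True`; the volume pipeline's
default) removes, after the coarse init, points whose nearest-neighbour
residual exceeds 3× the median — points facing the other acquisition's
occluded sector have no true counterpart and otherwise bias the pose. The
final transform still applies to the full clouds. The pipeline default
also raises w to 0.3, reflecting the larger unmatched fraction of real
multi-projection pairs.

## Synthetic phantom

Clinical fetal volumes are not redistributable, so all tests run on a
generator that emulates the acquisition geometry: an ellipsoidal cranium
shell (default semi-axes 28 × 24 × 20 mm, 2.5 mm thick) over interior
tissue and background (intensities 200/90/30), on a 128³ grid at 0.5 mm
isotropic spacing; multiplicative speckle (Rayleigh field, unit mean,
Gaussian-correlated with σ = 0.8 voxels); and azimuthal occlusion wedges
about the beam axis whose shell intensities are multiplied by an
attenuation factor and whose labels are dropped (a 90° wedge removes ≈25%
of the shell). Acquisition B resamples A's noiseless anatomy trilinearly
under a known similarity transform, then applies its own wedges and an
independent speckle realization — as repeat acquisitions differ in
practice. Cloud pairs are drawn from one shared surface-sample pool
filtered by each acquisition's wedges (so that without occlusion the pair
corresponds point-to-point through the ground truth), with 0.5 mm
position noise by default (one voxel of surface quantization), optional
box-uniform outliers at an exact count, and beta-perturbed weights.

For end-to-end evaluation the two wedges are perpendicular, not antipodal:
on a centrally symmetric shell, antipodal wedges make the truth formally
unidentifiable (the 180° flip that maps hole onto hole is an exact shell
symmetry and strictly increases the likelihood), which is a degeneracy of
the idealized phantom, not of real crania.

What the phantom does **not** emulate: internal brain anatomy, beam
convolution/point-spread physics, scan conversion, fetal motion, or the
texture inhomogeneity of real tissue. Its segmentation task is therefore
far more separable than clinical data — cross-validated Dice and AUC sit
near 1.0, well above the ~0.85 reported for real volumes — so passing
segmentation tests demonstrates correctness of the pipeline, not clinical
performance. The registration phantom is, by the same token, *harder* than
real data in one respect: a symmetric ellipsoid gives the rotation a much
shallower likelihood than an asymmetric real cranium.

## Evaluation metrics

* **TRE** — mean Euclidean distance between n = 1000 uniform target points
  in the reference head's bounding box mapped through the true and the
  estimated transform (an RMS variant is available by flag; the mean is
  the default reading of the printed formula).
* **RMS translation/rotation error** — √(⅓ Σ (b_k − a_k)²) over the
  translation triplet (mm) and the intrinsic Z-Y-X Euler-angle triplet
  (degrees); any fixed Euler convention is valid since truth and estimate
  use the same extraction.
* **Dice** — 2|A∩B|/(|A|+|B|); two empty masks define 1.0.
* **HSD** — symmetric maximum of boundary-voxel-to-nearest-boundary-voxel
  distances in mm (95th-percentile variant by flag).
* **AUC** — probability a random positive voxel outscores a random
  negative one (ties ½).

Segmentation quality is assessed by k-fold cross-validation over phantom
volumes (train on k−1, score the held-out one).

## Problem sizes used in tests

Image-path tests run on 64³ phantoms (0.8 mm spacing, 18 × 16 × 14 mm
semi-axes) and the end-to-end check on the default 128³ phantom; cloud
registration tests use 500–1000 points. These sizes were chosen as the
smallest at which every stage operates in its intended regime (the 9³
filter window, two resolvable shell surfaces, ≥2000 boundary voxels).

## Known limitations

* The confidence model is a stand-in with two free rates; it is not a
  random-walk solution of the beam physics.
* The smallest-rotation flip rule assumes acquisitions within ~90° of each
  other; pairs flipped further require an external coarse orientation.
* Non-rigid deformation is out of scope; the transform family is
  similarity/rigid only.
* Forest hyperparameters were fixed a priori for the phantom regime and
  are exposed in `ForestConfig`; clinical data would need its own tuning
  and expert labels.
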