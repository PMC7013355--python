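# plcpd — probabilistic-learning coherent point drift

Automatic rigid/similarity registration of 3D ultrasound fetal-head
volumes. Second- and third-trimester fetal ultrasound carries speckle and
acoustic occlusion: the calcified cranium shadows part of every
acquisition, so two projections (axial, coronal) of the same head see
different, complementary fragments of the skull. `plcpd` aligns such pairs
geometrically: it segments the cranium with a random-forest voxel
classifier, samples the shell surfaces into a point cloud whose weights
are the classifier posteriors, and registers the clouds with a weighted
Gaussian-mixture formulation of coherent point drift in which the mixture
membership priors are those posteriors,

```
P(m)* = P(c=+1 | y_m) / Σ_k P(c=+1 | y_k) ,
```

so unreliable points (shadows, artefacts, outliers) contribute little to
the estimated similarity transform Θ = (R, s, t). With uniform weights the
algorithm reduces exactly to standard CPD. The package also ships the full
upstream pipeline (confidence-map preprocessing, an 8-feature texture/edge
bank, forest training and JSON serialization, weighted-cloud construction),
the evaluation metrics (TRE, RMS translation/rotation error, Dice,
Hausdorff surface distance, AUC), and a synthetic phantom generator with
known ground truth, since clinical volumes are not redistributable.

The audience is medical-image-analysis researchers working on fetal
ultrasound registration or on weighted point-set registration generally.

## Worked example

```python
import numpy as np
from dataclasses import replace
from plcpd import (OcclusionSector, PhantomSpec, evaluate_registration,
                   make_phantom_pair, pipeline_features, register_volume_pair,
                   train_forest)
from plcpd.phantom import sample_pair_spec

# Two simulated acquisitions of one head, related by a known similarity
# transform, each with its own 90-degree acoustic-shadow wedge.
spec = replace(
    sample_pair_spec(11, max_rotation_deg=25, max_translation_mm=8),
    sectors_a=(OcclusionSector((1, 0, 0), 90.0, 0.0),),
    sectors_b=(OcclusionSector((0, 1, 0), 90.0, 0.0),),
)
vol_a, vol_b, lab_a, lab_b, truth = make_phantom_pair(spec)

# Train the cranium classifier on an independent labelled phantom.
train_vol, _, train_lab, _, _ = make_phantom_pair(PhantomSpec(seed=99))
model = train_forest(pipeline_features(train_vol), train_lab, seed=5)

# Confidence-weight -> segment -> weighted clouds -> register.
pair = register_volume_pair(vol_a, vol_b, model, seed=3)

idx = np.argwhere(lab_a)
bbox = np.stack([idx.min(0), idx.max(0)]) * np.asarray(spec.spacing)
report = evaluate_registration(truth, pair.result.transform, bbox, seed=0)
print(f"TRE             {report.tre:.2f} mm over {report.n_targets} targets")
print(f"RMS translation {report.rms_translation:.2f} mm")
print(f"RMS rotation    {report.rms_rotation:.2f} deg")
```

Output from this script:

```
TRE             1.06 mm over 1000 targets
RMS translation 1.10 mm
RMS rotation    1.19 deg
```

The TRE is the mean distance by which 1000 uniformly sampled head points
land away from where the true transform would put them — here about 2% of
the phantom head's 48 mm mean diameter, i.e. the two acquisitions are
aligned to well within the shell thickness despite each missing a quarter
of the skull. The RMS rows decompose the residual into its translation
(mm) and Euler-angle (degrees) components.

Shorter, single-capability walkthroughs live in `examples/`:

| script | shows |
| --- | --- |
| `examples/confidence_weighting.py` | confidence maps and intensity homogenization |
| `examples/segment_cranium.py` | feature bank, forest training, posterior, Dice/AUC |
| `examples/register_clouds.py` | weighted cloud registration and transform recovery |
| `examples/weighting_advantage.py` | PL-CPD vs uniform-prior CPD under outliers |
| `examples/end_to_end.py` | the full volume-to-transform pipeline |

A thin CLI mirrors the pipeline stages
(`plcpd confidence | train | segment | cloud | register | phantom |
evaluate`); run `plcpd --help`.

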