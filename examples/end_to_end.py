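"""The full pipeline: volumes with complementary shadows to a transform.

Generates an occluded phantom acquisition pair with a known ground truth,
trains the cranium classifier on an independent phantom, runs
confidence-weighting -> segmentation -> weighted clouds -> registration,
and scores the result by TRE.
"""

import numpy as np
from dataclasses import replace

from plcpd import (
    OcclusionSector,
    PhantomSpec,
    evaluate_registration,
    make_phantom_pair,
    pipeline_features,
    register_volume_pair,
    train_forest,
)
from plcpd.phantom import sample_pair_spec

spec = replace(
    sample_pair_spec(11, max_rotation_deg=25, max_translation_mm=8),
    sectors_a=(OcclusionSector((1.0, 0.0, 0.0), 90.0, 0.0),),
    sectors_b=(OcclusionSector((0.0, 1.0, 0.0), 90.0, 0.0),),
)
vol_a, vol_b, lab_a, lab_b, truth = make_phantom_pair(spec)

train_vol, _, train_lab, _, _ = make_phantom_pair(PhantomSpec(seed=99))
model = train_forest(pipeline_features(train_vol), train_lab, seed=5)

pair = register_volume_pair(vol_a, vol_b, model, seed=3)

idx = np.argwhere(lab_a)
bbox = np.stack([idx.min(0), idx.max(0)]) * np.asarray(spec.spacing)
report = evaluate_registration(truth, pair.result.transform, bbox, seed=0)
mean_diameter = 2.0 * np.mean(spec.semi_axes)

print(f"TRE             {report.tre:.2f} mm over {report.n_targets} targets")
print(f"RMS translation {report.rms_translation:.2f} mm")
print(f"RMS rotation    {report.rms_rotation:.2f} deg")
print(f"TRE as % of the head's mean diameter: "
      f"{100 * report.tre / mean_diameter:.1f}%")
print(
    "Each acquisition is missing a different quarter of the skull, yet "
    "the recovered transform lands head points within a couple of mm of "
    "their true positions."
)
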