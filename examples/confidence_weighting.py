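"""Confidence maps: depth attenuation, acoustic shadows, and weighting.

Builds a small phantom acquisition, computes its confidence map, and shows
how weighting suppresses the shadowed shell while keeping proximal tissue.
"""

import numpy as np

from plcpd import (
    OcclusionSector,
    PhantomSpec,
    compute_confidence_map,
    make_phantom_pair,
    weight_by_confidence,
)

spec = PhantomSpec(
    shape=(64, 64, 64), spacing=(0.8, 0.8, 0.8),
    semi_axes=(18.0, 16.0, 14.0), shell_thickness=2.0, seed=0,
    sectors_a=(OcclusionSector((1.0, 0.0, 0.0), 90.0, 0.0),),
)
vol, _, labels, _, _ = make_phantom_pair(spec)

cmap = compute_confidence_map(vol, beam_axis=2, attenuation_coeff=0.02)
weighted = weight_by_confidence(vol, cmap)

k = vol.shape[2]
proximal = cmap.data[:, :, : k // 3].mean()
distal = cmap.data[:, :, -k // 3 :].mean()
print(f"mean confidence, proximal third : {proximal:.3f}")
print(f"mean confidence, distal third   : {distal:.3f}")
print(f"intensity std before weighting  : {vol.data.std():.1f}")
print(f"intensity std after weighting   : {weighted.data.std():.1f}")
print(
    "Confidence is 1 at the transducer face and decays with depth and "
    "behind strong reflectors; weighting homogenizes the volume before "
    "feature extraction."
)
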