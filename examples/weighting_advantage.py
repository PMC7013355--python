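"""Why weighted priors help: PL-CPD vs uniform-prior CPD under outliers.

Replaces 30% of the moving cloud by box-uniform outliers carrying weight
0.01 (inliers 0.95) and compares the classifier-weighted registration with
the uniform-prior baseline on the same seeds.
"""

import numpy as np

from plcpd import RegistrationConfig, evaluate_registration, make_cloud_pair, register
from plcpd.phantom import sample_pair_spec

tre_weighted, tre_uniform = [], []
for seed in range(10):
    spec = sample_pair_spec(seed)
    fixed, moving, truth = make_cloud_pair(
        spec, n_points=1000, outlier_fraction=0.3,
        inlier_weight=0.95, outlier_weight=0.01,
    )
    bbox = np.stack([fixed.points.min(0), fixed.points.max(0)])
    for use_weights, store in [(True, tre_weighted), (False, tre_uniform)]:
        res = register(
            fixed, moving, RegistrationConfig(w=0.3, use_weights=use_weights)
        )
        store.append(
            evaluate_registration(truth, res.transform, bbox, seed=seed).tre
        )

wins = sum(a < b for a, b in zip(tre_weighted, tre_uniform))
print(f"weighted priors win on {wins}/10 seeds")
print(f"median TRE, weighted priors : {np.median(tre_weighted):.3f} mm")
print(f"median TRE, uniform priors  : {np.median(tre_uniform):.3f} mm")
print(
    "Outliers carry almost no membership prior, so they barely influence "
    "the weighted transform update; the uniform baseline gives every "
    "centroid the same 1/M prior."
)
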