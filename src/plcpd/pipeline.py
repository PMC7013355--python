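"""End-to-end pipeline: volumes → confidence weighting → segmentation →
weighted clouds → registration, plus the cross-validation harness used to
validate the cranium classifier.

The stage order mirrors the method: the feature bank is computed on the
confidence-weighted volume (raw intensity is restored as the first feature
plane so the classifier sees both), the forest posterior is thresholded
into the cranium mask, the mask boundary becomes the weighted cloud with
posteriors as weights, and the two clouds are registered with the
posterior-derived membership priors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cloud import WeightedPointCloud, build_weighted_cloud
from .confidence import compute_confidence_map, weight_by_confidence
from .features import FeatureStack, extract_features
from .forest import (
    ForestConfig,
    ForestModel,
    PosteriorVolume,
    binarize_posterior,
    predict_posterior,
    train_forest,
)
from .metrics import dice_coefficient, hausdorff_surface_distance, roc_auc
from .registration import RegistrationConfig, RegistrationResult, register
from .volume import Volume3D

__all__ = [
    "pipeline_features",
    "segment_volume",
    "volume_to_cloud",
    "register_volume_pair",
    "cross_validate_segmentation",
]


def pipeline_features(
    vol: Volume3D,
    beam_axis: int | None = None,
    window: int = 9,
    attenuation_coeff: float = 0.02,
    shadow_gain: float = 0.5,
) -> FeatureStack:
    """Feature stack on the confidence-weighted volume, raw intensity kept.

    The first feature plane is replaced by the raw (unweighted) intensity so
    the classifier sees both the homogenized and the original signal.
    """
    cmap = compute_confidence_map(
        vol,
        beam_axis=beam_axis,
        attenuation_coeff=attenuation_coeff,
        shadow_gain=shadow_gain,
    )
    weighted = weight_by_confidence(vol, cmap)
    stack = extract_features(weighted, window=window)
    stack.data[..., 0] = vol.data
    return stack


def segment_volume(
    vol: Volume3D,
    model: ForestModel,
    threshold: float = 0.5,
    window: int = 9,
    beam_axis: int | None = None,
) -> tuple[PosteriorVolume, np.ndarray]:
    """Posterior volume and binarized cranium mask of one acquisition."""
    stack = pipeline_features(vol, beam_axis=beam_axis, window=window)
    posterior = predict_posterior(model, stack)
    mask = binarize_posterior(posterior, threshold=threshold)
    return posterior, mask


def volume_to_cloud(
    vol: Volume3D,
    model: ForestModel,
    target_points: int = 2000,
    threshold: float = 0.5,
    window: int = 9,
    seed: int | None = None,
) -> WeightedPointCloud:
    """Segment an acquisition and build its weighted boundary cloud."""
    posterior, mask = segment_volume(vol, model, threshold=threshold, window=window)
    return build_weighted_cloud(
        mask,
        posterior.data,
        spacing=vol.spacing,
        origin=vol.origin,
        target_points=target_points,
        seed=seed,
    )


@dataclass
class PairRegistration:
    fixed_cloud: WeightedPointCloud
    moving_cloud: WeightedPointCloud
    result: RegistrationResult


def register_volume_pair(
    fixed_vol: Volume3D,
    moving_vol: Volume3D,
    model: ForestModel,
    target_points: int = 2000,
    threshold: float = 0.5,
    window: int = 9,
    seed: int | None = None,
    config: RegistrationConfig | None = None,
) -> PairRegistration:
    """Full pipeline on a volume pair; the result's transform maps the
    moving acquisition's frame onto the fixed one.

    The default registration configuration raises the outlier mass to
    w = 0.3 and enables partial-overlap trimming: acquisitions from
    different projections carry complementary acoustic shadows, so a
    sizeable fraction of each cloud has no true counterpart.
    """
    if config is None:
        config = RegistrationConfig(w=0.3, trim=True)
    fixed_cloud = volume_to_cloud(
        fixed_vol, model, target_points=target_points, threshold=threshold,
        window=window, seed=seed,
    )
    moving_cloud = volume_to_cloud(
        moving_vol, model, target_points=target_points, threshold=threshold,
        window=window, seed=None if seed is None else seed + 1,
    )
    result = register(fixed_cloud, moving_cloud, config=config)
    return PairRegistration(fixed_cloud, moving_cloud, result)


def cross_validate_segmentation(
    stacks: list[FeatureStack],
    labels: list[np.ndarray],
    spacings: list[tuple[float, float, float]] | None = None,
    config: ForestConfig | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Leave-one-out / k-fold cross-validation of the cranium classifier.

    With k volumes this runs k folds, each training on k−1 volumes and
    scoring the held-out one by Dice (of the binarized posterior), Hausdorff
    surface distance (mm) and AUC of the raw posterior.  Returns one row per
    fold.
    """
    k = len(stacks)
    if k < 2:
        raise ValueError("cross-validation needs at least two volumes")
    if len(labels) != k:
        raise ValueError("one label volume per feature stack required")
    if spacings is None:
        spacings = [s.spacing for s in stacks]
    rows = []
    for fold in range(k):
        train_stacks = [s for i, s in enumerate(stacks) if i != fold]
        train_labels = [l for i, l in enumerate(labels) if i != fold]
        model = train_forest(
            train_stacks, train_labels, config=config, seed=seed + fold
        )
        posterior = predict_posterior(model, stacks[fold])
        mask = binarize_posterior(posterior, threshold=threshold)
        truth = np.asarray(labels[fold]) > 0
        rows.append(
            {
                "fold": fold,
                "dice": dice_coefficient(mask, truth),
                "hsd_mm": hausdorff_surface_distance(
                    mask, truth, spacing=spacings[fold]
                ),
                "auc": roc_auc(posterior.data.reshape(-1), truth.reshape(-1)),
            }
        )
    return pd.DataFrame(rows)
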