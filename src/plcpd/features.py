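"""Per-voxel texture/edge feature bank for cranium classification.

Eight features per voxel, the first six over a cubic analysis window
(default 9×9×9): raw intensity, local variance, local rank, local entropy,
local median, Wiener-filtered intensity; plus a slice-wise Canny edge map
and a 6-neighbour discrete Laplacian response.

Rank and entropy are computed from binned local intensity histograms
(uniform filter per bin), which makes the 9³-window statistics tractable on
full volumes: rank is the fraction of window voxels below the centre value
(ties counted half), normalized to [0, 1]; entropy is the Shannon entropy
(bits) of the binned local distribution.  The Wiener filter is the local
adaptive filter using window mean/variance with the noise variance
estimated as the mean of the local variances (scipy's formulation).  Canny
is a 2D operator, so it is applied slice-wise along a beam-perpendicular
axis with hysteresis thresholds at 0.1/0.2 of the slice's maximum gradient
magnitude, recorded as a binary feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage import feature as skfeature
from skimage import filters as skfilters

from .volume import Volume3D

__all__ = ["FeatureStack", "extract_features", "FEATURE_NAMES"]

FEATURE_NAMES = (
    "intensity",
    "variance",
    "rank",
    "entropy",
    "median",
    "wiener",
    "canny",
    "laplacian",
)

_N_BINS = 32  # intensity bins for local rank/entropy histograms


@dataclass
class FeatureStack:
    """(X, Y, Z, d) response stack with grid metadata."""

    data: np.ndarray
    names: tuple[str, ...]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 4:
            raise ValueError(f"feature stack must be 4D, got {arr.ndim}D")
        if arr.shape[-1] != len(self.names):
            raise ValueError(
                f"{arr.shape[-1]} feature planes but {len(self.names)} names"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature stack contains non-finite values")
        self.data = arr

    @property
    def n_features(self) -> int:
        return self.data.shape[-1]

    def as_matrix(self) -> np.ndarray:
        """Flatten to an (n_voxels, d) design matrix."""
        return self.data.reshape(-1, self.n_features)


def _local_rank_entropy(
    data: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Local rank of the centre voxel and local histogram entropy (bits)."""
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:  # constant volume: rank 1/2 by the tie convention, entropy 0
        return np.full(data.shape, 0.5), np.zeros(data.shape)
    bins = np.clip(
        ((data - lo) / (hi - lo) * _N_BINS).astype(np.int32), 0, _N_BINS - 1
    )
    below = np.zeros(data.shape, dtype=np.float32)
    own = np.zeros(data.shape, dtype=np.float32)
    entropy = np.zeros(data.shape, dtype=np.float32)
    cum_below = np.zeros(data.shape, dtype=np.float32)
    for k in range(_N_BINS):
        frac = ndimage.uniform_filter((bins == k).astype(np.float32), size=window)
        sel = bins == k
        below[sel] = cum_below[sel]
        own[sel] = frac[sel]
        cum_below += frac
        nz = frac > 0
        entropy[nz] -= frac[nz] * np.log2(frac[nz])
    rank = np.clip(below + 0.5 * own, 0.0, 1.0)
    return rank.astype(float), np.clip(entropy, 0.0, None).astype(float)


def _canny_slicewise(data: np.ndarray, slice_axis: int = 0) -> np.ndarray:
    """Binary Canny edge map, computed per 2D slice along ``slice_axis``."""
    moved = np.moveaxis(data, slice_axis, 0)
    out = np.zeros(moved.shape, dtype=float)
    for i in range(moved.shape[0]):
        sl = moved[i]
        gmax = float(skfilters.sobel(sl).max())
        if gmax <= 0:
            continue
        out[i] = skfeature.canny(
            sl, low_threshold=0.1 * gmax, high_threshold=0.2 * gmax
        )
    return np.moveaxis(out, 0, slice_axis)


def extract_features(vol: Volume3D, window: int = 9) -> FeatureStack:
    """Compute the 8-feature per-voxel stack of a volume.

    ``window`` is the odd cubic analysis window edge (voxels) used by the
    local statistics; the volume must be strictly larger than the window on
    every axis.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if any(s <= window for s in vol.shape):
        raise ValueError(
            f"volume shape {vol.shape} must exceed the {window}-voxel window"
        )
    data = vol.data

    mean = ndimage.uniform_filter(data, size=window)
    mean_sq = ndimage.uniform_filter(data * data, size=window)
    variance = np.clip(mean_sq - mean * mean, 0.0, None)
    rank, entropy = _local_rank_entropy(data, window)
    median = ndimage.median_filter(data, size=window)
    with np.errstate(divide="ignore", invalid="ignore"):
        wiener = signal.wiener(data, mysize=window)
    # zero-variance windows make the adaptive gain 0/0; fall back to the mean
    wiener = np.where(np.isfinite(wiener), wiener, mean)
    canny = _canny_slicewise(data)
    laplacian = ndimage.laplace(data)

    stack = np.stack(
        [data, variance, rank, entropy, median, wiener, canny, laplacian], axis=-1
    )
    return FeatureStack(
        data=stack, names=FEATURE_NAMES, spacing=vol.spacing, origin=vol.origin
    )
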