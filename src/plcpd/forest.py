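"""Random-forest voxel classifier producing cranium posteriors.

An ensemble of T binary decision trees separates fetal-cranium voxels
(c = +1) from everything else (c = −1).  Each internal node draws a fresh
random candidate set of split parameters — ⌈√d⌉ feature indices crossed
with quantile thresholds of the node's samples — and keeps the candidate
maximizing the information gain

    I(S, β) = H(S) − Σ_{i∈{L,R}} (|S_i| / |S|) · H(S_i),

with H the Shannon entropy (bits) of the node's empirical class histogram.
Leaves store that histogram; the forest posterior is the plain average of
the reached leaves' positive-class frequencies over the T trees.  Training
is fully deterministic given the seed, and models serialize losslessly to
JSON (array-of-nodes layout) for exact reload.

The classifier is deliberately self-contained: its split rule, candidate
structure and leaf bookkeeping are part of the method's contract (the leaf
posteriors feed the registration priors downstream), and tests cross-check
its held-out behaviour against an independent ensemble implementation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .features import FeatureStack

__all__ = [
    "entropy",
    "information_gain",
    "ForestConfig",
    "ForestModel",
    "PosteriorVolume",
    "train_forest",
    "train_forest_samples",
    "predict_posterior",
    "binarize_posterior",
]


def entropy(hist) -> float:
    """Shannon entropy in bits of a discrete distribution (0·log 0 ≡ 0)."""
    p = np.asarray(hist, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def _label_entropy(labels: np.ndarray) -> float:
    n = labels.size
    if n == 0:
        return 0.0
    p = np.count_nonzero(labels > 0) / n
    return entropy((p, 1.0 - p))


def information_gain(parent_labels, left_mask) -> float:
    """Information gain (bits) of splitting a labeled set by a boolean mask.

    ``left_mask[i]`` routes element i to the left child, otherwise right;
    an empty child contributes 0.  Always in [0, H(parent)].
    """
    y = np.asarray(parent_labels)
    mask = np.asarray(left_mask, dtype=bool)
    if mask.shape != y.shape:
        raise ValueError("split mask must match the parent subset in length")
    n = y.size
    if n == 0:
        raise ValueError("parent subset is empty")
    h = _label_entropy(y)
    nl = int(mask.sum())
    gain = h
    if nl:
        gain -= nl / n * _label_entropy(y[mask])
    if n - nl:
        gain -= (n - nl) / n * _label_entropy(y[~mask])
    return float(gain)


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters (none are dictated by the method itself)."""

    n_trees: int = 50
    max_depth: int = 12
    n_thresholds: int = 10  # quantile thresholds per candidate feature
    min_leaf: int = 5
    max_voxels: int = 50_000  # class-balanced subsample cap per volume
    bootstrap: bool = True


@dataclass
class _Tree:
    """Array-of-nodes binary tree; leaves self-loop via children = -1."""

    feature: np.ndarray  # (n_nodes,) int, -1 at leaves
    threshold: np.ndarray  # (n_nodes,) float
    left: np.ndarray  # (n_nodes,) int child index, -1 at leaves
    right: np.ndarray
    p_pos: np.ndarray  # (n_nodes,) leaf P(c=+1); internal nodes carry it too

    def predict(self, x: np.ndarray) -> np.ndarray:
        node = np.zeros(x.shape[0], dtype=np.intp)
        active = self.left[node] >= 0
        while active.any():
            idx = node[active]
            go_left = x[active, self.feature[idx]] <= self.threshold[idx]
            node[active] = np.where(go_left, self.left[idx], self.right[idx])
            active = self.left[node] >= 0
        return self.p_pos[node]

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "p_pos": self.p_pos.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Tree":
        return cls(
            feature=np.asarray(d["feature"], dtype=np.intp),
            threshold=np.asarray(d["threshold"], dtype=float),
            left=np.asarray(d["left"], dtype=np.intp),
            right=np.asarray(d["right"], dtype=np.intp),
            p_pos=np.asarray(d["p_pos"], dtype=float),
        )


def _grow_tree(
    x: np.ndarray, y: np.ndarray, cfg: ForestConfig, rng: np.random.Generator
) -> _Tree:
    d = x.shape[1]
    n_cand_features = math.ceil(math.sqrt(d))
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    p_pos: list[float] = []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        p_pos.append(0.0)
        return len(feature) - 1

    def grow(indices: np.ndarray, depth: int) -> int:
        node = new_node()
        yl = y[indices]
        frac_pos = float(np.count_nonzero(yl > 0)) / yl.size
        p_pos[node] = frac_pos
        if (
            depth >= cfg.max_depth
            or yl.size < 2 * cfg.min_leaf
            or frac_pos in (0.0, 1.0)
        ):
            return node
        h_parent = entropy((frac_pos, 1.0 - frac_pos))
        feats = rng.choice(d, size=min(n_cand_features, d), replace=False)
        best_gain, best_feat, best_thr = 0.0, -1, 0.0
        qs = np.linspace(0.05, 0.95, cfg.n_thresholds)
        ypos = (yl > 0).astype(np.float64)
        npos = ypos.sum()
        for f in feats:
            col = x[indices, f]
            thrs = np.unique(np.quantile(col, qs))
            for thr in thrs:
                mask = col <= thr
                nl = int(mask.sum())
                nr = yl.size - nl
                if nl < cfg.min_leaf or nr < cfg.min_leaf:
                    continue
                npos_l = float(ypos[mask].sum())
                pl = min(max(npos_l / nl, 0.0), 1.0)
                pr = min(max((npos - npos_l) / nr, 0.0), 1.0)
                gain = (
                    h_parent
                    - nl / yl.size * entropy((pl, 1.0 - pl))
                    - nr / yl.size * entropy((pr, 1.0 - pr))
                )
                if gain > best_gain:
                    best_gain, best_feat, best_thr = gain, int(f), float(thr)
        if best_feat < 0:
            return node
        assert best_gain >= 0.0  # information gain of a realized split
        mask = x[indices, best_feat] <= best_thr
        feature[node] = best_feat
        threshold[node] = best_thr
        left[node] = grow(indices[mask], depth + 1)
        right[node] = grow(indices[~mask], depth + 1)
        return node

    grow(np.arange(x.shape[0]), 0)
    return _Tree(
        feature=np.asarray(feature, dtype=np.intp),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.intp),
        right=np.asarray(right, dtype=np.intp),
        p_pos=np.asarray(p_pos, dtype=float),
    )


@dataclass
class ForestModel:
    """Trained ensemble with per-leaf class histograms."""

    trees: list[_Tree]
    n_features: int
    config: ForestConfig = field(default_factory=ForestConfig)
    seed: int | None = None
    feature_names: tuple[str, ...] | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """P(c = +1 | x): average of the reached leaves over all trees."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.n_features:
            raise ValueError(
                f"model expects {self.n_features} features, got shape {x.shape}"
            )
        acc = np.zeros(x.shape[0])
        for tree in self.trees:
            acc += tree.predict(x)
        return acc / self.n_trees

    # ------------------------------------------------------------------- JSON
    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_features": self.n_features,
            "seed": self.seed,
            "feature_names": list(self.feature_names) if self.feature_names else None,
            "config": {
                "n_trees": self.config.n_trees,
                "max_depth": self.config.max_depth,
                "n_thresholds": self.config.n_thresholds,
                "min_leaf": self.config.min_leaf,
                "max_voxels": self.config.max_voxels,
                "bootstrap": self.config.bootstrap,
            },
            "trees": [t.to_dict() for t in self.trees],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ForestModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            trees=[_Tree.from_dict(t) for t in payload["trees"]],
            n_features=payload["n_features"],
            config=ForestConfig(**payload["config"]),
            seed=payload["seed"],
            feature_names=tuple(payload["feature_names"])
            if payload["feature_names"]
            else None,
        )


@dataclass
class PosteriorVolume:
    """Voxelwise P(c = +1 | features) in [0, 1] on the source grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
            raise ValueError("posterior values must lie in [0, 1]")
        self.data = np.clip(arr, 0.0, 1.0)


def train_forest_samples(
    x: np.ndarray,
    y: np.ndarray,
    config: ForestConfig | None = None,
    seed: int = 0,
    feature_names: tuple[str, ...] | None = None,
) -> ForestModel:
    """Train a forest on an (n, d) sample matrix with ±1 (or boolean) labels."""
    cfg = config or ForestConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    y = np.where(y > 0, 1, -1)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("x must be (n, d) with one label per row")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training data: only one class present")
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(cfg.n_trees):
        tree_rng = np.random.default_rng(rng.integers(2**31))
        if cfg.bootstrap:
            idx = tree_rng.integers(x.shape[0], size=x.shape[0])
            trees.append(_grow_tree(x[idx], y[idx], cfg, tree_rng))
        else:
            trees.append(_grow_tree(x, y, cfg, tree_rng))
    return ForestModel(
        trees=trees,
        n_features=x.shape[1],
        config=cfg,
        seed=seed,
        feature_names=feature_names,
    )


def subsample_balanced(
    labels: np.ndarray,
    max_total: int,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Flat indices of a class-balanced voxel subsample (≤ max_total)."""
    flat = np.asarray(labels).reshape(-1)
    valid = np.ones(flat.shape, dtype=bool) if mask is None else np.asarray(mask).reshape(-1)
    pos = np.flatnonzero((flat > 0) & valid)
    neg = np.flatnonzero((flat <= 0) & valid)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("degenerate training data: only one class present")
    per_class = min(pos.size, neg.size, max_total // 2)
    sel = np.concatenate(
        [
            rng.choice(pos, size=per_class, replace=False),
            rng.choice(neg, size=per_class, replace=False),
        ]
    )
    return np.sort(sel)


def train_forest(
    features: FeatureStack | list[FeatureStack],
    labels: np.ndarray | list[np.ndarray],
    config: ForestConfig | None = None,
    seed: int = 0,
    mask: np.ndarray | list[np.ndarray] | None = None,
) -> ForestModel:
    """Train the cranium classifier from feature stacks and label volumes.

    Labels are +1 (cranium) / −1 (everything else), or boolean.  Each volume
    contributes a class-balanced random subsample of at most
    ``config.max_voxels`` voxels (optionally restricted by a sampling mask).
    """
    cfg = config or ForestConfig()
    stacks = features if isinstance(features, list) else [features]
    lab_list = labels if isinstance(labels, list) else [labels]
    mask_list = mask if isinstance(mask, list) else [mask] * len(stacks)
    if len(stacks) != len(lab_list):
        raise ValueError("one label volume per feature stack required")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    names = stacks[0].names
    for stack, lab, msk in zip(stacks, lab_list, mask_list):
        lab = np.asarray(lab)
        if lab.shape != stack.data.shape[:-1]:
            raise ValueError(
                f"label shape {lab.shape} != grid {stack.data.shape[:-1]}"
            )
        sel = subsample_balanced(lab, cfg.max_voxels, rng, mask=msk)
        xs.append(stack.as_matrix()[sel])
        ys.append(np.where(lab.reshape(-1)[sel] > 0, 1, -1))
    return train_forest_samples(
        np.vstack(xs),
        np.concatenate(ys),
        config=cfg,
        seed=int(rng.integers(2**31)),
        feature_names=names,
    )


def predict_posterior(model: ForestModel, features: FeatureStack) -> PosteriorVolume:
    """Apply the forest voxelwise, returning the posterior volume."""
    if features.n_features != model.n_features:
        raise ValueError(
            f"model trained on {model.n_features} features, stack has "
            f"{features.n_features}"
        )
    probs = model.predict_proba(features.as_matrix())
    return PosteriorVolume(
        data=probs.reshape(features.data.shape[:-1]),
        spacing=features.spacing,
        origin=features.origin,
    )


def binarize_posterior(
    posterior: PosteriorVolume | np.ndarray,
    threshold: float = 0.5,
    largest_component: bool = True,
) -> np.ndarray:
    """Threshold the posterior into a boolean cranium mask (ties → cranium).

    With ``largest_component`` (default) only the largest 26-connected
    component survives — the cranium is a single shell.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    data = posterior.data if isinstance(posterior, PosteriorVolume) else np.asarray(posterior)
    mask = data >= threshold
    if largest_component and mask.any():
        structure = np.ones((3, 3, 3), dtype=bool)
        labeled, n = ndimage.label(mask, structure=structure)
        if n > 1:
            counts = np.bincount(labeled.reshape(-1))[1:]
            mask = labeled == (int(np.argmax(counts)) + 1)
    return mask
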