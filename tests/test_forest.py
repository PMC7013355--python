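import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plcpd import (
    ForestConfig,
    ForestModel,
    binarize_posterior,
    entropy,
    information_gain,
    predict_posterior,
    train_forest,
    train_forest_samples,
)
from plcpd.features import FeatureStack


# ------------------------------------------------------------------ entropy
@pytest.mark.parametrize(
    "hist, expected",
    [
        ((0.5, 0.5), 1.0),
        ((1.0, 0.0), 0.0),
        ((0.75, 0.25), 0.8112781244591328),  # -Σ p log2 p evaluated directly
    ],
)
def test_entropy_reference_values(hist, expected):
    assert entropy(hist) == pytest.approx(expected, abs=1e-12)


def test_entropy_rejects_invalid_distributions():
    with pytest.raises(ValueError):
        entropy((-0.1, 1.1))
    with pytest.raises(ValueError):
        entropy((0.5, 0.6))


@settings(derandomize=True, max_examples=50)
@given(st.floats(min_value=0.0, max_value=1.0))
def test_binary_entropy_bounded_and_symmetric(p):
    h = entropy((p, 1.0 - p))
    assert 0.0 <= h <= 1.0 + 1e-12
    assert h == pytest.approx(entropy((1.0 - p, p)), abs=1e-12)


# ---------------------------------------------------------- information gain
def test_information_gain_reference_cases():
    # parent (4,4) split into pure children -> full bit
    y = np.array([1, 1, 1, 1, -1, -1, -1, -1])
    assert information_gain(y, y > 0) == pytest.approx(1.0, abs=1e-12)
    # children with the parent's class ratio -> no information
    mask = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=bool)
    assert information_gain(y, mask) == pytest.approx(0.0, abs=1e-12)
    # parent (6,2) split (4,0)/(2,2): H(0.75) - 0.5*0 - 0.5*1
    y2 = np.array([1, 1, 1, 1, 1, 1, -1, -1])
    mask2 = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
    assert information_gain(y2, mask2) == pytest.approx(
        0.8112781244591328 - 0.5, abs=1e-12
    )


def test_information_gain_bounds_on_random_splits():
    rng = np.random.default_rng(0)
    for _ in range(100):
        y = rng.choice([-1, 1], size=rng.integers(2, 40))
        mask = rng.random(y.size) < rng.random()
        g = information_gain(y, mask)
        p = (y > 0).mean()
        assert -1e-12 <= g <= entropy((p, 1 - p)) + 1e-12


# ------------------------------------------------------------------ training
def test_single_tree_fits_separable_data_perfectly():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 1, size=(200, 1))
    y = np.where(x[:, 0] > 0.5, 1, -1)
    model = train_forest_samples(
        x, y, ForestConfig(n_trees=1, bootstrap=False, min_leaf=1), seed=0
    )
    pred = np.where(model.predict_proba(x) >= 0.5, 1, -1)
    assert (pred == y).all()


def test_training_is_deterministic_given_seed(tmp_path):
    rng = np.random.default_rng(2)
    x = rng.normal(size=(300, 4))
    y = np.where(x[:, 0] + x[:, 2] > 0, 1, -1)
    m1 = train_forest_samples(x, y, ForestConfig(n_trees=5), seed=42)
    m2 = train_forest_samples(x, y, ForestConfig(n_trees=5), seed=42)
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    m1.to_json(p1)
    m2.to_json(p2)
    assert p1.read_text() == p2.read_text()


def test_xor_pattern_learned_out_of_sample():
    rng = np.random.default_rng(3)
    x = rng.uniform(-1, 1, size=(1000, 2))
    y = np.where(x[:, 0] * x[:, 1] > 0, 1, -1)
    n_train = 700
    model = train_forest_samples(
        x[:n_train], y[:n_train], ForestConfig(n_trees=50, max_depth=6), seed=0
    )
    pred = np.where(model.predict_proba(x[n_train:]) >= 0.5, 1, -1)
    assert (pred == y[n_train:]).mean() > 0.9


def test_single_class_training_rejected():
    x = np.zeros((50, 2))
    with pytest.raises(ValueError, match="one class"):
        train_forest_samples(x, np.ones(50), seed=0)


def test_comparable_to_sklearn_forest_on_held_out_data():
    """Independent cross-check: held-out AUC within a few points of sklearn."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(4)
    n = 1500
    x = rng.normal(size=(n, 5))
    logits = 1.2 * x[:, 0] - 0.8 * x[:, 1] * x[:, 2] + 0.4 * rng.normal(size=n)
    y = np.where(logits > 0, 1, -1)
    tr = slice(0, 1000)
    te = slice(1000, None)
    ours = train_forest_samples(x[tr], y[tr], ForestConfig(n_trees=50), seed=0)
    auc_ours = roc_auc_score(y[te] > 0, ours.predict_proba(x[te]))
    ref = RandomForestClassifier(n_estimators=50, random_state=0).fit(x[tr], y[tr] > 0)
    auc_ref = roc_auc_score(y[te] > 0, ref.predict_proba(x[te])[:, 1])
    assert auc_ours > 0.85
    assert abs(auc_ours - auc_ref) < 0.05


# ---------------------------------------------------------------- prediction
def _tiny_stack(data4d):
    return FeatureStack(
        data=data4d,
        names=tuple(f"f{i}" for i in range(data4d.shape[-1])),
        spacing=(1.0, 1.0, 1.0),
        origin=(0.0, 0.0, 0.0),
    )


def test_posterior_is_leaf_average_and_bounded():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(400, 3))
    y = np.where(x[:, 0] > 0, 1, -1)
    m1 = train_forest_samples(x, y, ForestConfig(n_trees=1), seed=0)
    m3 = train_forest_samples(x, y, ForestConfig(n_trees=3), seed=0)
    p1 = m1.predict_proba(x)
    # T=1 posterior is exactly the single tree's leaf value
    np.testing.assert_array_equal(p1, m1.trees[0].predict(x))
    # averaging a duplicated tree changes nothing
    m_dup = ForestModel(trees=m1.trees * 3, n_features=3)
    np.testing.assert_allclose(m_dup.predict_proba(x), p1, atol=1e-12)
    p3 = m3.predict_proba(x)
    assert p3.min() >= 0.0 and p3.max() <= 1.0
    # three-tree posterior is the mean of the tree outputs
    np.testing.assert_allclose(
        p3, np.mean([t.predict(x) for t in m3.trees], axis=0), atol=1e-12
    )


def test_feature_count_mismatch_rejected():
    rng = np.random.default_rng(6)
    x = rng.normal(size=(100, 4))
    y = np.where(x[:, 0] > 0, 1, -1)
    model = train_forest_samples(x, y, ForestConfig(n_trees=2), seed=0)
    stack = _tiny_stack(rng.normal(size=(8, 8, 8, 3)))
    with pytest.raises(ValueError, match="features"):
        predict_posterior(model, stack)


def test_json_round_trip_preserves_predictions(tmp_path):
    rng = np.random.default_rng(7)
    x = rng.normal(size=(300, 4))
    y = np.where(x[:, 1] - x[:, 3] > 0, 1, -1)
    model = train_forest_samples(x, y, ForestConfig(n_trees=10), seed=1)
    path = tmp_path / "forest.json"
    model.to_json(path)
    back = ForestModel.from_json(path)
    np.testing.assert_array_equal(back.predict_proba(x), model.predict_proba(x))


def test_volume_training_path(phantom_pair_64):
    """train_forest on feature stacks + label volumes produces a usable model."""
    from plcpd import pipeline_features

    spec, (va, vb, la, lb, truth) = phantom_pair_64
    stack = pipeline_features(va)
    model = train_forest(
        stack, la, ForestConfig(n_trees=10, max_voxels=10_000), seed=0
    )
    post = predict_posterior(model, stack)
    assert post.data.shape == va.shape
    assert 0.0 <= post.data.min() and post.data.max() <= 1.0


# ---------------------------------------------------------------- binarize
def test_binarize_threshold_ties_and_component_cleanup():
    post = np.full((10, 10, 10), 0.9)
    assert binarize_posterior(post, 0.5).all()
    # ties go to cranium
    assert binarize_posterior(np.full((8, 8, 8), 0.5), 0.5).all()
    # only the largest connected component survives cleanup
    post = np.zeros((20, 20, 20))
    post[2:12, 2:12, 2:12] = 1.0  # 1000 voxels
    post[16:18, 16:18, 16:18] = 1.0  # 8 voxels
    mask = binarize_posterior(post, 0.5, largest_component=True)
    assert mask[2:12, 2:12, 2:12].all() and not mask[16:18, 16:18, 16:18].any()
    both = binarize_posterior(post, 0.5, largest_component=False)
    assert both[16:18, 16:18, 16:18].all()
    with pytest.raises(ValueError):
        binarize_posterior(post, 0.0)
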