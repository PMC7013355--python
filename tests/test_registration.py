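import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from plcpd import (
    GMMState,
    RegistrationConfig,
    SimilarityTransform,
    WeightedPointCloud,
    apply_transform,
    e_step,
    m_step_similarity,
    make_cloud_pair,
    normalize_priors,
    objective_q,
    random_similarity,
    register,
)
from plcpd.phantom import sample_pair_spec


# ---------------------------------------------------------- prior weighting
def test_normalize_priors_reference_cases():
    np.testing.assert_allclose(
        normalize_priors([0.8, 0.8, 0.4]), [0.4, 0.4, 0.2], atol=1e-15
    )
    np.testing.assert_allclose(normalize_priors([0.7] * 5), np.full(5, 0.2))
    np.testing.assert_allclose(normalize_priors([1.0, 0.0, 0.0]), [1.0, 0.0, 0.0])


def test_normalize_priors_preserves_order_and_rejects_degenerate():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=30)
    out = normalize_priors(p)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)
    assert (np.argsort(out) == np.argsort(p)).all()
    with pytest.raises(ValueError, match="degenerate"):
        normalize_priors(np.zeros(10))
    with pytest.raises(ValueError):
        normalize_priors([0.5, 1.2])


# ------------------------------------------------------------------- E-step
def _naive_estep(x, y, priors, w, sigma2):
    m, n = len(y), len(x)
    p = np.zeros((m, n))
    const = w / (1 - w) * (2 * math.pi * sigma2) ** 1.5 / n if w > 0 else 0.0
    for j in range(n):
        nums = [
            priors[i] * math.exp(-np.sum((x[j] - y[i]) ** 2) / (2 * sigma2))
            for i in range(m)
        ]
        for i in range(m):
            p[i, j] = nums[i] / (sum(nums) + const)
    return p


def test_estep_single_pair_explains_fully():
    state = GMMState(sigma2=2.0, w=0.0, priors=np.array([1.0]), n_fixed=1)
    p = e_step(np.zeros((1, 3)), np.ones((1, 3)), state)
    np.testing.assert_allclose(p, 1.0)


def test_estep_matches_naive_bayes_oracle():
    rng = np.random.default_rng(1)
    for _ in range(25):
        m, n = rng.integers(2, 10, size=2)
        x = rng.normal(size=(n, 3)) * 3
        y = rng.normal(size=(m, 3)) * 3
        priors = normalize_priors(rng.uniform(0.05, 1.0, m))
        w = float(rng.uniform(0, 0.6))
        s2 = float(rng.uniform(0.2, 4.0))
        state = GMMState(sigma2=s2, w=w, priors=priors, n_fixed=n)
        np.testing.assert_allclose(
            e_step(x, y, state), _naive_estep(x, y, priors, w, s2), atol=1e-12
        )


def test_estep_identical_centroids_split_by_prior_ratio():
    y = np.zeros((2, 3))
    x = np.random.default_rng(2).normal(size=(6, 3))
    state = GMMState(sigma2=1.0, w=0.0, priors=np.array([0.9, 0.1]), n_fixed=6)
    p = e_step(x, y, state)
    np.testing.assert_allclose(p[0] / p[1], 9.0, rtol=1e-12)


def test_estep_column_masses():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(7, 3))
    y = rng.normal(size=(5, 3))
    pri = np.full(5, 0.2)
    p0 = e_step(x, y, GMMState(sigma2=1.0, w=0.0, priors=pri, n_fixed=7))
    np.testing.assert_allclose(p0.sum(axis=0), 1.0, atol=1e-12)
    pw = e_step(x, y, GMMState(sigma2=1.0, w=0.4, priors=pri, n_fixed=7))
    sums = pw.sum(axis=0)
    assert np.all(sums > 0) and np.all(sums < 1)


# ------------------------------------------------------------------- M-step
def test_mstep_self_alignment_is_identity():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(10, 3)) * 10
    t, s2 = m_step_similarity(x, x, np.eye(10))
    np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
    assert t.scale == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(t.translation, 0.0, atol=1e-8)
    assert s2 == pytest.approx(1e-8)  # at the floor


def test_mstep_recovers_known_transform_exactly():
    rng = np.random.default_rng(5)
    for _ in range(20):
        truth = random_similarity(rng)
        y = rng.normal(size=(12, 3)) * 20
        x = truth.apply(y)
        t, _ = m_step_similarity(x, y, np.eye(12))
        np.testing.assert_allclose(t.rotation, truth.rotation, atol=1e-9)
        assert t.scale == pytest.approx(truth.scale, abs=1e-9)
        np.testing.assert_allclose(t.translation, truth.translation, atol=1e-8)


def test_mstep_determinant_correction_on_reflective_configuration():
    # mirrored correspondence drives the raw SVD toward a reflection
    rng = np.random.default_rng(6)
    y = rng.normal(size=(15, 3))
    x = y * np.array([1.0, 1.0, -1.0])
    t, _ = m_step_similarity(x, y, np.eye(15))
    assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)


def test_mstep_empty_posterior_rejected():
    with pytest.raises(ValueError, match="correspondence"):
        m_step_similarity(np.zeros((3, 3)), np.zeros((3, 3)), np.zeros((3, 3)))


# ---------------------------------------------------------------- objective
def test_objective_zero_residual_unit_variance():
    x = np.random.default_rng(7).normal(size=(6, 3))
    state = GMMState(sigma2=1.0, w=0.0, priors=np.full(6, 1 / 6), n_fixed=6)
    q, _ = objective_q(x, x, np.eye(6), state, SimilarityTransform.identity())
    assert q == pytest.approx(0.0, abs=1e-12)


def test_objective_uniform_prior_shift_is_np_log_m():
    rng = np.random.default_rng(8)
    m, n = 5, 7
    x = rng.normal(size=(n, 3))
    y = rng.normal(size=(m, 3))
    p = rng.uniform(size=(m, n))
    p /= p.sum(axis=0, keepdims=True) * 1.25  # column masses < 1
    state = GMMState(sigma2=0.7, w=0.2, priors=np.full(m, 1 / m), n_fixed=n)
    q, q_star = objective_q(x, y, p, state, SimilarityTransform.identity())
    assert q_star - q == pytest.approx(-p.sum() * math.log(m), abs=1e-10)


def test_objective_matches_naive_double_loop():
    rng = np.random.default_rng(9)
    for _ in range(20):
        m, n = rng.integers(2, 10, size=2)
        x = rng.normal(size=(n, 3))
        y = rng.normal(size=(m, 3))
        p = rng.uniform(size=(m, n))
        t = random_similarity(rng)
        s2 = float(rng.uniform(0.1, 2.0))
        state = GMMState(
            sigma2=s2, w=0.1, priors=normalize_priors(rng.uniform(0.1, 1, m)),
            n_fixed=n,
        )
        q, _ = objective_q(x, y, p, state, t)
        yt = t.apply(y)
        brute = sum(
            p[i, j] * np.sum((x[j] - yt[i]) ** 2) for i in range(m) for j in range(n)
        ) / (2 * s2) + 1.5 * p.sum() * math.log(s2)
        assert q == pytest.approx(brute, abs=1e-10 * max(1, abs(brute)))


# ----------------------------------------------------------- apply_transform
def test_apply_transform_identity_translation_inverse():
    cloud = WeightedPointCloud(np.array([[0.0, 0.0, 0.0]]), np.array([0.5]))
    assert np.allclose(
        apply_transform(cloud, SimilarityTransform.identity()).points, cloud.points
    )
    t = SimilarityTransform(translation=np.array([1.0, 2.0, 3.0]))
    np.testing.assert_allclose(apply_transform(cloud, t).points, [[1, 2, 3]])
    rng = np.random.default_rng(10)
    cloud = WeightedPointCloud(rng.normal(size=(30, 3)), rng.uniform(size=30))
    t = random_similarity(rng)
    back = apply_transform(apply_transform(cloud, t), t.inverse())
    np.testing.assert_allclose(back.points, cloud.points, atol=1e-9)
    np.testing.assert_array_equal(back.weights, cloud.weights)


# ----------------------------------------------------------------- register
def test_register_fixed_point_is_identity():
    rng = np.random.default_rng(11)
    pts = rng.normal(size=(50, 3)) * 10
    cloud = WeightedPointCloud(pts, np.ones(50))
    res = register(cloud, cloud)
    assert res.converged
    np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-6)
    np.testing.assert_allclose(res.transform.translation, 0.0, atol=1e-6)
    assert res.transform.scale == pytest.approx(1.0, abs=1e-6)


def test_register_uniform_weights_equal_standard_cpd():
    spec = sample_pair_spec(5)
    fixed, moving, _ = make_cloud_pair(spec, n_points=200)
    uniform = WeightedPointCloud(moving.points, np.full(len(moving), 0.7))
    res_w = register(fixed, uniform, RegistrationConfig(use_weights=True))
    res_u = register(fixed, uniform, RegistrationConfig(use_weights=False))
    np.testing.assert_allclose(
        res_w.transform.rotation, res_u.transform.rotation, atol=1e-12
    )
    np.testing.assert_allclose(
        res_w.transform.translation, res_u.transform.translation, atol=1e-12
    )
    np.testing.assert_allclose(res_w.q_trajectory, res_u.q_trajectory, atol=1e-9)


def test_register_error_contracts():
    tiny = WeightedPointCloud(np.zeros((3, 3)), np.ones(3))
    with pytest.raises(ValueError, match="4 points"):
        register(tiny, tiny)
    rng = np.random.default_rng(12)
    fixed = WeightedPointCloud(rng.normal(size=(20, 3)), np.ones(20))
    dead = WeightedPointCloud(rng.normal(size=(20, 3)), np.zeros(20))
    with pytest.raises(ValueError, match="degenerate"):
        register(fixed, dead)


def test_register_equivariant_under_joint_rigid_motion():
    spec = sample_pair_spec(2)
    fixed, moving, _ = make_cloud_pair(spec, n_points=300)
    res1 = register(fixed, moving)
    q = Rotation.from_rotvec([0.3, -0.2, 0.5]).as_matrix()
    conj_t = SimilarityTransform(q, 1.0, np.array([5.0, -7.0, 2.0]))
    res2 = register(fixed.transformed(conj_t), moving.transformed(conj_t))
    expected = conj_t.compose(res1.transform).compose(conj_t.inverse())
    np.testing.assert_allclose(res2.transform.rotation, expected.rotation, atol=1e-6)
    np.testing.assert_allclose(
        res2.transform.translation, expected.translation, atol=1e-5
    )
    assert res2.transform.scale == pytest.approx(expected.scale, abs=1e-6)


def test_q_trajectory_non_increasing_on_seeded_registrations():
    for seed in range(3):
        spec = sample_pair_spec(seed)
        fixed, moving, _ = make_cloud_pair(spec, n_points=400)
        res = register(fixed, moving)
        q = res.q_trajectory
        assert len(q) >= 2
        assert np.all(np.diff(q) <= 1e-8 * np.maximum(1.0, np.abs(q[:-1])))


def test_rigid_mode_keeps_unit_scale():
    spec = sample_pair_spec(4, scale_range=(1.0, 1.0))
    fixed, moving, truth = make_cloud_pair(spec, n_points=300, position_noise_mm=0.0)
    res = register(fixed, moving, RegistrationConfig(allow_scale=False))
    assert res.transform.scale == 1.0
    np.testing.assert_allclose(res.transform.rotation, truth.rotation, atol=1e-5)
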