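"""Weighted-prior Gaussian-mixture point-set registration (PL-CPD).

Coherent point drift treats the moving cloud Y = {y_m} as the centroids of a
Gaussian mixture with isotropic variance σ² and fits it to the fixed cloud
X = {x_n} by EM, estimating a similarity transform 𝒯(y) = sRy + t.  An extra
uniform component with mixing mass w absorbs outliers, occlusion artefacts
and noise.  Standard CPD gives every centroid the same membership prior
P(m) = 1/M; the probabilistic-learning variant replaces it with the
classifier posterior at each centroid, normalized over the cloud:

    P(m)* = P(c = +1 | y_m) / λ,    λ = Σ_k P(c = +1 | y_k),

so that centroids unlikely to be true cranium contribute little to the
correspondence posterior and hence to the transform update.  With uniform
weights the iterates coincide with standard CPD to machine precision.

E-step (correspondence posterior, stabilized with per-column max
subtraction):

    P(m | x_n) = P(m)* exp(-‖x_n - 𝒯(y_m)‖² / 2σ²)
                 / [ Σ_k P(k)* exp(-‖x_n - 𝒯(y_k)‖² / 2σ²)
                     + (w / (1-w)) (2πσ²)^{D/2} / N ]

M-step: closed-form weighted Procrustes over (R, s, t) followed by the σ²
update; the EM objective

    Q(Θ, σ²) = (1 / 2σ²) ΣΣ P(m|x_n) ‖x_n - 𝒯(y_m)‖² + (D N_p / 2) log σ²

is non-increasing across iterations.  Q* adds the prior term
ΣΣ P(m|x_n) log P(m)*, which reduces to Q - N_p log M under uniform priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import WeightedPointCloud
from .transform import SimilarityTransform

__all__ = [
    "GMMState",
    "RegistrationConfig",
    "RegistrationResult",
    "normalize_priors",
    "e_step",
    "m_step_similarity",
    "objective_q",
    "register",
    "apply_transform",
]

_D = 3  # spatial dimensionality


@dataclass
class GMMState:
    """Mixture bookkeeping for one EM pass."""

    sigma2: float
    w: float
    priors: np.ndarray  # (M,) normalized membership priors, sum 1
    n_fixed: int  # N, size of the fixed cloud (outlier density 1/N)

    def __post_init__(self) -> None:
        p = np.asarray(self.priors, dtype=float).reshape(-1)
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")
        if not 0.0 <= self.w < 1.0:
            raise ValueError(f"outlier weight w must lie in [0, 1), got {self.w}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"priors must sum to 1, got {p.sum()}")
        self.priors = p


@dataclass
class RegistrationConfig:
    """Tunable parameters of the EM registration."""

    w: float = 0.1  # outlier mixture mass
    tol: float = 1e-6  # relative ΔQ stopping threshold
    max_iter: int = 150
    sigma2_floor: float = 1e-8  # mm²; guards against collapse
    allow_scale: bool = True  # similarity (True) vs rigid (False)
    scale_bounds: tuple[float, float] = (0.5, 2.0)
    use_weights: bool = True  # False forces uniform priors (standard CPD)
    init: str = "auto"  # "auto" (ellipsoid fit, identity fallback), "ellipsoid", "identity"
    monotone_sigma2: bool = True  # treat σ² as an annealing resolution: never re-inflate
    trim: bool = False  # drop no-counterpart points after the coarse init
    trim_factor: float = 3.0  # trim points with NN residual > factor × median


@dataclass
class RegistrationResult:
    transform: SimilarityTransform
    posterior: np.ndarray  # (M, N) final correspondence posterior
    q_trajectory: np.ndarray  # (iters,) Q per accepted iteration
    q_star_trajectory: np.ndarray  # (iters,) Q* per accepted iteration
    iterations: int
    converged: bool
    sigma2: float  # final isotropic variance, mm²
    message: str = field(default="")


def normalize_priors(posteriors_at_y: np.ndarray) -> np.ndarray:
    """Normalize classifier posteriors at the centroids into mixture priors.

    ``P(m)* = P(c=+1 | y_m) / λ`` with ``λ = Σ_k P(c=+1 | y_k)``.  Inputs must
    lie in [0, 1] and not all be zero.
    """
    p = np.asarray(posteriors_at_y, dtype=float).reshape(-1)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("classifier posteriors must lie in [0, 1]")
    lam = p.sum()
    if lam <= 0:
        raise ValueError(
            "degenerate weights: all classifier posteriors are zero; "
            "registration cannot proceed"
        )
    return p / lam


def _sq_dists(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(M, N) matrix of squared distances ‖x_n - y_m‖²."""
    diff = y[:, None, :] - x[None, :, :]
    return np.einsum("mnd,mnd->mn", diff, diff)


def _e_step_loglik(
    x: np.ndarray,
    y_transformed: np.ndarray,
    state: GMMState,
) -> tuple[np.ndarray, float]:
    """Posterior matrix plus the negative log-likelihood of the mixture.

    The negative log-likelihood E(Θ, σ²) = −Σ_n log p(x_n) falls out of the
    same stabilized column sums that the posterior needs, so it is returned
    alongside (it is the model's true objective, used to select the best
    iterate visited by the EM loop).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_transformed, dtype=float)
    priors = state.priors
    if priors.shape[0] != y.shape[0]:
        raise ValueError(
            f"{priors.shape[0]} priors for {y.shape[0]} centroids"
        )
    s2 = state.sigma2
    d2 = _sq_dists(x, y)  # (M, N)
    with np.errstate(divide="ignore"):
        log_num = np.log(priors)[:, None] - d2 / (2.0 * s2)
    col_max = log_num.max(axis=0, keepdims=True)
    if state.w > 0.0:
        # Outlier constant (w/(1-w)) (2πσ²)^{D/2} / N, folded into the
        # max-subtraction so far-outlying columns cannot overflow.
        log_c = (
            np.log(state.w)
            - np.log1p(-state.w)
            + 0.5 * _D * np.log(2.0 * np.pi * s2)
            - np.log(state.n_fixed)
        )
        col_max = np.maximum(col_max, log_c)
        expd = np.exp(log_num - col_max)
        denom = expd.sum(axis=0, keepdims=True) + np.exp(log_c - col_max)
    else:
        expd = np.exp(log_num - col_max)
        denom = expd.sum(axis=0, keepdims=True)
    # log p(x_n) up to the constants shared by all iterates:
    #   log[(1-w) Σ_m P(m)* g_m(x_n) + w/N] with g the normalized Gaussian.
    log_px = (
        np.log(denom[0])
        + col_max[0]
        - 0.5 * _D * np.log(2.0 * np.pi * s2)
        + np.log1p(-state.w)
    )
    return expd / denom, float(-log_px.sum())


def e_step(
    x: np.ndarray,
    y_transformed: np.ndarray,
    state: GMMState,
) -> np.ndarray:
    """Correspondence posterior matrix P(m | x_n), shape (M, N).

    Computed in log space with per-column max subtraction.  With w = 0 every
    column sums to exactly 1; with w > 0 the deficit 1 - column sum is the
    outlier mass of that fixed point.
    """
    return _e_step_loglik(x, y_transformed, state)[0]


def m_step_similarity(
    x: np.ndarray,
    y: np.ndarray,
    posterior: np.ndarray,
    allow_scale: bool = True,
    scale_bounds: tuple[float, float] = (0.5, 2.0),
    sigma2_floor: float = 1e-8,
) -> tuple[SimilarityTransform, float]:
    """Closed-form weighted Procrustes update of (R, s, t) and σ².

    Minimizes the EM objective for fixed correspondence posterior:
    posterior-weighted centroids, SVD of the weighted cross-covariance with
    the determinant-corrected rotation (det R = +1 always), the scale ratio
    tr(ΣC) over the weighted spread of Y (clamped; or s = 1 in rigid mode),
    and σ² from the weighted residual, floored.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p = np.asarray(posterior, dtype=float)
    n_p = p.sum()
    if n_p <= 0:
        raise ValueError("empty correspondence: posterior matrix sums to zero")
    px = p.sum(axis=0)  # (N,) mass per fixed point
    py = p.sum(axis=1)  # (M,) mass per centroid
    mu_x = px @ x / n_p
    mu_y = py @ y / n_p
    xc = x - mu_x
    yc = y - mu_y
    a = xc.T @ p.T @ yc  # (3, 3) weighted cross-covariance
    u, sv, vt = np.linalg.svd(a)
    c = np.ones(_D)
    c[-1] = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag(c) @ vt
    trace_sc = float(sv @ c)
    spread_y = float(py @ np.einsum("md,md->m", yc, yc))
    spread_x = float(px @ np.einsum("nd,nd->n", xc, xc))
    if allow_scale and spread_y > 0:
        s = trace_sc / spread_y
        s = float(np.clip(s, *scale_bounds))
    else:
        s = 1.0
    t = mu_x - s * rot @ mu_y
    # Generic residual: valid also when s is clamped or fixed at 1.
    resid = spread_x - 2.0 * s * trace_sc + s * s * spread_y
    sigma2 = max(resid / (n_p * _D), sigma2_floor)
    return SimilarityTransform(rotation=rot, scale=s, translation=t), sigma2


def objective_q(
    x: np.ndarray,
    y: np.ndarray,
    posterior: np.ndarray,
    state: GMMState,
    transform: SimilarityTransform,
) -> tuple[float, float]:
    """EM objective Q and its prior-augmented variant Q*.

    ``Q = (1/2σ²) ΣΣ P(m,n) ‖x_n - 𝒯(y_m)‖² + (D N_p / 2) log σ²`` and
    ``Q* = Q + ΣΣ P(m,n) log P(m)*`` (0·log 0 ≡ 0 where a prior vanishes).
    """
    x = np.asarray(x, dtype=float)
    yt = transform.apply(np.asarray(y, dtype=float))
    p = np.asarray(posterior, dtype=float)
    d2 = _sq_dists(x, yt)
    n_p = p.sum()
    q = float((p * d2).sum() / (2.0 * state.sigma2) + 0.5 * _D * n_p * np.log(state.sigma2))
    priors = state.priors
    pm = p.sum(axis=1)
    nz = priors > 0
    q_star = q + float(pm[nz] @ np.log(priors[nz]))
    return q, q_star


def apply_transform(
    cloud: WeightedPointCloud, transform: SimilarityTransform
) -> WeightedPointCloud:
    """Map a cloud's points through the transform; weights are unchanged."""
    return cloud.transformed(transform)


def _initial_sigma2(x: np.ndarray, y: np.ndarray) -> float:
    """σ²₀ = (1/(D M N)) ΣΣ ‖x_n - y_m‖², computed without the full matrix."""
    n, m = x.shape[0], y.shape[0]
    sx, sy = x.sum(axis=0), y.sum(axis=0)
    total = (
        m * np.einsum("nd,nd->", x, x)
        + n * np.einsum("md,md->", y, y)
        - 2.0 * sx @ sy
    )
    return float(total / (_D * m * n))


def _fit_ellipsoid(
    points: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted least-squares general-quadric (ellipsoid) fit.

    Returns ``(center, semi_axes, axes_matrix)`` with axes as the columns of
    a rotation-like orthonormal matrix, sorted by descending semi-axis.
    Raises ``ValueError`` when the best-fit quadric is not an ellipsoid.
    """
    x, y, z = points.T
    design = np.column_stack(
        [x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z, x, y, z,
         np.ones_like(x)]
    )
    if weights is not None:
        design = design * np.sqrt(np.asarray(weights, float))[:, None]
    _, sv, vt = np.linalg.svd(design, full_matrices=False)
    if sv[0] <= 0 or sv[-1] / sv[0] > 0.5:  # no clear quadric structure
        raise ValueError("degenerate quadric fit")
    v = vt[-1]
    q = np.array([[v[0], v[3], v[4]], [v[3], v[1], v[5]], [v[4], v[5], v[2]]])
    b = v[6:9]
    c = v[9]
    center = np.linalg.solve(-2.0 * q, b)
    k = center @ q @ center + b @ center + c
    if k == 0:
        raise ValueError("degenerate quadric fit")
    m = q / (-k)
    evals, evecs = np.linalg.eigh(m)
    if np.any(evals <= 0):  # hyperboloid/paraboloid: not an ellipsoid
        raise ValueError("best-fit quadric is not an ellipsoid")
    semi_axes = 1.0 / np.sqrt(evals)
    order = np.argsort(-semi_axes)
    return center, semi_axes[order], evecs[:, order]


def _ellipsoid_init(
    x: np.ndarray, y: np.ndarray, priors: np.ndarray
) -> SimilarityTransform:
    """Coarse alignment by fitting an ellipsoid to each cloud.

    The cranium shell is modelled as (two nested) ellipsoid surfaces, and a
    least-squares quadric fit recovers each cloud's centre and principal
    axes robustly even with large angular sectors of missing data — unlike
    raw second moments, which the missing sectors bias heavily.  The
    moving-cloud fit uses the membership priors as weights, so gross
    low-weight outliers barely influence it.  Axis correspondence leaves a
    four-fold proper-flip ambiguity; since the flips differ pairwise by
    180°, at most one candidate lies within 90° of the identity and that
    smallest-rotation candidate is chosen (the acquisitions are assumed
    oriented within a quarter turn of each other).  The result is
    equivariant under joint rigid motion of both clouds.
    """
    cx, _, ux = _fit_ellipsoid(x)
    cy, _, uy = _fit_ellipsoid(y, weights=priors * y.shape[0])
    parity = np.sign(np.linalg.det(ux) * np.linalg.det(uy))
    flips = (
        [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]
        if parity > 0
        else [(-1, 1, 1), (1, -1, 1), (1, 1, -1), (-1, -1, -1)]
    )
    best_rot, best_angle = np.eye(_D), np.inf
    for f in flips:
        rot = ux @ np.diag(f) @ uy.T
        angle = np.arccos(np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0))
        if angle < best_angle:
            best_rot, best_angle = rot, angle
    return SimilarityTransform(
        rotation=best_rot, translation=cx - best_rot @ cy
    )


def _nn_sigma2(x: np.ndarray, y_transformed: np.ndarray) -> float:
    """Median squared nearest-neighbour residual — the EM start scale after
    a coarse init.  The median keeps points facing the other acquisition's
    missing sectors (which have no true counterpart) from inflating the
    start scale back into the misleading coarse basins."""
    from scipy.spatial import cKDTree

    d = cKDTree(x).query(y_transformed)[0]
    return float(np.median(d) ** 2)


def register(
    fixed: WeightedPointCloud | np.ndarray,
    moving: WeightedPointCloud | np.ndarray,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Align the moving cloud onto the fixed cloud by EM.

    The moving cloud's weights (classifier posteriors) become the GMM
    membership priors; the fixed cloud's weights are ignored by the model.
    Both clouds are centred and scaled to unit RMS radius before EM and the
    recovered transform is mapped back to mm.  Returns the transform taking
    moving-frame points into the fixed frame plus diagnostics.
    """
    cfg = config or RegistrationConfig()
    if not isinstance(fixed, WeightedPointCloud):
        fixed = WeightedPointCloud(np.asarray(fixed, float), np.ones(len(fixed)))
    if not isinstance(moving, WeightedPointCloud):
        moving = WeightedPointCloud(np.asarray(moving, float), np.ones(len(moving)))
    if len(fixed) < 4 or len(moving) < 4:
        raise ValueError("registration needs at least 4 points in each cloud")

    if cfg.use_weights:
        priors = normalize_priors(moving.weights)
    else:
        priors = np.full(len(moving), 1.0 / len(moving))

    x_raw = fixed.points
    y_raw = moving.points
    mu_x, mu_y = x_raw.mean(axis=0), y_raw.mean(axis=0)
    sx = float(np.sqrt(np.mean(np.sum((x_raw - mu_x) ** 2, axis=1))))
    sy = float(np.sqrt(np.mean(np.sum((y_raw - mu_y) ** 2, axis=1))))
    sx = sx if sx > 0 else 1.0
    sy = sy if sy > 0 else 1.0
    x = (x_raw - mu_x) / sx
    y = (y_raw - mu_y) / sy

    n = x.shape[0]
    transform = None
    if cfg.init in ("auto", "ellipsoid") and min(len(fixed), len(moving)) >= 16:
        try:
            transform = _ellipsoid_init(x, y, priors)
            # EM resumes at the residual scale of the coarse fit.
            sigma2 = max(_nn_sigma2(x, transform.apply(y)), 1e-6)
        except (ValueError, np.linalg.LinAlgError):
            if cfg.init == "ellipsoid":
                raise
            transform = None
    elif cfg.init not in ("auto", "ellipsoid", "identity"):
        raise ValueError(
            f"unknown init {cfg.init!r} (use 'auto', 'ellipsoid' or 'identity')"
        )
    coarse_init_ok = transform is not None
    if transform is None:
        transform = SimilarityTransform.identity()
        sigma2 = _initial_sigma2(x, y)

    if cfg.trim and coarse_init_ok:
        # Partial-overlap trimming: points with no plausible counterpart
        # after the coarse alignment (e.g. facing the other acquisition's
        # occluded sector) are excluded from the EM estimation; the final
        # transform still applies to the full clouds.
        from scipy.spatial import cKDTree

        y0 = transform.apply(y)
        res_y = cKDTree(x).query(y0)[0]
        res_x = cKDTree(y0).query(x)[0]
        cut_y = cfg.trim_factor * np.median(res_y)
        cut_x = cfg.trim_factor * np.median(res_x)
        keep_y = res_y <= cut_y
        keep_x = res_x <= cut_x
        if keep_y.sum() >= 4 and keep_x.sum() >= 4:
            x = x[keep_x]
            y = y[keep_y]
            priors = priors[keep_y]
            psum = priors.sum()
            if psum <= 0:
                raise ValueError(
                    "degenerate weights: trimming removed all prior mass"
                )
            priors = priors / psum
            n = x.shape[0]
    # σ² floor transferred to the normalized frame.
    floor_norm = cfg.sigma2_floor / (sx * sx)
    scale_bounds = cfg.scale_bounds if cfg.allow_scale else (1.0, 1.0)

    q_traj: list[float] = []
    qs_traj: list[float] = []
    posterior = np.zeros((y.shape[0], n))
    best: tuple[float, SimilarityTransform, float, np.ndarray] | None = None
    converged = False
    message = ""
    it = 0
    for it in range(1, cfg.max_iter + 1):
        state = GMMState(sigma2=sigma2, w=cfg.w, priors=priors, n_fixed=n)
        posterior, neg_loglik = _e_step_loglik(x, transform.apply(y), state)
        if best is None or neg_loglik < best[0]:
            best = (neg_loglik, transform, sigma2, posterior)
        n_p = posterior.sum()
        if n_p <= 0:
            message = "empty correspondence: all mass assigned to outliers"
            break
        transform_new, sigma2_new = m_step_similarity(
            x,
            y,
            posterior,
            allow_scale=cfg.allow_scale,
            scale_bounds=scale_bounds,
            sigma2_floor=floor_norm,
        )
        if cfg.monotone_sigma2:
            # σ² acts as an annealing resolution: once the match has reached
            # a scale, re-inflating it would re-open coarse (and, for shells
            # with missing sectors, misleading) correspondence basins.
            sigma2_new = min(sigma2_new, sigma2)
        state_new = GMMState(sigma2=sigma2_new, w=cfg.w, priors=priors, n_fixed=n)
        q, q_star = objective_q(x, y, posterior, state_new, transform_new)
        if q_traj and q > q_traj[-1] + 1e-8 * max(1.0, abs(q_traj[-1])):
            # Safeguard: a step that raises the EM objective is rejected and
            # the iteration stops (the best-likelihood iterate is kept).
            converged = True
            message = "stopped at Q plateau"
            break
        transform, sigma2 = transform_new, sigma2_new
        q_traj.append(q)
        qs_traj.append(q_star)
        if len(q_traj) > 1:
            dq = abs(q_traj[-2] - q) / max(1.0, abs(q))
            if dq < cfg.tol:
                converged = True
                break
        if sigma2 <= floor_norm:
            converged = True
            message = "sigma2 reached its floor"
            break
    if not converged and not message:
        message = f"did not converge within {cfg.max_iter} iterations"

    # The returned solution is the iterate with the best model likelihood.
    if best is not None:
        state = GMMState(sigma2=sigma2, w=cfg.w, priors=priors, n_fixed=n)
        posterior, neg_loglik = _e_step_loglik(x, transform.apply(y), state)
        if neg_loglik <= best[0]:
            best = (neg_loglik, transform, sigma2, posterior)
        _, transform, sigma2, posterior = best

    # De-normalize: x_mm = mu_x + sx * ( s' R' (y_mm - mu_y)/sy + t' )
    s_mm = transform.scale * sx / sy
    r_mm = transform.rotation
    t_mm = mu_x + sx * transform.translation - s_mm * r_mm @ mu_y
    final = SimilarityTransform(rotation=r_mm, scale=s_mm, translation=t_mm)
    return RegistrationResult(
        transform=final,
        posterior=posterior,
        q_trajectory=np.asarray(q_traj),
        q_star_trajectory=np.asarray(qs_traj),
        iterations=it,
        converged=converged,
        sigma2=sigma2 * sx * sx,
        message=message,
    )
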