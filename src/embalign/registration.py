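"""Rigid alignment of an unlabeled snapshot to atlas slice templates.

The pose search follows a coarse-to-fine tournament. Both clouds are
centered and scaled by their median pairwise distance, the observation's
+/-PC1 axes are aligned to the reference PC1 axis (two seeds, resolving
PCA sign ambiguity), a discrete rotational sweep about the reference PC1
axis scores each orientation by the Sinkhorn-weighted sum of squared
Euclidean distances, and the top-k angular valleys (separated by at least
``min_valley_separation_deg``) seed a soft ICP loop that alternates
entropically regularized optimal transport with a weighted Kabsch update.
Candidates are scored by the total Mahalanobis cost of their optimal
one-to-one assignment; the winning slice/orientation supplies the labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator

from .atlas import AtlasSlice, EmbryoAtlas, SliceDatabase
from .config import RunConfig
from .io import ObservedFrame

log = logging.getLogger("embalign")


class DegenerateCloudError(ValueError):
    """Point cloud has no usable geometry (identical points)."""


class NoTemplateError(LookupError):
    """No atlas slice matches the observed cell count."""

    def __init__(self, observed_n: int, available: Sequence[int]):
        self.observed_n = observed_n
        self.available = sorted(available)
        nearest = min(self.available, key=lambda n: abs(n - observed_n)) if self.available else None
        self.nearest_n = nearest
        super().__init__(
            f"no atlas slice with N={observed_n} cells"
            + (f"; nearest available N is {nearest}" if nearest is not None else
               "; slice database is empty"))


# ---------------------------------------------------------------------------
# geometry primitives


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (normalized units)."""

    rotation: np.ndarray     # (3, 3), det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det +1, no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = R_s (R_o x + t_o) + t_s."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def normalize_cloud(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Center a cloud and scale it by its median pairwise distance.

    Returns (normalized points, original centroid, scale). After
    normalization the centroid is the origin and the median pairwise
    distance is 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need an (N>=2, 3) array of points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    scale = float(np.median(pdist(pts)))
    if scale <= 0:
        raise DegenerateCloudError("all points coincide; cloud has no scale")
    return centered / scale, centroid, scale


def principal_axis(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading principal axis of a centered cloud, with a deterministic sign.

    The sign is fixed so the axis component of largest magnitude is
    positive (first such component on ties). Returns (unit axis,
    eigenvalue gap between the two leading components).
    """
    pts = np.asarray(points, dtype=float)
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    k = int(np.argmax(np.abs(axis)))
    if axis[k] < 0:
        axis = -axis
    return axis, float(evals[-1] - evals[-2])


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal proper rotation taking unit vector a onto unit vector b."""
    a = np.asarray(a, dtype=float) / np.linalg.norm(a)
    b = np.asarray(b, dtype=float) / np.linalg.norm(b)
    v = np.cross(a, b)
    s, c = np.linalg.norm(v), float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: 180 degrees about a deterministic axis orthogonal to a
        helper = np.eye(3)[int(np.argmin(np.abs(a)))]
        axis = np.cross(a, helper)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(angle * v / s).as_matrix()


def pc1_seed_rotations(obs: np.ndarray, ref: np.ndarray) -> list[np.ndarray]:
    """Two seed rotations mapping the observation's +/-PC1 onto the reference PC1.

    Both are minimal (smallest-angle) proper rotations; the pair resolves
    the sign ambiguity of principal component analysis. An isotropic cloud
    (leading-eigenvalue tie) is handled with the deterministic axis-sign
    convention of :func:`principal_axis` and a logged warning.
    """
    a, gap_o = principal_axis(obs)
    b, gap_r = principal_axis(ref)
    if min(gap_o, gap_r) <= 1e-9:
        log.warning("pc1_seed_rotations: near-isotropic cloud (eigenvalue gap %.2e); "
                    "using deterministic axis convention", min(gap_o, gap_r))
    return [rotation_between(a, b), rotation_between(-a, b)]


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed (counter-clockwise viewed from the +axis tip) rotation."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()


# ---------------------------------------------------------------------------
# entropic optimal transport


@dataclass
class CorrespondenceMatrix:
    """Sinkhorn soft correspondence plan with uniform 1/N marginals."""

    plan: np.ndarray  # (N, N), non-negative, total mass 1
    converged: bool
    n_iters: int
    potentials: tuple[np.ndarray, np.ndarray] | None = None  # warm-start reuse

    def row_entropies(self) -> np.ndarray:
        """Shannon entropy (nats) of each plan row after renormalization."""
        rows = self.plan / np.maximum(self.plan.sum(axis=1, keepdims=True), 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(rows > 0, rows * np.log(rows), 0.0)
        return -terms.sum(axis=1)


def _logsumexp(x: np.ndarray, axis: int) -> np.ndarray:
    m = x.max(axis=axis, keepdims=True)
    out = np.log(np.exp(x - m).sum(axis=axis, keepdims=True))
    out += m
    return out.squeeze(axis)


def sinkhorn_plan(cost: np.ndarray, epsilon: float, max_iters: int = 1000,
                  tol: float = 1e-6,
                  init: tuple[np.ndarray, np.ndarray] | None = None
                  ) -> CorrespondenceMatrix:
    """Entropically regularized OT plan with uniform marginals, log domain.

    Solves for P = diag(u) exp(-C/eps) diag(v) with row and column sums
    1/N; iterates until the worst marginal violation is below ``tol`` or
    ``max_iters`` is reached (the ``converged`` flag records which).
    ``init`` warm-starts the dual potentials (e.g. from the previous
    refinement iteration).
    """
    C = np.asarray(cost, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("cost matrix must be square")
    if not np.all(np.isfinite(C)):
        raise ValueError("cost matrix contains non-finite entries")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if init is None:
        # epsilon scaling: warm-start the potentials through a short
        # geometric schedule; greatly accelerates convergence at small eps
        f0 = None
        eps_hot = max(epsilon, float(np.ptp(C)) / 2 or epsilon)
        while eps_hot > epsilon * 1.001:
            _, _, _, f, g = _sinkhorn_batch(C[None], eps_hot, 30, tol, f0)
            f0 = (f, g)
            eps_hot = max(epsilon, eps_hot / 4)
    else:
        f0 = (init[0][None], init[1][None])
    plan, converged, iters, f, g = _sinkhorn_batch(C[None], epsilon, max_iters,
                                                   tol, f0)
    return CorrespondenceMatrix(plan[0], bool(converged[0]), iters,
                                potentials=(f[0], g[0]))


def _sinkhorn_batch(C: np.ndarray, epsilon: float, max_iters: int, tol: float,
                    init: tuple[np.ndarray, np.ndarray] | None = None,
                    check_every: int = 5):
    """Vectorized log-domain Sinkhorn over a (B, N, N) stack of cost matrices."""
    B, N, _ = C.shape
    log_a = -np.log(N)
    Ke = C / epsilon  # scaled-potential domain: fe = f/eps, ge = g/eps
    fe = np.zeros((B, N)) if init is None else np.asarray(init[0], dtype=float) / epsilon
    ge = np.zeros((B, N)) if init is None else np.asarray(init[1], dtype=float) / epsilon
    it = 0
    for it in range(1, max_iters + 1):
        fe = log_a - _logsumexp(ge[:, None, :] - Ke, axis=2)
        ge = log_a - _logsumexp(fe[:, :, None] - Ke, axis=1)
        if it % check_every == 0 or it == max_iters:
            row_log = _logsumexp(fe[:, :, None] + ge[:, None, :] - Ke, axis=2)
            row_err = np.abs(np.exp(row_log) - 1.0 / N).max(axis=1)
            if row_err.max() <= tol:
                break
    P = np.exp(fe[:, :, None] + ge[:, None, :] - Ke)
    row_err = np.abs(P.sum(axis=2) - 1.0 / N).max(axis=1)
    col_err = np.abs(P.sum(axis=1) - 1.0 / N).max(axis=1)
    return P, np.maximum(row_err, col_err) <= tol, it, fe * epsilon, ge * epsilon


# ---------------------------------------------------------------------------
# coarse sweep and valley selection


@dataclass
class CostLandscape:
    """Sinkhorn-weighted squared-distance cost at each coarse sweep angle."""

    base_rotation: np.ndarray
    axis: np.ndarray            # sweep axis (reference PC1)
    angles: np.ndarray          # degrees, [0, 360)
    costs: np.ndarray


def _pairwise_sq(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances; supports a batched (B, N, 3) first arg."""
    diff = x[..., :, None, :] - y[None, :, :] if x.ndim == 3 else x[:, None, :] - y[None, :, :]
    return np.einsum("...ijk,...ijk->...ij", diff, diff)


def coarse_sweep(obs: np.ndarray, ref: np.ndarray, base_rotation: np.ndarray,
                 step_deg: float = 10.0, epsilon: float = 0.05,
                 axis: np.ndarray | None = None, max_iters: int = 200,
                 tol: float = 1e-6) -> CostLandscape:
    """Score every discrete rotation of obs about the reference PC1 axis.

    For each angle theta in [0, 360) the observation (after the base
    rotation) is rotated about the axis, a Sinkhorn plan is computed on
    the squared Euclidean cost matrix, and the plan-weighted total cost
    sum_ij P_ij ||x_i - mu_j||^2 is recorded.
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if obs.shape != ref.shape:
        raise ValueError(f"point counts differ: obs {obs.shape} vs ref {ref.shape}")
    if 360.0 % step_deg:
        raise ValueError("step_deg must divide 360")
    if axis is None:
        axis, _ = principal_axis(ref)
    angles = np.arange(0.0, 360.0, step_deg)
    based = obs @ base_rotation.T
    rots = Rotation.from_rotvec(
        np.deg2rad(angles)[:, None] * (axis / np.linalg.norm(axis))[None, :]).as_matrix()
    rotated = np.einsum("bij,nj->bni", rots, based)       # (B, N, 3)
    C = _pairwise_sq(rotated, ref)                        # (B, N, N)
    P, _, _, _, _ = _sinkhorn_batch(C, epsilon, max_iters, tol)
    costs = np.einsum("bij,bij->b", P, C)
    return CostLandscape(base_rotation, axis, angles, costs)


def select_valleys(landscape: CostLandscape, k: int = 3,
                   min_sep_deg: float = 30.0) -> list[float]:
    """Greedily pick up to k circular local minima separated by >= min_sep_deg.

    A valley is an angle whose cost is no greater than either circular
    neighbor and strictly below at least one (interior points of flat
    plateaus do not count). Valleys are sorted by ascending cost (angle
    breaks ties) and accepted only if their circular distance to every
    already-accepted angle is at least ``min_sep_deg``. A flat landscape
    yields the single global minimum.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if min_sep_deg <= 0:
        raise ValueError("min_sep_deg must be positive")
    costs = np.asarray(landscape.costs, dtype=float)
    angles = np.asarray(landscape.angles, dtype=float)
    n = len(costs)
    if np.allclose(costs, costs[0]):
        return [float(angles[int(np.argmin(costs))])]
    minima = [i for i in range(n)
              if costs[i] <= costs[(i - 1) % n] and costs[i] <= costs[(i + 1) % n]
              and (costs[i] < costs[(i - 1) % n] or costs[i] < costs[(i + 1) % n])]
    minima.sort(key=lambda i: (costs[i], angles[i]))
    chosen: list[float] = []
    for i in minima:
        a = float(angles[i])
        sep = [min(abs(a - b), 360.0 - abs(a - b)) for b in chosen]
        if all(s >= min_sep_deg for s in sep):
            chosen.append(a)
        if len(chosen) == k:
            break
    return chosen


# ---------------------------------------------------------------------------
# weighted Kabsch and soft-ICP refinement


def weighted_kabsch(obs: np.ndarray, ref: np.ndarray,
                    weights: np.ndarray) -> RigidTransform:
    """Optimal proper rigid motion under a soft correspondence plan.

    Minimizes sum_ij P_ij ||R x_i + t - mu_j||^2 in closed form via the
    SVD of the plan-weighted cross-covariance, with the determinant
    correction that forbids reflections.
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    P = np.asarray(weights, dtype=float)
    if np.any(P < 0):
        raise ValueError("plan weights must be non-negative")
    mass = P.sum()
    if mass <= 0:
        raise ValueError("plan has zero total mass")
    x_bar = (P.sum(axis=1) @ obs) / mass
    y_bar = (P.sum(axis=0) @ ref) / mass
    H = (obs - x_bar).T @ P @ (ref - y_bar)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, y_bar - R @ x_bar)


@dataclass
class AlignmentCandidate:
    """One refined pose hypothesis (slice x PC1 seed x valley angle)."""

    seed_angle: float
    transform: RigidTransform
    plan: CorrespondenceMatrix
    trace: list[float]
    converged: bool

    @property
    def final_cost(self) -> float:
        return self.trace[-1]

    @property
    def best_cost(self) -> float:
        return min(self.trace)


def refine_alignment(obs: np.ndarray, ref: np.ndarray, seed_angle: float,
                     base_rotation: np.ndarray, config: RunConfig,
                     axis: np.ndarray | None = None) -> AlignmentCandidate:
    """Soft ICP: alternate Sinkhorn correspondence and weighted Kabsch.

    The regularization strength anneals geometrically from
    ``sinkhorn_epsilon`` to ``sinkhorn_epsilon_min`` so the plan sharpens
    toward a permutation as the pose locks in; the best (lowest-cost)
    iterate is returned even if a later step increased the cost, so the
    result is never worse than the seed orientation.
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if obs.shape != ref.shape:
        raise ValueError("refine_alignment requires equal point counts")
    if axis is None:
        axis, _ = principal_axis(ref)
    R = rotation_about_axis(axis, seed_angle) @ base_rotation
    t = np.zeros(3)
    eps = config.sinkhorn_epsilon
    trace: list[float] = []
    best: tuple[float, RigidTransform, CorrespondenceMatrix] | None = None
    prev_cost = np.inf
    converged = False
    warm = None
    for _ in range(config.refine_max_iters):
        moved = obs @ R.T + t
        C = _pairwise_sq(moved, ref)
        plan = sinkhorn_plan(C, eps, config.sinkhorn_max_iters,
                             config.sinkhorn_tol, init=warm)
        warm = plan.potentials
        cost = float((plan.plan * C).sum())
        trace.append(cost)
        if best is None or cost < best[0]:
            best = (cost, RigidTransform(R, t), plan)
        at_floor = eps <= config.sinkhorn_epsilon_min * (1 + 1e-9)
        if at_floor and prev_cost - cost < config.refine_tol:
            converged = True
            break
        prev_cost = cost
        T = weighted_kabsch(obs, ref, plan.plan)
        R, t = T.rotation, T.translation
        eps = max(eps * config.sinkhorn_anneal, config.sinkhorn_epsilon_min)
    _, transform, plan = best
    return AlignmentCandidate(seed_angle, transform, plan, trace, converged)


# ---------------------------------------------------------------------------
# scoring and label transfer


def mahalanobis_cost_matrix(aligned_obs: np.ndarray, means: np.ndarray,
                            covariances: np.ndarray) -> np.ndarray:
    """Mahalanobis distance of each observed point to each template Gaussian."""
    x = np.asarray(aligned_obs, dtype=float)
    mu = np.asarray(means, dtype=float)
    cov = np.asarray(covariances, dtype=float)
    np.linalg.cholesky(cov)  # raises LinAlgError if any template is not SPD
    inv = np.linalg.inv(cov)
    diff = x[:, None, :] - mu[None, :, :]
    d2 = np.einsum("nmi,mij,nmj->nm", diff, inv, diff)
    return np.sqrt(np.maximum(d2, 0.0))


def assign_labels(cost: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimum-cost one-to-one assignment (Hungarian / linear sum assignment).

    Returns (perm, total) where observed point i is assigned to template
    column perm[i].
    """
    C = np.asarray(cost, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"cost matrix must be square, got {C.shape}")
    if not np.all(np.isfinite(C)):
        raise ValueError("cost matrix contains non-finite entries")
    rows, cols = linear_sum_assignment(C)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm, float(C[rows, cols].sum())


@dataclass
class FrameResult:
    """Outcome of aligning one frame: winner, labels, scores and all traces."""

    frame: ObservedFrame
    slice: AtlasSlice
    candidate: AlignmentCandidate
    assigned_names: list[str]
    assignment: np.ndarray        # perm: observed i -> slice column perm[i]
    cost_matrix: np.ndarray       # full winning Mahalanobis matrix (N, N)
    mahalanobis: np.ndarray       # per observed cell, winning assignment
    entropies: np.ndarray         # Sinkhorn row entropies, winning plan
    total_cost: float             # sum of assigned Mahalanobis distances
    obs_centroid: np.ndarray
    obs_scale: float
    ref_centroid: np.ndarray
    ref_scale: float
    candidates: list[dict] = field(default_factory=list)   # all tournament entries
    landscapes: list[CostLandscape] = field(default_factory=list)
    confidences: np.ndarray | None = None
    frame_confidence: float | None = None

    @property
    def t_med(self) -> float:
        return self.slice.t_med


def align_frame(obs: ObservedFrame, db: SliceDatabase,
                config: RunConfig | None = None) -> FrameResult:
    """Register a snapshot against every same-N slice and transfer labels.

    Runs the full tournament {candidate slices} x {+/-PC1 seeds} x
    {top-k valley angles}; each candidate is refined and scored by the
    total Mahalanobis cost of its optimal assignment. Strict N equality
    is enforced — a missing template raises :class:`NoTemplateError`
    rather than silently padding or trimming.
    """
    config = config or RunConfig()
    n = obs.n_cells
    slices = db.get(n)
    if not slices:
        raise NoTemplateError(n, db.counts())
    obs_n, obs_centroid, obs_scale = normalize_cloud(obs.positions)

    best = None  # (total_cost, payload)
    summaries: list[dict] = []
    landscapes: list[CostLandscape] = []
    for s_idx, sl in enumerate(slices):
        ref_n, ref_centroid, ref_scale = normalize_cloud(sl.means)
        covs_n = sl.covariances / ref_scale**2
        axis, _ = principal_axis(ref_n)
        for seed_idx, base in enumerate(pc1_seed_rotations(obs_n, ref_n)):
            landscape = coarse_sweep(obs_n, ref_n, base, config.sweep_step_deg,
                                     config.sinkhorn_epsilon, axis,
                                     config.sinkhorn_max_iters, config.sinkhorn_tol)
            landscapes.append(landscape)
            for angle in select_valleys(landscape, config.k_seeds,
                                        config.min_valley_separation_deg):
                cand = refine_alignment(obs_n, ref_n, angle, base, config, axis)
                aligned = cand.transform.apply(obs_n)
                M = mahalanobis_cost_matrix(aligned, ref_n, covs_n)
                if config.plan_weighted_assignment:
                    selection_cost_matrix = (n * cand.plan.plan) * M
                else:
                    selection_cost_matrix = M
                perm, total = assign_labels(selection_cost_matrix)
                per_cell = M[np.arange(n), perm]
                summaries.append({
                    "slice_index": s_idx,
                    "slice_cells": sl.cell_names,
                    "seed_index": seed_idx,
                    "seed_angle": angle,
                    "final_cost": total,
                    "refine_trace": list(cand.trace),
                    "converged": cand.converged,
                })
                key = (total, s_idx, seed_idx, angle)
                if best is None or key < best[0]:
                    best = (key, (sl, cand, perm, per_cell, M,
                                  ref_centroid, ref_scale))

    (_, (sl, cand, perm, per_cell, M, ref_centroid, ref_scale)) = best
    names = [sl.cell_names[j] for j in perm]
    entropies = cand.plan.row_entropies()
    summaries.sort(key=lambda d: d["final_cost"])
    return FrameResult(
        frame=obs, slice=sl, candidate=cand, assigned_names=names,
        assignment=perm, cost_matrix=M,
        mahalanobis=per_cell, entropies=entropies,
        total_cost=float(per_cell.sum()),
        obs_centroid=obs_centroid, obs_scale=obs_scale,
        ref_centroid=ref_centroid, ref_scale=ref_scale,
        candidates=summaries, landscapes=landscapes)


# ---------------------------------------------------------------------------
# estimator facade


class FrameAligner(BaseEstimator):
    """sklearn-style facade: fit an atlas from labeled frames, predict labels.

    Parameters mirror :class:`RunConfig` plus an optional prefit
    ``atlas``. ``predict`` returns the list of assigned lineage names for
    a single frame (or a list of lists for a sequence of frames);
    ``align`` exposes the full :class:`FrameResult`.
    """

    def __init__(self, atlas: EmbryoAtlas | None = None,
                 config: RunConfig | None = None,
                 reference_embryo: str | None = None):
        self.atlas = atlas
        self.config = config
        self.reference_embryo = reference_embryo

    def fit(self, X: Sequence[ObservedFrame], y=None) -> "FrameAligner":
        cfg = self.config or RunConfig()
        if self.atlas is not None:
            self.atlas_ = self.atlas
        else:
            self.atlas_ = EmbryoAtlas(
                reference_embryo=self.reference_embryo,
                time_bin_width=cfg.time_bin_width,
                covariance_jitter=cfg.covariance_jitter,
                gp_restarts=cfg.gp_restarts,
                random_state=cfg.random_seed).fit(X)
        self.config_ = cfg
        return self

    def align(self, frame: ObservedFrame) -> FrameResult:
        if not hasattr(self, "atlas_"):
            raise RuntimeError("FrameAligner is not fitted")
        return align_frame(frame, self.atlas_.slice_db_, self.config_)

    def predict(self, X):
        if isinstance(X, ObservedFrame):
            return self.align(X).assigned_names
        return [self.align(f).assigned_names for f in X]
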