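"""Spatiotemporal atlas construction.

The atlas turns a cohort of lineage-labeled centroid time series into:

* a canonical developmental time axis (dynamic time warping of each
  embryo's cell-count curve onto a reference embryo's),
* one Gaussian-process trajectory model per cell and axis (RBF + white
  kernel), giving expected position and uncertainty at any canonical time,
* a database of empirically observed "slices" — sets of co-existing cell
  identities keyed by cell count N — inflated at the midpoint of their
  shared existence window into 3D Gaussian reference templates,
* an empirical growth curve (mean/sd of cell count per canonical-time bin)
  used for staging diagnostics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .io import ObservedFrame

log = logging.getLogger("embalign")


class FitError(ValueError):
    """Trajectory model cannot be fitted from the given samples."""


class OutOfWindowError(ValueError):
    """Canonical time outside a cell's lifespan."""


class InconsistentSliceError(ValueError):
    """Slice members have no overlapping existence window."""


# ---------------------------------------------------------------------------
# canonical time via dynamic time warping


def dtw_align(a: np.ndarray, b: np.ndarray) -> tuple[float, list[tuple[int, int]]]:
    """Optimal monotone alignment of two 1D sequences.

    Symmetric step pattern (diagonal, insertion, deletion), absolute
    difference local cost. Returns the total path cost and the warping
    path as (i, j) index pairs from (0, 0) to (n-1, m-1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    local = np.abs(a[:, None] - b[None, :])
    acc = np.full((n, m), np.inf)
    acc[0, 0] = local[0, 0]
    for i in range(n):
        for j in range(m):
            if i == j == 0:
                continue
            best = np.inf
            if i and j:
                best = acc[i - 1, j - 1]
            if i:
                best = min(best, acc[i - 1, j])
            if j:
                best = min(best, acc[i, j - 1])
            acc[i, j] = local[i, j] + best
    # backtrack, preferring the diagonal step on ties
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        candidates = []
        if i and j:
            candidates.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i:
            candidates.append((acc[i - 1, j], (i - 1, j)))
        if j:
            candidates.append((acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(candidates, key=lambda c: c[0])
        path.append((i, j))
    path.reverse()
    return float(acc[n - 1, m - 1]), path


@dataclass
class TimeWarp:
    """Monotone map from one embryo's frame indices to canonical time."""

    embryo_id: str
    frames: np.ndarray          # source frame indices, ascending
    canonical_times: np.ndarray  # matched canonical times, non-decreasing
    path_cost: float

    def __call__(self, frame) -> np.ndarray | float:
        """Canonical time for a frame index (linear interpolation between knots)."""
        out = np.interp(frame, self.frames, self.canonical_times)
        return float(out) if np.isscalar(frame) else out


def _as_frame_count_arrays(seq) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(seq, dtype=float)
    if arr.ndim == 1:
        return np.arange(len(arr), dtype=float), arr
    if arr.ndim == 2 and arr.shape[1] == 2:
        order = np.argsort(arr[:, 0], kind="stable")
        return arr[order, 0], arr[order, 1]
    raise ValueError("expected a sequence of counts or of (frame, count) pairs")


def warp_to_canonical_time(query_counts, reference_counts,
                           embryo_id: str = "") -> TimeWarp:
    """Stage an embryo by warping its cell-count curve onto the reference's.

    Canonical time is the reference embryo's frame axis; a query frame
    matched to several reference frames maps to their mean.
    """
    q_frames, q_counts = _as_frame_count_arrays(query_counts)
    r_frames, r_counts = _as_frame_count_arrays(reference_counts)
    if len(q_counts) < 2 or len(r_counts) < 2:
        raise ValueError("both count sequences must have length >= 2")
    if np.any(q_counts <= 0) or np.any(r_counts <= 0):
        raise ValueError("cell counts must be positive")
    cost, path = dtw_align(q_counts, r_counts)
    matched: dict[int, list[float]] = {}
    for i, j in path:
        matched.setdefault(i, []).append(r_frames[j])
    canonical = np.array([np.mean(matched[i]) for i in range(len(q_frames))])
    return TimeWarp(embryo_id, q_frames, canonical, cost)


# ---------------------------------------------------------------------------
# per-cell Gaussian-process trajectory models


def _make_kernel(span: float, fixed: Mapping[str, float] | None = None):
    if fixed is not None:
        return (ConstantKernel(fixed.get("rbf_variance", 1.0), "fixed")
                * RBF(fixed.get("length_scale", max(span / 3, 1.0)), "fixed")
                + WhiteKernel(fixed.get("white_variance", 1e-6), "fixed"))
    lo = min(1.0, span / 2)
    return (ConstantKernel(1.0, (1e-6, 1e3))
            * RBF(max(span / 3, lo), (lo, max(span, lo * (1 + 1e-9))))
            + WhiteKernel(1e-2, (1e-6, 1e3)))


@dataclass
class CellTrajectoryModel:
    """Per-axis GP posterior over one cell's position on the canonical axis.

    ``empirical_variance`` holds the per-axis variance of the cell's
    residuals from the GP mean across training embryos; it is aggregated
    additively with the GP posterior variance by
    :func:`total_positional_variance`.
    """

    cell_name: str
    times: np.ndarray            # (n,) canonical sample times
    positions: np.ndarray        # (n, 3) micrometers
    gps: list                    # three fitted GaussianProcessRegressor
    empirical_variance: np.ndarray = field(default_factory=lambda: np.zeros(3))
    t_birth: float = 0.0
    t_division: float = 0.0

    def mean(self, t) -> np.ndarray:
        """Posterior mean position(s) at canonical time(s) t; shape (..., 3)."""
        tq = np.atleast_1d(np.asarray(t, dtype=float)).reshape(-1, 1)
        out = np.column_stack([gp.predict(tq) for gp in self.gps])
        return out[0] if np.isscalar(t) else out

    def variance(self, t) -> np.ndarray:
        """Posterior variance per axis at canonical time(s) t; shape (..., 3)."""
        tq = np.atleast_1d(np.asarray(t, dtype=float)).reshape(-1, 1)
        out = np.column_stack([gp.predict(tq, return_std=True)[1] ** 2 for gp in self.gps])
        return out[0] if np.isscalar(t) else out

    @property
    def lifespan(self) -> tuple[float, float]:
        return (self.t_birth, self.t_division)


def fit_cell_trajectory(samples, empirical_variance=None, *, cell_name: str = "",
                        restarts: int = 3, random_state: int = 0,
                        fixed_hyperparams: Mapping[str, float] | None = None
                        ) -> CellTrajectoryModel:
    """Fit independent 1D GPs (RBF + white kernel) to a cell's trajectory.

    ``samples`` is a sequence of (canonical_time, 3-vector) pairs or a
    (times, positions) tuple. Hyperparameters are optimized by marginal
    likelihood with restarts unless ``fixed_hyperparams`` pins them.
    The cell's lifespan is the sampled time span.
    """
    if isinstance(samples, tuple) and len(samples) == 2:
        times = np.asarray(samples[0], dtype=float)
        positions = np.asarray(samples[1], dtype=float)
    else:
        samples = list(samples)
        times = np.array([s[0] for s in samples], dtype=float)
        positions = np.array([s[1] for s in samples], dtype=float)
    if times.ndim != 1 or positions.shape != (len(times), 3):
        raise FitError("samples must pair scalar times with 3-vector positions")
    if len(times) < 2:
        raise FitError(f"need >= 2 samples to fit a trajectory, got {len(times)}")
    span = float(times.max() - times.min())
    if span <= 0:
        raise FitError("all sample times are identical; trajectory is degenerate")

    gps = []
    for axis in range(3):
        gp = GaussianProcessRegressor(
            kernel=_make_kernel(span, fixed_hyperparams),
            n_restarts_optimizer=0 if fixed_hyperparams is not None else restarts,
            optimizer=None if fixed_hyperparams is not None else "fmin_l_bfgs_b",
            normalize_y=True,
            alpha=1e-10,
            random_state=random_state + axis,
        )
        with warnings.catch_warnings():
            # hyperparameters legitimately sit on their bounds for
            # near-static or near-linear trajectories
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(times.reshape(-1, 1), positions[:, axis])
        gps.append(gp)

    model = CellTrajectoryModel(
        cell_name=cell_name, times=times, positions=positions, gps=gps,
        t_birth=float(times.min()), t_division=float(times.max()))
    if empirical_variance is None:
        resid = positions - model.mean(times)
        empirical_variance = resid.var(axis=0)
    model.empirical_variance = np.asarray(empirical_variance, dtype=float)
    return model


def total_positional_variance(model: CellTrajectoryModel, t: float,
                              jitter: float = 1e-6) -> np.ndarray:
    """Aggregate GP posterior and empirical variance into a 3x3 covariance.

    Diagonal covariance ``diag(v_axis(t) + s2_axis) + jitter * I``; the
    jitter floor keeps it symmetric positive definite.
    """
    if not (model.t_birth <= t <= model.t_division):
        raise OutOfWindowError(
            f"t={t} outside lifespan [{model.t_birth}, {model.t_division}] of {model.cell_name!r}")
    return np.diag(model.variance(float(t)) + model.empirical_variance + jitter)


# ---------------------------------------------------------------------------
# slice database


@dataclass
class AtlasSlice:
    """An empirically observed set of co-existing cell identities.

    Uninflated slices carry only the membership and the canonical times at
    which the combination was observed; inflation fills the existence
    window, its midpoint t_med, and per-cell Gaussian templates there.
    """

    cell_names: tuple[str, ...]
    observed_times: list[float] = field(default_factory=list)
    t_start: float | None = None
    t_end: float | None = None
    t_med: float | None = None
    means: np.ndarray | None = None        # (N, 3)
    covariances: np.ndarray | None = None  # (N, 3, 3)

    @property
    def n(self) -> int:
        return len(self.cell_names)

    @property
    def inflated(self) -> bool:
        return self.means is not None


class SliceDatabase:
    """Slices grouped by cell count N; membership sets are unique per N."""

    def __init__(self):
        self._by_n: dict[int, list[AtlasSlice]] = {}
        self._seen: set[frozenset] = set()

    def add(self, sl: AtlasSlice) -> bool:
        key = frozenset(sl.cell_names)
        if key in self._seen:
            existing = next(s for s in self._by_n[sl.n]
                            if frozenset(s.cell_names) == key)
            existing.observed_times.extend(sl.observed_times)
            return False
        self._seen.add(key)
        self._by_n.setdefault(sl.n, []).append(sl)
        return True

    def get(self, n: int) -> list[AtlasSlice]:
        return self._by_n.get(n, [])

    def counts(self) -> list[int]:
        return sorted(self._by_n)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_n.values())

    def __iter__(self):
        for n in sorted(self._by_n):
            yield from self._by_n[n]

    def member_sets(self) -> set[frozenset]:
        return set(self._seen)


def extract_slice_database(labeled_frames: Sequence[ObservedFrame]) -> SliceDatabase:
    """Collect the distinct co-existing label sets from fully labeled frames.

    Frames must be fully labeled; each frame contributes its label set
    under key N = frame cell count, with duplicates collapsed and the
    observation's canonical time recorded (frame index if unstaged).
    """
    db = SliceDatabase()
    for f in labeled_frames:
        if not f.is_labeled:
            raise ValueError(
                f"frame {f.embryo_id}/{f.frame_index} contains unlabeled cells; "
                "slice extraction needs fully labeled frames")
        t = f.canonical_time if f.canonical_time is not None else float(f.frame_index)
        db.add(AtlasSlice(tuple(sorted(f.cell_names)), observed_times=[t]))
    return db


def inflate_slice(cell_names: Sequence[str],
                  trajectories: Mapping[str, CellTrajectoryModel],
                  jitter: float = 1e-6,
                  observed_times: Sequence[float] | None = None) -> AtlasSlice:
    """Turn a membership set into a 3D Gaussian reference template.

    The existence window is the intersection of member lifespans; the GP
    atlas is queried at its midpoint t_med for expected positions, and
    total positional variance supplies each cell's covariance.
    """
    names = tuple(sorted(cell_names))
    missing = [n for n in names if n not in trajectories]
    if missing:
        raise KeyError(f"slice members absent from atlas: {missing}")
    models = [trajectories[n] for n in names]
    t_start = max(m.t_birth for m in models)
    t_end = min(m.t_division for m in models)
    if t_start > t_end:
        raise InconsistentSliceError(
            f"members {names} share no existence window "
            f"(max birth {t_start} > min division {t_end})")
    t_med = 0.5 * (t_start + t_end)
    means = np.stack([m.mean(t_med) for m in models])
    covs = np.stack([total_positional_variance(m, t_med, jitter) for m in models])
    return AtlasSlice(names, list(observed_times or []), t_start, t_end, t_med,
                      means, covs)


# ---------------------------------------------------------------------------
# growth curve


@dataclass
class GrowthCurve:
    """Mean/sd of total cell count per canonical-time bin (population sd)."""

    bin_width: float
    bin_starts: np.ndarray  # ascending, one per non-empty bin
    means: np.ndarray
    sds: np.ndarray
    counts: np.ndarray      # frames per bin

    @property
    def span(self) -> tuple[float, float]:
        return (float(self.bin_starts[0]), float(self.bin_starts[-1] + self.bin_width))

    def bin_index_for(self, t: float) -> int | None:
        """Index of the bin containing t, or None if t falls outside every bin."""
        idx = np.flatnonzero((self.bin_starts <= t) & (t < self.bin_starts + self.bin_width))
        return int(idx[0]) if idx.size else None


def build_growth_curve(labeled_frames: Sequence[ObservedFrame],
                       bin_width: float = 1.0) -> GrowthCurve:
    """Bin frames by canonical time; summarize total cell count per bin."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    frames = list(labeled_frames)
    if not frames:
        raise ValueError("need at least one frame")
    times = np.array([f.canonical_time if f.canonical_time is not None
                      else float(f.frame_index) for f in frames])
    ns = np.array([f.n_cells for f in frames], dtype=float)
    bins = np.floor(times / bin_width).astype(int)
    starts, means, sds, counts = [], [], [], []
    for b in np.unique(bins):
        sel = ns[bins == b]
        starts.append(b * bin_width)
        means.append(sel.mean())
        sds.append(sel.std())  # population sd; 0 for singleton bins
        counts.append(len(sel))
    return GrowthCurve(bin_width, np.array(starts, dtype=float), np.array(means),
                       np.array(sds), np.array(counts, dtype=int))


# ---------------------------------------------------------------------------
# the estimator


class EmbryoAtlas(BaseEstimator):
    """Spatiotemporal atlas fitted from labeled centroid cohorts.

    Parameters
    ----------
    reference_embryo : str or None
        Embryo whose frame axis defines canonical time. Defaults to the
        first embryo encountered in the training frames.
    time_bin_width : float
        Growth-curve bin width in canonical frames.
    covariance_jitter : float
        Variance floor (um^2) added to every template covariance diagonal.
    gp_restarts : int
        Marginal-likelihood optimizer restarts per cell and axis.
    random_state : int
        Seed for the GP hyperparameter restarts.

    Attributes (after ``fit``)
    --------------------------
    trajectories_ : dict[str, CellTrajectoryModel]
    slice_db_ : SliceDatabase (inflated slices)
    growth_curve_ : GrowthCurve
    warps_ : dict[str, TimeWarp]
    frames_ : list[ObservedFrame]  (copies carrying canonical times)
    reference_embryo_ : str
    """

    def __init__(self, reference_embryo: str | None = None,
                 time_bin_width: float = 1.0, covariance_jitter: float = 1e-6,
                 gp_restarts: int = 3, random_state: int = 0):
        self.reference_embryo = reference_embryo
        self.time_bin_width = time_bin_width
        self.covariance_jitter = covariance_jitter
        self.gp_restarts = gp_restarts
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, frames: Sequence[ObservedFrame], y=None) -> "EmbryoAtlas":
        frames = list(frames)
        if not frames:
            raise ValueError("no training frames")
        for f in frames:
            if not f.is_labeled:
                raise ValueError(
                    f"training frame {f.embryo_id}/{f.frame_index} has unlabeled cells")

        by_embryo: dict[str, list[ObservedFrame]] = {}
        for f in frames:
            by_embryo.setdefault(f.embryo_id, []).append(f)
        for fs in by_embryo.values():
            fs.sort(key=lambda f: f.frame_index)

        ref = self.reference_embryo or next(iter(by_embryo))
        if ref not in by_embryo:
            raise ValueError(f"reference embryo {ref!r} not in training data")
        ref_counts = [(f.frame_index, f.n_cells) for f in by_embryo[ref]]

        self.warps_ = {}
        self.frames_ = []
        for eid, fs in by_embryo.items():
            counts = [(f.frame_index, f.n_cells) for f in fs]
            warp = warp_to_canonical_time(counts, ref_counts, embryo_id=eid)
            self.warps_[eid] = warp
            for f in fs:
                self.frames_.append(replace(f, canonical_time=warp(f.frame_index)))

        # gather per-cell samples on the canonical axis
        samples: dict[str, list[tuple[float, np.ndarray]]] = {}
        for f in self.frames_:
            for r in f.records:
                samples.setdefault(r.cell_name, []).append((f.canonical_time, r.position))

        self.trajectories_ = {}
        skipped: set[str] = set()
        for idx, (name, pts) in enumerate(sorted(samples.items())):
            ts = np.array([p[0] for p in pts])
            if len(pts) < 2 or ts.max() - ts.min() <= 0:
                skipped.add(name)
                continue
            self.trajectories_[name] = fit_cell_trajectory(
                pts, cell_name=name, restarts=self.gp_restarts,
                random_state=self.random_state + 1000 * idx)
        if skipped:
            log.warning("atlas: skipping %d cell(s) with <2 usable samples: %s",
                        len(skipped), sorted(skipped)[:10])

        raw_db = extract_slice_database(self.frames_)
        self.slice_db_ = SliceDatabase()
        for sl in raw_db:
            if skipped.intersection(sl.cell_names):
                log.warning("atlas: dropping slice with unmodeled member(s): N=%d", sl.n)
                continue
            self.slice_db_.add(inflate_slice(sl.cell_names, self.trajectories_,
                                             self.covariance_jitter, sl.observed_times))

        self.growth_curve_ = build_growth_curve(self.frames_, self.time_bin_width)
        self.reference_embryo_ = ref
        return self

    # -- serialization -----------------------------------------------------

    def _to_dict(self) -> dict:
        cells = {}
        for name, m in self.trajectories_.items():
            cells[name] = {
                "times": m.times.tolist(),
                "positions": m.positions.tolist(),
                "empirical_variance": m.empirical_variance.tolist(),
                "theta": [gp.kernel_.theta.tolist() for gp in m.gps],
                "t_birth": m.t_birth, "t_division": m.t_division,
            }
        slices = [{
            "cell_names": list(sl.cell_names),
            "observed_times": list(map(float, sl.observed_times)),
            "t_start": sl.t_start, "t_end": sl.t_end, "t_med": sl.t_med,
            "means": sl.means.tolist(),
            "covariances": sl.covariances.tolist(),
        } for sl in self.slice_db_]
        gc = self.growth_curve_
        return {
            "params": self.get_params(),
            "reference_embryo": self.reference_embryo_,
            "cells": cells,
            "slices": slices,
            "growth_curve": {"bin_width": gc.bin_width,
                             "bin_starts": gc.bin_starts.tolist(),
                             "means": gc.means.tolist(), "sds": gc.sds.tolist(),
                             "counts": gc.counts.tolist()},
        }

    @classmethod
    def _from_dict(cls, data: dict) -> "EmbryoAtlas":
        atlas = cls(**data["params"])
        atlas.reference_embryo_ = data["reference_embryo"]
        atlas.warps_ = {}
        atlas.frames_ = []
        atlas.trajectories_ = {}
        for name, c in data["cells"].items():
            times = np.asarray(c["times"], dtype=float)
            positions = np.asarray(c["positions"], dtype=float)
            gps = []
            for axis in range(3):
                theta = np.exp(np.asarray(c["theta"][axis], dtype=float))
                fixed = {"rbf_variance": theta[0], "length_scale": theta[1],
                         "white_variance": theta[2]}
                gp = GaussianProcessRegressor(
                    kernel=_make_kernel(1.0, fixed), optimizer=None,
                    normalize_y=True, alpha=1e-10)
                gp.fit(times.reshape(-1, 1), positions[:, axis])
                gps.append(gp)
            atlas.trajectories_[name] = CellTrajectoryModel(
                cell_name=name, times=times, positions=positions, gps=gps,
                empirical_variance=np.asarray(c["empirical_variance"], dtype=float),
                t_birth=c["t_birth"], t_division=c["t_division"])
        atlas.slice_db_ = SliceDatabase()
        for s in data["slices"]:
            atlas.slice_db_.add(AtlasSlice(
                tuple(s["cell_names"]), list(s["observed_times"]),
                s["t_start"], s["t_end"], s["t_med"],
                np.asarray(s["means"], dtype=float),
                np.asarray(s["covariances"], dtype=float)))
        gc = data["growth_curve"]
        atlas.growth_curve_ = GrowthCurve(
            gc["bin_width"], np.asarray(gc["bin_starts"], dtype=float),
            np.asarray(gc["means"], dtype=float), np.asarray(gc["sds"], dtype=float),
            np.asarray(gc["counts"], dtype=int))
        return atlas
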