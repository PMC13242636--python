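"""Synthetic ground-truth lineage cohorts.

Emulates the statistical structure the atlas assumes about early
C. elegans development: a binary division tree with near-synchronous
division waves, stereotyped smooth 3D trajectories confined to an
ellipsoidal embryo volume, embryo-to-embryo clock dilation, small
per-cell positional offsets, measurement noise, arbitrary rigid pose and
optional nucleus dropout. Names follow a Sulston-like binary scheme
("P0a", "P0ap", ...); they are synthetic, not real lineage identities.

All randomness flows from a single integer seed: the lineage uses it
directly, and cohorts draw independent child seeds from a generator
seeded with it (one per embryo, then one per frame for noise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .io import CentroidRecord, ObservedFrame
from .registration import RigidTransform

DEFAULT_SEMI_AXES = (25.0, 15.0, 10.0)  # um, roughly an uncompressed embryo


def _settle_progress(v: np.ndarray | float):
    """Monotone C^1 progress on [0, 1]: q(0)=0, q'(0)=2, q(1)=1, q'(1)=0.

    Daughters separate promptly after birth and then rest at their target
    position until division, the way interphase nuclei do.
    """
    v = np.clip(v, 0.0, 1.0)
    return 1.0 - (1.0 - v) ** 2


@dataclass
class LineageCell:
    name: str
    parent: str | None
    generation: int
    t_birth: float
    t_division: float  # terminal time for leaves
    p_birth: np.ndarray
    target: np.ndarray
    settle_time: float = 1.5

    def position(self, t: float) -> np.ndarray:
        settle = min(self.settle_time, self.t_division - self.t_birth)
        v = (t - self.t_birth) / settle
        return self.p_birth + (self.target - self.p_birth) * _settle_progress(v)


@dataclass
class SyntheticLineage:
    """Binary division tree with smooth per-cell trajectories."""

    cells: dict[str, LineageCell]
    n_generations: int
    cycle: float
    semi_axes: tuple[float, float, float]
    seed: int

    @property
    def span(self) -> tuple[float, float]:
        t0 = min(c.t_birth for c in self.cells.values())
        t1 = max(c.t_division for c in self.cells.values())
        return (t0, t1)

    def alive_set(self, t: float) -> list[str]:
        """Names of cells alive at lineage time t (sorted)."""
        out = []
        for c in self.cells.values():
            is_leaf = c.generation == self.n_generations
            if c.t_birth <= t < c.t_division or (is_leaf and t == c.t_division):
                out.append(c.name)
        return sorted(out)

    def position(self, name: str, t: float) -> np.ndarray:
        return self.cells[name].position(t)


def _sample_in_ellipsoid(rng: np.random.Generator, semi_axes, existing: list[np.ndarray],
                         min_sep: float, center: np.ndarray | None = None,
                         radius: float = np.inf, tries: int = 400) -> np.ndarray:
    """Draw a point inside the ellipsoid, optionally within ``radius`` of
    ``center`` (divisions are local events), rejecting points closer than
    ``min_sep`` to any existing point."""
    semi = np.asarray(semi_axes)
    best, best_d = None, -np.inf
    for _ in range(tries):
        if center is None or not np.isfinite(radius):
            while True:
                u = rng.uniform(-1, 1, 3)
                if u @ u <= 1:
                    break
            p = u * semi
        else:
            while True:
                u = rng.uniform(-1, 1, 3)
                if u @ u <= 1:
                    break
            p = center + u * radius
            if np.sum((p / semi) ** 2) > 1.0:
                continue
        d = min((np.linalg.norm(p - q) for q in existing), default=np.inf)
        if d >= min_sep:
            return p
        if d > best_d:
            best, best_d = p, d
    return best


def make_lineage(n_generations: int, seed: int = 0, cycle: float = 8.0,
                 stagger: float = 2.5, settle_time: float = 1.5,
                 semi_axes: tuple[float, float, float] = DEFAULT_SEMI_AXES,
                 min_target_sep: float = 5.5,
                 daughter_radius: float = 6.0) -> SyntheticLineage:
    """Build a deterministic binary lineage with staggered division waves.

    Generation g divides in a wave spread over [g*cycle, g*cycle+stagger];
    cells divide one at a time within the wave (a seeded order with
    jitter), so cell counts ramp through every intermediate value and
    frames near waves show the transient mixed-count states real embryos
    do. Divisions are local: each daughter's stereotyped target lies
    within ``daughter_radius`` of the mother's division point, so a
    missing nucleus perturbs the cloud locally rather than globally.
    Leaves persist one extra cycle. 2**n_generations leaf cells;
    2**(n_generations+1) - 2 cells in total excluding the root.
    """
    if not 2 <= n_generations <= 8:
        raise ValueError(f"n_generations must be in [2, 8], got {n_generations}")
    rng = np.random.default_rng(seed)

    # tree layout and division schedule first
    gens: dict[int, list[str]] = {1: ["P0a", "P0p"]}
    for g in range(2, n_generations + 1):
        gens[g] = [n + s for n in gens[g - 1] for s in "ap"]
    t_div: dict[str, float] = {}
    for g in range(1, n_generations):
        order = rng.permutation(len(gens[g]))
        for name, rank in zip(gens[g], order):
            frac = (rank + rng.uniform(0.2, 0.8)) / len(gens[g])
            t_div[name] = g * cycle + stagger * frac
    for name in gens[n_generations]:
        t_div[name] = (n_generations + 1) * cycle

    # positions top-down: daughters start at the mother's division point
    cells: dict[str, LineageCell] = {}

    def grow(name: str, parent: str | None, gen: int, t_birth: float,
             p_birth: np.ndarray):
        same_gen = [c.target for c in cells.values() if c.generation == gen]
        target = _sample_in_ellipsoid(rng, semi_axes, same_gen, min_target_sep,
                                      center=np.asarray(p_birth, dtype=float),
                                      radius=daughter_radius)
        cell = LineageCell(name, parent, gen, t_birth, t_div[name],
                           np.asarray(p_birth, dtype=float), target, settle_time)
        cells[name] = cell
        if gen < n_generations:
            p_split = cell.position(cell.t_division)
            grow(name + "a", name, gen + 1, cell.t_division, p_split)
            grow(name + "p", name, gen + 1, cell.t_division, p_split)

    # the (unrendered) root divides one cycle before t=0, so the first
    # generation is already well separated at every non-negative time
    origin = np.zeros(3)
    grow("P0a", None, 1, -cycle, origin)
    grow("P0p", None, 1, -cycle, origin)
    return SyntheticLineage(cells, n_generations, cycle, tuple(semi_axes), seed)


def random_rigid_transform(rng: np.random.Generator,
                           translation_scale: float = 10.0) -> RigidTransform:
    """Uniformly random proper rotation plus a Gaussian translation."""
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    return RigidTransform(R, rng.normal(0.0, translation_scale, 3))


def sample_frame(lineage: SyntheticLineage, t: float, noise_sd: float = 0.0,
                 pose: RigidTransform | None = None, dropout_p: float = 0.0,
                 seed: int = 0, embryo_id: str = "query", frame_index: int = 0,
                 labeled: bool = False) -> tuple[ObservedFrame, list[str]]:
    """Render one snapshot at lineage time t.

    Positions are trajectory values plus isotropic Gaussian noise, posed
    by the rigid transform; each nucleus is independently dropped with
    probability ``dropout_p``. Returns (frame, ground-truth names); the
    frame's records are unlabeled unless ``labeled`` is set.
    """
    lo, hi = lineage.span
    if not lo <= t <= hi:
        raise ValueError(f"t={t} outside lineage span [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    names = lineage.alive_set(t)
    pts = np.stack([lineage.position(n, t) for n in names])
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    if dropout_p > 0:
        keep = rng.random(len(names)) >= dropout_p
        if not keep.any():
            raise ValueError("dropout removed every nucleus; frames must be non-empty")
        names = [n for n, k in zip(names, keep) if k]
        pts = pts[keep]
    if pose is not None:
        pts = pose.apply(pts)
    records = [CentroidRecord(embryo_id, frame_index, n if labeled else "", p)
               for n, p in zip(names, pts)]
    return ObservedFrame(embryo_id, frame_index, records), names


def make_cohort(lineage: SyntheticLineage, n_embryos: int,
                dilation_range: tuple[float, float] = (0.9, 1.1),
                jitter_sd: float = 0.5, seed: int = 0, noise_sd: float = 0.0,
                frame_step: float = 1.0, min_cells: int = 4
                ) -> dict[str, list[ObservedFrame]]:
    """Render a labeled training cohort.

    Each embryo gets a clock dilation factor drawn from
    ``dilation_range`` (its frame k samples the lineage at time
    k*frame_step*dilation, exercising the DTW staging), a constant
    per-cell positional offset with sd ``jitter_sd`` (exercising the
    empirical variance term) and optional isotropic measurement noise.
    Training frames keep the identity pose, emulating curated exports
    that share an orientation. Frames with fewer than ``min_cells``
    nuclei are not rendered: identities at the 2-cell stage (and
    near-degenerate 3-cell geometries) are underdetermined from
    positions alone under free rotation.
    """
    if n_embryos < 2:
        raise ValueError("a cohort needs at least 2 embryos")
    lo, hi = (float(dilation_range[0]), float(dilation_range[1]))
    if hi < lo or lo <= 0:
        raise ValueError(f"invalid dilation range [{lo}, {hi}]")
    master = np.random.default_rng(seed)
    t_end = lineage.span[1]
    cohort: dict[str, list[ObservedFrame]] = {}
    for e in range(n_embryos):
        erng = np.random.default_rng(master.integers(2**31))
        eid = f"emb{e:02d}"
        dilation = erng.uniform(lo, hi) if hi > lo else lo
        bias = {name: erng.normal(0.0, jitter_sd, 3) if jitter_sd > 0 else np.zeros(3)
                for name in sorted(lineage.cells)}
        frames = []
        k = 0
        while k * frame_step * dilation <= t_end:
            t = k * frame_step * dilation
            names = lineage.alive_set(t)
            if len(names) < min_cells:
                k += 1
                continue
            pts = np.stack([lineage.position(n, t) + bias[n] for n in names])
            if noise_sd > 0:
                pts = pts + erng.normal(0.0, noise_sd, pts.shape)
            recs = [CentroidRecord(eid, k, n, p) for n, p in zip(names, pts)]
            frames.append(ObservedFrame(eid, k, recs))
            k += 1
        cohort[eid] = frames
    return cohort


def cohort_frames(cohort: Mapping[str, list[ObservedFrame]]) -> list[ObservedFrame]:
    """Flatten a cohort mapping into one frame list (embryo then frame order)."""
    return [f for eid in sorted(cohort) for f in cohort[eid]]
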