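# Methods

This note documents the models, numerical choices and evaluation
conditions behind `embalign`, in the spirit of a model-description
vignette: what is assumed, what is tunable, and what the synthetic
results do and do not demonstrate about real data.

## Canonical time

Embryos develop at different rates, so frame indices are not comparable
across individuals. We stage each embryo by dynamic time warping of its
total-cell-count curve onto a designated reference embryo's curve
(absolute-difference local cost, symmetric steps: diagonal, insertion,
deletion). Cell count is the one staging signal available in every
labeled export and is monotone through development, which makes the
warp well behaved; the cost of this choice is that canonical time is
only resolved up to stretches of constant count (between divisions the
warp interpolates linearly). Canonical time equals the reference
embryo's frame axis; a query frame matched to several reference frames
maps to their mean. The reference defaults to the first training embryo
and is selectable.

## Trajectory models

Each cell's x, y and z coordinates over canonical time are modeled by
independent Gaussian-process regressors with kernel
σ²·RBF(ℓ) + σ²_white. Hyperparameters are optimized by log marginal
likelihood with 3 restarts (seeded); bounds are ℓ ∈ [min(1, span/2),
span] canonical frames and variances ∈ [1e-6, 1e3] on standardized
targets. Targets are standardized per axis (`normalize_y`), so the
variance bounds are dimensionless. A cell's lifespan [t_birth,
t_division] is the span of its canonical sample times.

Total positional variance at time t is the per-axis sum of the GP
posterior variance, the cell's empirical residual variance (variance of
its training residuals from the GP mean across embryos), and a jitter
floor (default 1e-6 µm²) that guarantees symmetric positive definite
covariances. The aggregation is additive and diagonal: the GP treats
axes independently and nothing in the training signal identifies
cross-axis covariance reliably at these sample sizes.

Note one degenerate regime: a cohort with no embryo-to-embryo
variability and no noise drives the empirical variances to ~0, leaving
covariances at the jitter floor. Mahalanobis costs then amplify
sub-micrometer discrepancies by ~10³ and are dominated by per-cell
variance ratios rather than geometry. Realistic cohorts (the generator
default includes 0.5 µm per-cell bias) do not enter this regime.

## Slice database

Only empirically observed combinations of co-existing cells become
reference templates: each fully labeled training frame contributes its
label set under key N (frame cell count), duplicates collapsed. A slice
is inflated by intersecting its members' lifespans (max birth, min
division — an inconsistent slice raises), querying the GP atlas at the
window midpoint t_med for expected positions, and attaching the total
positional variance at t_med as each cell's covariance. Template
retrieval at alignment time is strict N-equality; a query whose count
was never observed in training raises a no-template error naming the
nearest available N rather than silently padding or trimming. Dense
temporal coverage of the training data therefore matters: brief
transient states (a count held for a fraction of a frame interval)
enter the database only if some training embryo sampled them.

## Registration

Both clouds are centered and scaled by their median pairwise distance;
slice covariances are scaled by the same factor squared so Mahalanobis
distances are computed in the common normalized frame. The pose search:

1. **±PC1 seeding.** The observation's leading principal axis (sign
   fixed deterministically: largest-magnitude component positive) is
   rotated onto the reference PC1 by the minimal rotation; both signs
   are tried. Antiparallel axes use a 180° rotation about a
   deterministic perpendicular axis.
2. **Coarse sweep.** 36 angles (10° steps) about the reference PC1
   axis, counter-clockwise viewed from the +PC1 tip. Each orientation
   is scored by Σᵢⱼ Pᵢⱼ‖xᵢ − μⱼ‖² with P the Sinkhorn plan on squared
   Euclidean costs (ε = 0.05); all 36 plans are solved as one batched
   log-domain iteration.
3. **Valleys.** Circular local minima (plateau interiors excluded),
   greedily accepted by ascending cost subject to ≥30° circular
   separation, at most k = 3.
4. **Soft ICP.** Alternate Sinkhorn plan ↔ weighted Kabsch update
   (SVD of the plan-weighted cross-covariance with determinant
   correction; translations in closed form). ε anneals geometrically
   (×0.7 per iteration) from 0.05 to a floor of 1e-3 so the plan
   sharpens toward a permutation as the pose locks in; with exact data
   this makes pose recovery machine-exact. Dual potentials are
   warm-started across iterations; cold starts use ε-scaling. The loop
   stops when the cost improvement falls below 1e-9 at the ε floor (or
   at 60 iterations) and returns the best iterate, so the result is
   never worse than its seed orientation.
5. **Scoring and transfer.** Each refined candidate is scored by the
   total Mahalanobis cost of its optimal one-to-one assignment
   (Hungarian algorithm). The minimum over {slices × seeds × valleys}
   wins, with deterministic tie-breaking (slice index, then seed, then
   angle). Per-cell Mahalanobis distances and renormalized Sinkhorn row
   entropies (natural log) are recorded. A config switch
   (`plan_weighted_assignment`) instead weights the assignment matrix
   by N·P for users who prefer plan-weighted transfer; the default
   follows the plain Mahalanobis matrix.

Sinkhorn convergence is declared when the worst marginal deviation from
1/N is ≤ 1e-6; the flag is recorded and rare ill-conditioned cost
matrices that exhaust the iteration budget are used as-is with the flag
unset.

## Confidence layer

A random forest (200 trees, max depth 10, fixed seed, unweighted
classes by default with a `rf_balanced` switch) predicts assignment
correctness from five features (entropy, Mahalanobis, N, t_med, life
progress clipped to [0, 1]). Correctness is exact string equality of
assigned and true names — sister-cell swaps get no credit. The PR curve
for the *error* class uses step-wise interpolated precision (precision
at recall r is the best achievable at any recall ≥ r); AUPRC is its
step integral. Error/success recall are reported at confidence
threshold 0.5.

Because the aligner is nearly perfect on synthetic data, the LOOCV
harness can inject assignment corruptions: a chosen fraction of cells
per frame have their labels swapped pairwise, and Mahalanobis and
life-progress features are recomputed for the swapped identities. This
gives the classifier a two-class training signal whose error class has
the geometric signature of real misassignments. Injection never touches
the accuracy bookkeeping, which is recorded before corruption.

## Synthetic cohorts

The generator emulates the statistical structure the atlas assumes:

* a binary lineage over 4 (configurable 2–8) generations; generation g
  divides in a wave spread over 2.5 time units of an 8-unit cycle, one
  cell at a time, so counts ramp through every intermediate value;
* divisions are local: daughters start at the mother's division point
  (position-continuous) and settle within 1.5 time units to stereotyped
  targets sampled within 6 µm of it (≈ one cell diameter), at least
  5.5 µm from same-generation targets, inside a 25×15×10 µm ellipsoid;
* per embryo: a clock dilation drawn from [0.9, 1.1], a constant
  per-cell positional bias (sd 0.5 µm), optional isotropic noise,
  optional per-frame rigid pose and dropout. Frames with fewer than 4
  cells are not rendered — 2-cell identities are geometrically
  underdetermined under free rotation.

The generator has two regimes. With the default settle time, cells move
within slice windows, so a template inflated at t_med differs from an
observation at t by a real, non-rigid displacement; frames caught
mid-wave show transient accuracy dips — the qualitative behavior real
embryos show during synchronous division waves — and noise-free LOOCV
accuracy sits just below 1 (≈0.98–0.99). With settle time → 0 the
positions are stepwise-stationary, every frame matches its slice
template exactly, and noise-free LOOCV recovery is exactly perfect;
this variant defines the noise-free reference condition. What passing
these tests does *not* show: robustness to segmentation artifacts,
anisotropic localization error, non-rigid deformation of the embryo, or
lineage variability — real data have all four.

## Evaluation conditions and problem sizes

* LOOCV: 5 embryos, 4 generations (30 cells, frames of 4–16 nuclei,
  ~27 frames/embryo), noise sd = 5% of the median pairwise distance of
  a mid-stage frame, diagnostic layer trained with 5% injected swaps.
* Pose recovery: 20 random proper rigid poses on noise-free template
  frames; labels must be 100% correct and the composed rotation must
  undo the pose to ≤1e-6 (Frobenius).
* Noise ladder: {0, 5, 10, 20}% of median pairwise distance, 20 seeded
  frames per level; mean accuracy must be non-increasing.
* Missing-nucleus probe: 50 trials; one nucleus deleted from a
  noise-free posed frame, forcing alignment onto the overlapping
  (N−1)-cell slice; success = majority of shared labels correct. The
  atlas for this probe is fitted on a 6-embryo, 0.5-frame-step cohort
  so that every transient state is represented in the slice database.
* Operator oracles: linear sum assignment vs exhaustive permutations
  (N ≤ 7), weighted Kabsch vs 1000-rotation random search and planted
  rotations, Sinkhorn at ε = 1e-3 vs the Hungarian permutation, DTW vs
  exhaustive monotone-path enumeration (lengths ≤ 8).

These sizes keep the full suite and the acceptance script to a few
minutes on a single CPU while exercising every stage of the pipeline.

## Serialization

The atlas bundle is a single versioned JSON archive holding, per cell,
the training samples and the optimized kernel hyperparameters; loading
rebuilds each GP with fixed hyperparameters (a deterministic Cholesky
solve), so reloaded posterior means agree with the original to ≤1e-9.
Slices are stored inflated. A schema-version mismatch or truncated file
raises a distinct bundle error.

## Known limitations

* Strict N matching makes the pipeline sensitive to detection errors by
  design; the missing-nucleus probe shows failures stay local but does
  not remove the requirement to QC segmentation first.
* Covariances are diagonal; correlated positional variation (e.g. along
  the anteroposterior axis) is not modeled.
* DTW staging carries no positional information; embryos with atypical
  division timing but typical geometry may be mis-staged.
* The confidence model is uncalibrated (no isotonic/Platt step);
  probabilities order cells well but are not guaranteed to be
  frequency-calibrated.
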