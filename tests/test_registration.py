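"""Normalization, seeding, sweep, Sinkhorn, Kabsch, refinement, assignment."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from embalign.registration import (CostLandscape, DegenerateCloudError,
                                   FrameAligner, NoTemplateError,
                                   align_frame, assign_labels,
                                   coarse_sweep, mahalanobis_cost_matrix,
                                   normalize_cloud, pc1_seed_rotations,
                                   principal_axis, refine_alignment,
                                   rotation_about_axis, select_valleys,
                                   sinkhorn_plan, weighted_kabsch)
from embalign.synthetic import random_rigid_transform, sample_frame
from tests.conftest import frame_from_points


def random_cloud(rng, n=10, aniso=(3.0, 1.5, 1.0)):
    return rng.normal(size=(n, 3)) * np.asarray(aniso)


class TestNormalizeCloud:
    def test_two_points(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        norm, centroid, scale = normalize_cloud(pts)
        assert scale == pytest.approx(2.0)
        np.testing.assert_allclose(centroid, [1, 0, 0])
        np.testing.assert_allclose(sorted(norm[:, 0]), [-0.5, 0.5])

    def test_unit_square_median_one(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        norm, _, scale = normalize_cloud(pts)
        assert scale == pytest.approx(1.0)
        assert np.median(pdist(norm)) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(norm.mean(axis=0), 0, atol=1e-12)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(0)
        pts = random_cloud(rng)
        T = random_rigid_transform(rng)
        n1, _, s1 = normalize_cloud(pts)
        n2, _, s2 = normalize_cloud(T.apply(pts))
        assert s1 == pytest.approx(s2)
        np.testing.assert_allclose(n2, n1 @ T.rotation.T, atol=1e-9)

    def test_identical_points_degenerate(self):
        with pytest.raises(DegenerateCloudError):
            normalize_cloud(np.zeros((4, 3)))


class TestPC1Seeds:
    def test_identical_clouds_identity_and_flip(self):
        rng = np.random.default_rng(1)
        pts = random_cloud(rng)
        pts -= pts.mean(axis=0)
        r1, r2 = pc1_seed_rotations(pts, pts)
        np.testing.assert_allclose(r1, np.eye(3), atol=1e-9)
        # second seed is a 180-degree rotation about an axis perpendicular to PC1
        angle = np.arccos(np.clip((np.trace(r2) - 1) / 2, -1, 1))
        assert angle == pytest.approx(np.pi, abs=1e-9)
        axis_dir = Rotation.from_matrix(r2).as_rotvec()
        pc1, _ = principal_axis(pts)
        assert abs(np.dot(axis_dir / np.linalg.norm(axis_dir), pc1)) < 1e-9

    def test_maps_x_axis_cloud_onto_z_axis_cloud(self):
        # symmetric cloud: covariance is exactly diagonal, PC1 exactly +x
        base = np.array([[5.0, 0, 0], [-5.0, 0, 0], [0, 1.0, 0],
                         [0, -1.0, 0], [0, 0, 0.5], [0, 0, -0.5]])
        swap = base[:, [2, 1, 0]]  # PC1 exactly along z
        r1, _ = pc1_seed_rotations(base, swap)
        np.testing.assert_allclose(r1 @ np.array([1.0, 0, 0]), [0, 0, 1], atol=1e-9)

    def test_seeds_are_proper_rotations(self):
        rng = np.random.default_rng(3)
        a, b = random_cloud(rng), random_cloud(rng)
        for R in pc1_seed_rotations(a - a.mean(0), b - b.mean(0)):
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0)


class TestCoarseSweep:
    def test_self_alignment_minimum_at_zero(self):
        rng = np.random.default_rng(4)
        pts, _, _ = normalize_cloud(random_cloud(rng))
        ls = coarse_sweep(pts, pts, np.eye(3), step_deg=10.0)
        assert len(ls.angles) == 36
        assert ls.costs[0] == pytest.approx(ls.costs.min())

    def test_known_rotation_found_one_step_away(self):
        rng = np.random.default_rng(5)
        ref, _, _ = normalize_cloud(random_cloud(rng, n=14))
        axis, _ = principal_axis(ref)
        obs = ref @ rotation_about_axis(axis, 90.0).T
        ls = coarse_sweep(obs, ref, np.eye(3), step_deg=10.0, axis=axis)
        best = ls.angles[np.argmin(ls.costs)]
        # the sweep must undo the applied rotation: 270 degrees (or 90 if the
        # deterministic PC1 sign convention flipped the axis)
        assert min(abs(best - 270.0), abs(best - 90.0)) <= 10.0

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="point counts"):
            coarse_sweep(np.zeros((3, 3)), np.zeros((4, 3)), np.eye(3))


def greedy_valley_oracle(costs, k, min_sep, step):
    """Independent reimplementation: circular local minima, greedy by cost."""
    n = len(costs)
    if len(set(costs.tolist())) == 1:
        return [0.0]
    minima = [i for i in range(n)
              if costs[i] <= costs[(i - 1) % n] and costs[i] <= costs[(i + 1) % n]
              and not (costs[i] == costs[(i - 1) % n] == costs[(i + 1) % n])]
    chosen = []
    for i in sorted(minima, key=lambda i: (costs[i], i * step)):
        ok = True
        for j in chosen:
            d = abs(i - j) * step
            if min(d, 360 - d) < min_sep:
                ok = False
        if ok:
            chosen.append(i)
        if len(chosen) == k:
            break
    return [i * step for i in chosen]


class TestSelectValleys:
    def _landscape(self, costs, step=10.0):
        return CostLandscape(np.eye(3), np.array([0, 0, 1.0]),
                             np.arange(0, 360, step), np.asarray(costs, dtype=float))

    def test_two_separated_minima(self):
        costs = np.full(36, 5.0)
        costs[0], costs[18] = 1.0, 2.0
        assert select_valleys(self._landscape(costs), k=2) == [0.0, 180.0]

    def test_close_minima_suppressed(self):
        costs = np.full(36, 5.0)
        costs[0], costs[2] = 1.0, 2.0
        assert select_valleys(self._landscape(costs), k=2, min_sep_deg=30.0) == [0.0]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        costs = rng.uniform(0, 10, 36)
        got = select_valleys(self._landscape(costs), k=3, min_sep_deg=30.0)
        assert got == greedy_valley_oracle(costs, 3, 30.0, 10.0)

    def test_flat_landscape_single_minimum(self):
        assert select_valleys(self._landscape(np.ones(36)), k=3) == [0.0]


class TestSinkhorn:
    def test_single_point(self):
        plan = sinkhorn_plan(np.array([[3.0]]), epsilon=0.1)
        np.testing.assert_allclose(plan.plan, [[1.0]])

    def test_constant_costs_uniform_plan(self):
        plan = sinkhorn_plan(np.zeros((3, 3)) + 7.0, epsilon=0.1)
        np.testing.assert_allclose(plan.plan, np.full((3, 3), 1 / 9), atol=1e-9)

    def test_marginals_uniform_when_converged(self):
        rng = np.random.default_rng(6)
        C = rng.uniform(0, 1, (9, 9))
        plan = sinkhorn_plan(C, epsilon=0.05)
        assert plan.converged
        np.testing.assert_allclose(plan.plan.sum(axis=0), 1 / 9, atol=1e-6)
        np.testing.assert_allclose(plan.plan.sum(axis=1), 1 / 9, atol=1e-6)
        assert np.all(plan.plan >= 0)

    def test_small_epsilon_approaches_hungarian(self):
        rng = np.random.default_rng(7)
        C = rng.uniform(0, 1, (8, 8))
        perm, _ = assign_labels(C)
        plan = sinkhorn_plan(C, epsilon=1e-3, max_iters=2000)
        hard = np.round(8 * plan.plan)
        expected = np.zeros((8, 8))
        expected[np.arange(8), perm] = 1
        np.testing.assert_array_equal(hard, expected)

    def test_nonfinite_cost_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            sinkhorn_plan(np.array([[np.inf, 0], [0, 0.0]]), epsilon=0.1)

    def test_row_entropy_limits(self):
        from embalign.registration import CorrespondenceMatrix
        one_hot = np.zeros((4, 4))
        one_hot[np.arange(4), np.arange(4)] = 0.25
        cm = CorrespondenceMatrix(one_hot, True, 1)
        np.testing.assert_allclose(cm.row_entropies(), 0.0, atol=1e-12)
        cm = CorrespondenceMatrix(np.full((4, 4), 1 / 16), True, 1)
        np.testing.assert_allclose(cm.row_entropies(), np.log(4), atol=1e-12)


class TestWeightedKabsch:
    def test_identity_on_matched_clouds(self):
        rng = np.random.default_rng(8)
        pts = random_cloud(rng)
        T = weighted_kabsch(pts, pts, np.eye(len(pts)) / len(pts))
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(T.translation, 0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_recovers_planted_rotation(self, seed):
        rng = np.random.default_rng(100 + seed)
        ref = random_cloud(rng)
        R0 = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        obs = ref @ R0.T  # obs = R0 ref
        T = weighted_kabsch(obs, ref, np.eye(len(ref)) / len(ref))
        np.testing.assert_allclose(T.rotation, R0.T, atol=1e-9)

    def test_beats_random_rotations(self):
        rng = np.random.default_rng(9)
        obs, ref = random_cloud(rng, 6), random_cloud(rng, 6)
        P = rng.uniform(0, 1, (6, 6))
        P /= P.sum()
        T = weighted_kabsch(obs, ref, P)

        def cost(R, t):
            moved = obs @ R.T + t
            d = moved[:, None, :] - ref[None, :, :]
            return float((P * np.einsum("ijk,ijk->ij", d, d)).sum())

        achieved = cost(T.rotation, T.translation)
        for i in range(1000):
            R = Rotation.random(random_state=np.random.RandomState(i)).as_matrix()
            # optimal translation for this rotation
            mass = P.sum()
            xb = (P.sum(1) @ obs) / mass
            yb = (P.sum(0) @ ref) / mass
            assert achieved <= cost(R, yb - R @ xb) + 1e-9

    def test_zero_mass_plan_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            weighted_kabsch(np.eye(3), np.eye(3), np.zeros((3, 3)))


class TestRefineAlignment:
    def test_recovers_exact_pose_noise_free(self, config):
        rng = np.random.default_rng(10)
        ref, _, _ = normalize_cloud(random_cloud(rng, 12))
        T = random_rigid_transform(rng, translation_scale=0.5)
        obs = T.apply(ref)
        axis, _ = principal_axis(ref)
        base, base_neg = pc1_seed_rotations(obs, ref)
        best = None
        for b in (base, base_neg):
            ls = coarse_sweep(obs, ref, b, axis=axis)
            for ang in select_valleys(ls, k=3):
                cand = refine_alignment(obs, ref, ang, b, config, axis)
                if best is None or cand.best_cost < best.best_cost:
                    best = cand
        assert best.best_cost <= 1e-6
        # composed motion undoes the pose
        np.testing.assert_allclose(best.transform.rotation @ T.rotation,
                                   np.eye(3), atol=1e-6)

    def test_trace_bounded_and_not_worse_than_seed(self, config):
        rng = np.random.default_rng(11)
        ref, _, _ = normalize_cloud(random_cloud(rng, 8))
        obs, _, _ = normalize_cloud(random_cloud(rng, 8))
        cand = refine_alignment(obs, ref, 40.0, np.eye(3), config)
        assert len(cand.trace) <= config.refine_max_iters
        assert cand.best_cost <= cand.trace[0] + 1e-12


class TestMahalanobis:
    def test_identity_covariance_is_euclidean(self):
        rng = np.random.default_rng(12)
        x, mu = random_cloud(rng, 5), random_cloud(rng, 5)
        covs = np.tile(np.eye(3), (5, 1, 1))
        M = mahalanobis_cost_matrix(x, mu, covs)
        d = np.linalg.norm(x[:, None] - mu[None, :], axis=2)
        np.testing.assert_allclose(M, d, atol=1e-12)

    def test_hand_computed_anisotropic_distance(self):
        x = np.array([[1.0, 0, 0]])
        mu = np.zeros((1, 3))
        covs = np.diag([4.0, 1, 1])[None]
        assert mahalanobis_cost_matrix(x, mu, covs)[0, 0] == pytest.approx(0.5)

    def test_whitening_equivalence(self):
        rng = np.random.default_rng(13)
        x, mu = random_cloud(rng, 4), random_cloud(rng, 4)
        diag = rng.uniform(0.5, 3.0, 3)
        covs = np.tile(np.diag(diag), (4, 1, 1))
        M = mahalanobis_cost_matrix(x, mu, covs)
        W = np.diag(1 / np.sqrt(diag))
        d = np.linalg.norm((x @ W)[:, None] - (mu @ W)[None, :], axis=2)
        np.testing.assert_allclose(M, d, atol=1e-9)


class TestAssignLabels:
    def test_simple_two_by_two(self):
        perm, total = assign_labels(np.array([[1.0, 2], [2, 1]]))
        assert perm.tolist() == [0, 1] and total == 2.0

    def test_matches_exhaustive_five_by_five(self):
        rng = np.random.default_rng(14)
        C = rng.uniform(0, 1, (5, 5))
        _, total = assign_labels(C)
        brute = min(sum(C[i, p[i]] for i in range(5))
                    for p in itertools.permutations(range(5)))
        assert total == pytest.approx(brute)

    def test_dominant_diagonal_identity(self):
        C = np.full((4, 4), 10.0)
        np.fill_diagonal(C, 0.0)
        perm, _ = assign_labels(C)
        assert perm.tolist() == [0, 1, 2, 3]

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            assign_labels(np.zeros((2, 3)))


class TestAlignFrame:
    def test_template_sampled_frame_recovers_slice_and_labels(self, clean_atlas):
        rng = np.random.default_rng(15)
        sl = clean_atlas.slice_db_.get(16)[0]
        T = random_rigid_transform(rng)
        frame = frame_from_points(T.apply(sl.means))
        res = align_frame(frame, clean_atlas.slice_db_)
        assert res.slice is sl
        assert list(res.assigned_names) == list(sl.cell_names)

    def test_missing_cell_count_raises_no_template(self, clean_atlas):
        frame = frame_from_points(np.random.default_rng(16).normal(size=(3, 3)))
        with pytest.raises(NoTemplateError, match="N=3"):
            align_frame(frame, clean_atlas.slice_db_)

    def test_generating_slice_beats_alternatives(self, lineage, clean_atlas):
        # sample from a slice's Gaussians with small spread: it must win
        rng = np.random.default_rng(17)
        candidates = [n for n in clean_atlas.slice_db_.counts()
                      if len(clean_atlas.slice_db_.get(n)) >= 1 and n >= 8]
        sl = clean_atlas.slice_db_.get(candidates[0])[0]
        pts = sl.means + rng.normal(0, 0.2, sl.means.shape)
        res = align_frame(frame_from_points(pts), clean_atlas.slice_db_)
        assert set(res.slice.cell_names) == set(sl.cell_names)
        losing = [c["final_cost"] for c in res.candidates
                  if set(c["slice_cells"]) != set(sl.cell_names)]
        assert all(res.total_cost < lc for lc in losing)

    def test_pose_invariance_of_labels(self, lineage, clean_atlas):
        rng = np.random.default_rng(18)
        frame, _ = sample_frame(lineage, 28.0, 0.0, None, seed=20)
        base = align_frame(frame, clean_atlas.slice_db_)
        for s in range(3):
            T = random_rigid_transform(rng)
            posed, _ = sample_frame(lineage, 28.0, 0.0, T, seed=20)
            res = align_frame(posed, clean_atlas.slice_db_)
            assert res.assigned_names == base.assigned_names


class TestFrameAligner:
    def test_sklearn_protocol_and_predict(self, clean_cohort, lineage, clean_atlas):
        from sklearn.base import clone

        aligner = FrameAligner(atlas=clean_atlas)
        assert set(clone(aligner).get_params(deep=False)) == {
            "atlas", "config", "reference_embryo"}
        aligner.fit([])
        frame, truth = sample_frame(lineage, 26.0, 0.0, None, seed=21)
        assert aligner.predict(frame) == truth

    def test_unfitted_align_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            FrameAligner().align(None)
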