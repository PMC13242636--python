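"""Shared fixtures: one small lineage and two fitted atlases per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from embalign import EmbryoAtlas, RunConfig
from embalign.io import CentroidRecord, ObservedFrame
from embalign.synthetic import cohort_frames, make_cohort, make_lineage

settings.register_profile(
    "ci", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lineage():
    return make_lineage(4, seed=1)


@pytest.fixture(scope="session")
def clean_cohort(lineage):
    """Noise-free, dilation-free, bias-free training cohort."""
    return make_cohort(lineage, 4, dilation_range=(1.0, 1.0), jitter_sd=0.0, seed=2)


@pytest.fixture(scope="session")
def clean_atlas(clean_cohort):
    return EmbryoAtlas().fit(cohort_frames(clean_cohort))


@pytest.fixture(scope="session")
def realistic_atlas(lineage):
    """Atlas fitted with clock dilation and per-cell bias in the cohort."""
    cohort = make_cohort(lineage, 4, dilation_range=(0.9, 1.1), jitter_sd=0.5, seed=3)
    return EmbryoAtlas().fit(cohort_frames(cohort))


@pytest.fixture()
def config():
    return RunConfig()


def frame_from_points(points, names=None, embryo="q", index=0) -> ObservedFrame:
    points = np.asarray(points, dtype=float)
    names = names or [""] * len(points)
    return ObservedFrame(embryo, index,
                         [CentroidRecord(embryo, index, n, p)
                          for n, p in zip(names, points)])


@pytest.fixture(scope="session")
def aligned_result(lineage, clean_atlas):
    """One full FrameResult on a posed noise-free frame (shared, read-only)."""
    from embalign.registration import align_frame
    from embalign.synthetic import random_rigid_transform, sample_frame

    rng = np.random.default_rng(7)
    pose = random_rigid_transform(rng)
    frame, truth = sample_frame(lineage, 30.0, 0.0, pose, seed=7)
    result = align_frame(frame, clean_atlas.slice_db_)
    return result, truth
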