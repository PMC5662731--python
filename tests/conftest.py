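"""Shared fixtures: a rendered training session, its decomposition and
candidate set, and a posture codebook trained on it.

The codebook is deliberately trained on one session (seed 3) while
detection-quality tests evaluate on a disjoint held-out session (seed 99),
so every downstream check measures cross-recording generalisation.
"""

import numpy as np
import pytest

from graspkin import synthetic as syn
from graspkin.codebook import train_posture_codebook
from graspkin.foreground import (
    decompose_low_rank_sparse,
    extract_candidates,
    remove_outliers_knn,
    sample_background_regions,
)


@pytest.fixture(scope="session")
def train_session():
    cfg = syn.SceneConfig(seed=3, n_frames=150)
    frames, gt, masks = syn.generate_session(
        cfg, n_grasps=4, return_masks=True
    )
    return {"config": cfg, "frames": frames, "gt": gt, "masks": masks}


@pytest.fixture(scope="session")
def train_decomposition(train_session):
    return decompose_low_rank_sparse(train_session["frames"])


@pytest.fixture(scope="session")
def train_candidates(train_session, train_decomposition):
    cs = extract_candidates(
        train_decomposition, train_session["frames"], n_samples=250, seed=0
    )
    return remove_outliers_knn(cs, k=10, removal_fraction=0.02)


@pytest.fixture(scope="session")
def posture_codebook(train_session, train_decomposition, train_candidates):
    bg = sample_background_regions(
        train_decomposition, train_session["frames"], n_samples=150, seed=1
    )
    return train_posture_codebook(
        train_candidates,
        K=4,
        negative_set_size=100,
        n_entries=40,
        seed=0,
        background_negatives=bg,
    )


@pytest.fixture(scope="session")
def heldout_session():
    cfg = syn.SceneConfig(seed=99, n_frames=100)
    frames, gt = syn.generate_session(cfg, n_grasps=3)
    return {"config": cfg, "frames": frames, "gt": gt}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
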