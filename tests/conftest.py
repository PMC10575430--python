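"""Shared fixtures.

The trained defocus network is expensive (minutes of CPU), so one model is
trained per session at the full study scale (45 cells x 11 defocus levels
= 495 ROIs) and shared by every test that needs inference.
"""

from __future__ import annotations

import numpy as np
import pytest

from patchcontact.cunet import CuNetConfig, train
from patchcontact.synthscene import SceneSpec, contact_scene, make_cunet_dataset, make_tip_rois

DEFOCUS_LEVELS = np.arange(0.0, 11.0)  # 0..10 um in 1 um steps


@pytest.fixture(scope="session")
def train_scene():
    scene, _ = contact_scene(0)
    return scene


@pytest.fixture(scope="session")
def trained_cunet(train_scene):
    """CU-net trained on ~500 synthetic ROIs spanning defocus 0-10 um."""
    data = make_cunet_dataset(train_scene, 45, DEFOCUS_LEVELS, seed=1)
    return train(data, CuNetConfig(seed=0))


@pytest.fixture(scope="session")
def heldout_cunet_samples(train_scene):
    """ROIs from cells the trained network never saw."""
    return make_cunet_dataset(train_scene, 6, DEFOCUS_LEVELS, seed=901)


@pytest.fixture(scope="session")
def tip_roi_samples():
    """50 seeded tip ROIs with ground truth and jittered detector boxes."""
    return make_tip_rois(50, seed=3)


@pytest.fixture()
def quiet_scene():
    """Noise-free, default-geometry scene for analytic pixel checks."""
    return SceneSpec(noise_sd=0.0)
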