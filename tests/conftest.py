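"""Shared fixtures: simulated data and a trained desk-scale classifier.

Everything is generated programmatically at test time from fixed seeds; no
binary fixtures are stored.
"""

import numpy as np
import pytest

from spinetrack.imgio import VoxelGeometry
from spinetrack.simulator import (RenderParams, patch_training_set,
                                  simulate_timeseries)

SIM_GEOMETRY = VoxelGeometry(dx=0.072, dy=0.072, bit_depth=12)


@pytest.fixture(scope="session")
def lownoise_sim():
    """Default-parameter simulation at a generous photon budget (γ=4)."""
    return simulate_timeseries(seed=3, gamma=4.0)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noise-free rendering for exact-invariance checks."""
    return simulate_timeseries(seed=5, noise=False)


@pytest.fixture(scope="session")
def trained_classifier():
    """Desk-scale 9-class patch classifier trained on simulator ground truth."""
    from spinetrack.detection import train_classifier

    sim = simulate_timeseries(seed=10, gamma=4.0,
                              render=RenderParams(n_boutons=3))
    X, y = patch_training_set(sim, n_per_class=150, seed=0)
    clf, cm_train, cm_val = train_classifier(X, y, small=True, epochs=12)
    return clf, cm_train, cm_val


def dice(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    s = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / s if s else 1.0
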