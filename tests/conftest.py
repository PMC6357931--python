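"""Shared fixtures: small phantoms rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from coroflow import MotionModel, generate_tree, render_sequence


@pytest.fixture(scope="session")
def still_phantom():
    """Motion-free, noise-free 256-px phantom: (tree, seq, truth)."""
    tree = generate_tree(seed=11, generations=6, image_size=256)
    seq, truth = render_sequence(tree, 0.25, MotionModel.still(), 44,
                                 noise_sd=0.0, seed=11)
    return tree, seq, truth


@pytest.fixture(scope="session")
def moving_phantom():
    """Phantom with cardiac motion and sensor noise: (tree, seq, truth)."""
    tree = generate_tree(seed=12, generations=5, image_size=256)
    seq, truth = render_sequence(tree, 0.25, MotionModel(), 36,
                                 noise_sd=5.0, seed=12)
    return tree, seq, truth


@pytest.fixture(scope="session")
def vessel_mask(still_phantom):
    """A fully propagated truth mask (dye-covered tree)."""
    _, _, truth = still_phantom
    return truth.truth_masks[truth.full_propagation_frame + 3]


@pytest.fixture(scope="session")
def soft_vessel(vessel_mask):
    """Gaussian-smoothed soft map of the vessel mask, as fed to the
    registration objective."""
    from scipy import ndimage as ndi
    return ndi.gaussian_filter(vessel_mask.astype(float), 2.0)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    denom = a.sum() + b.sum()
    return 2.0 * inter / denom if denom else 1.0
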