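"""Shared fixtures: synthetic scenes and a trained pixel classifier.

Session-scoped because scene generation and classifier training are the
expensive steps; every test treats them as read-only.
"""

import numpy as np
import pytest

import qdcoloc as q


@pytest.fixture(scope="session")
def default_scene():
    """One 512x512 scene at default SNR (f_boundary = 0.8, 50 spots)."""
    return q.make_scene(seed=42)


@pytest.fixture(scope="session")
def small_scene():
    """A 256x256 scene for fast module tests."""
    return q.make_scene(q.CellNetworkSpec(256, 256), seed=7)


@pytest.fixture(scope="session")
def trained_classifier():
    """Pixel classifier trained on its own training scene (seed 999)."""
    scene = q.make_scene(seed=999)
    train = q.sample_training_from_mask(scene.boundary_channel,
                                        scene.boundary_mask, rng_seed=7)
    return q.train_pixel_classifier(train, rng_seed=7)


@pytest.fixture
def noise_free_imaging():
    return q.ImagingSpec(noise_model="none", gaussian_noise_sd=0.0)


def detect_and_refine(scene, psf_sigma=1.5):
    cand = q.detect_spots(scene.qd_channel, psf_sigma)
    return q.refine_centroids(scene.qd_channel, cand)
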