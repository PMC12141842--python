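import numpy as np
import pytest

import pellikit as pk


@pytest.fixture(scope="session")
def speckle_image():
    """A medium speckle image reused across PIV tests."""
    return pk.generate_speckle(
        pk.SpeckleSpec(width_px=300, height_px=200, seed=3))


@pytest.fixture(scope="session")
def canonical_profile():
    """Noiseless dense sampling of the canonical rough profile."""
    return pk.DeformationProfile.from_nodes(pk.CANONICAL_ROUGH_NODES,
                                            n_points=101)


@pytest.fixture(scope="session")
def rough_fit(canonical_profile):
    """Piecewise fit of the noiseless canonical rough profile."""
    return pk.fit_piecewise(canonical_profile, n_segments=4)


def uniform_translation_nodes(c: float = 1.0):
    return pk.ProfileNodes(((0.0, c), (1.0, c)))


@pytest.fixture(scope="session")
def translated_pair(speckle_image):
    """Speckle image and a 4-px uniform-translation warp of it."""
    moved = pk.apply_displacement(speckle_image, uniform_translation_nodes(),
                                  4.0)
    return speckle_image, moved


def add_noise(image, sd, seed):
    rng = np.random.default_rng(seed)
    return pk.Image(np.clip(image.pixels + rng.normal(0, sd, image.shape),
                            0, 255))
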