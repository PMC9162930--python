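import numpy as np
import pytest

from biofilmz import ProfileSet, SyntheticTruth, ZProfile, simulate_profile


def make_profile(intensity, z=None, roi_id=1, image_id="img", **kw):
    intensity = np.asarray(intensity, dtype=float)
    if z is None:
        z = np.arange(len(intensity), dtype=float)
    return ZProfile(roi_id=roi_id, image_id=image_id, z=z, intensity=intensity, **kw)


@pytest.fixture
def slab_profile():
    """Noiseless 30 µm slab between two unequal backgrounds."""
    profile, truth = simulate_profile(SyntheticTruth())
    return profile, truth


@pytest.fixture
def one_image_set():
    """Ten noiseless ROI profiles of one synthetic z-image."""
    profiles = []
    for k in range(10):
        p, _ = simulate_profile(SyntheticTruth(seed=k), roi_id=k + 1, image_id="img01")
        profiles.append(p)
    return ProfileSet(profiles=profiles)
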