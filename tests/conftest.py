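import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thermotex as tt

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_design():
    """Reduced cohort for structural tests: same layout, fewer animals."""
    return tt.CohortDesign(
        n_nonpregnant=6, n_pregnant_per_subgroup=5, seed=11, frame_shape=(64, 96)
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    frames, metadata = tt.generate_cohort(small_design)
    return frames, metadata


@pytest.fixture(scope="session")
def small_table(small_cohort):
    frames, _ = small_cohort
    cfg = tt.TextureConfig(components=("R", "G", "I"), approaches=("HS", "GLCM"))
    return tt.extract_table(frames, cfg)


def random_masked_plane(rng, shape=(8, 8), levels=256):
    plane = rng.integers(0, levels, size=shape).astype(np.uint8)
    mask = rng.random(shape) < 0.7
    # keep at least one horizontal in-mask pair
    mask[shape[0] // 2, 0:2] = True
    return plane, mask
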