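import numpy as np
import pytest

import patchbag as pb


@pytest.fixture(scope="session")
def tiny_phantom_cfg():
    """A miniature cohort condition for fast mechanical tests (not the study
    condition; end-to-end recovery uses the generator defaults)."""
    return pb.PhantomConfig(
        extent=(32, 32, 32),
        n_per_class=5,
        lesion_center=(20, 12, 16),
        lesion_radius=4.0,
        n_distractors=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_phantom_cfg):
    return pb.generate_cohort(tiny_phantom_cfg)


@pytest.fixture(scope="session")
def small_state():
    """An untrained position-gate model with the smallest patch size."""
    return pb.build_model(pb.EncoderSpec(patch_size=9), "position_gate", seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
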