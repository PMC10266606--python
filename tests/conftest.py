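from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_field():
    """One deterministic synthetic monolayer field plus its ground truth."""
    from orgprof import synth

    params = synth.group1_wpb_params(rng_seed=7)
    image, truth = synth.generate_field(params)
    return params, image, truth


@pytest.fixture(scope="session")
def small_field_result(small_field):
    """Pipeline output on the shared synthetic field (default config)."""
    from orgprof import PipelineConfig, process_image

    _, image, _ = small_field
    return process_image(image, PipelineConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(42)
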