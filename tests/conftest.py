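import dataclasses

import numpy as np
import pytest

from epimea.conditions import DESK_GEOMETRY, desk_effect_model, protocol


@pytest.fixture
def desk_geometry():
    return DESK_GEOMETRY


@pytest.fixture
def desk_effect():
    return desk_effect_model()


@pytest.fixture
def short_timeline():
    return protocol(ictogenic_duration=120.0)


@pytest.fixture
def background_only_effect():
    """Pure homogeneous-Poisson background, no episodes, no noise surprises."""
    return dataclasses.replace(
        desk_effect_model(), p_ictal=0.0, p_se=0.0, burst_rate=0.0
    )


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(20260928))
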