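import numpy as np
import pytest

from otoshape.synthdata import (
    PopulationSpec,
    SynthConfig,
    default_config,
    default_populations,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def nss_spec():
    return default_populations()[0]


@pytest.fixture
def plain_spec():
    """A population with no shape effects (pure base curve)."""
    return PopulationSpec(
        name="plain", vbgm=(32.0, 0.4, -1.5), vs_mean=56.0, shape_effect=()
    )


@pytest.fixture
def small_config():
    """Small three-population study for fast end-to-end tests."""
    return default_config(seed=7, n_scale=0.4)


@pytest.fixture
def records_catch(small_config):
    from otoshape.synthdata import generate_fish_records

    return generate_fish_records(small_config)


def circle_outline(r=1.0, n=256, center=(0.0, 0.0)):
    from otoshape.outline import Outline

    th = 2 * np.pi * np.arange(n) / n
    return Outline(
        np.column_stack(
            [center[0] + r * np.cos(th), center[1] + r * np.sin(th)]
        )
    )
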