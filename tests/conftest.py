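import numpy as np
import pytest

from nirslat.config import PipelineConfig
from nirslat.design import LANDMARK, PICTURE_NAMING, make_block_design
from nirslat.montage import default_montage
from nirslat.simulate import EffectSpec, NoiseSpec, simulate_subject


@pytest.fixture(scope="session")
def montage16():
    return default_montage(16)


@pytest.fixture(scope="session")
def montage80():
    return default_montage(80)


@pytest.fixture(scope="session")
def short_designs():
    """Compact designs (few blocks) for fast pipeline tests."""
    return {
        PICTURE_NAMING: make_block_design(PICTURE_NAMING, n_blocks=4),
        LANDMARK: make_block_design(LANDMARK, n_blocks=3, rest_s=16.0, seed=0),
    }


@pytest.fixture(scope="session")
def clean_subject(montage16, short_designs):
    """Noise-free subject with known lateralization, compact designs."""
    effects = EffectSpec.from_li(0.5, -0.5, control_ratio=0.0)
    return simulate_subject(
        montage16, dict(short_designs), effects, NoiseSpec.zero(),
        rest_duration_s=120.0, seed=7,
    )


@pytest.fixture(scope="session")
def noisy_subject(montage16, short_designs):
    """Default-noise subject with compact designs."""
    return simulate_subject(
        montage16, dict(short_designs), EffectSpec.from_li(0.3, -0.3),
        NoiseSpec(), rest_duration_s=120.0, seed=11,
    )


@pytest.fixture()
def no_qc_config():
    return PipelineConfig(qc_enabled=False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
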