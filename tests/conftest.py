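import pytest

from methlift import SimulationConfig, build_id_mapping, make_platform_pair


@pytest.fixture
def cfg():
    """Small default simulation: 60 prefixes, default noise regime."""
    return SimulationConfig(seed=7, n_prefixes=60)


@pytest.fixture
def platform_pair(cfg):
    """(legacy manifest, suffixed manifest, legacy->suffixed true mapping)."""
    return make_platform_pair(cfg)


@pytest.fixture
def reverse_mapping(platform_pair):
    """Suffixed -> legacy mapping (the replicate-aggregating direction)."""
    legacy, suffixed, _ = platform_pair
    return build_id_mapping(suffixed, legacy)
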