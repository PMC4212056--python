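import pytest

from vcp.isomap import (DynamicMapping, UniverseSpec, build_static_mapping,
                        universe_size, STATIC_CAP)

_MAPPING_CACHE = {}


def get_mapping(n, r, directed):
    """Session-wide cache of element mappings; dynamic above the static cap
    or for the large directed multirelational universes."""
    key = (n, r, directed)
    if key not in _MAPPING_CACHE:
        spec = UniverseSpec(n, r, directed)
        if universe_size(spec) <= 2 ** 18:
            _MAPPING_CACHE[key] = build_static_mapping(spec)
        else:
            _MAPPING_CACHE[key] = DynamicMapping(spec)
    return _MAPPING_CACHE[key]


@pytest.fixture(scope="session")
def mapping_cache():
    return get_mapping
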