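import numpy as np
import pytest

import pulsescope as ps


@pytest.fixture(scope="session")
def rendered():
    """Render each packaged fixture once per test session."""
    cache: dict = {}

    def get(name: str):
        if name not in cache:
            script, cfg = ps.fixture(name)
            cache[name] = (script, cfg, ps.render(script, cfg))
        return cache[name]

    return get


@pytest.fixture(scope="session")
def decoded(rendered):
    """Decode each packaged fixture once per test session."""
    cache: dict = {}

    def get(name: str, **kwargs):
        key = (name, tuple(sorted(kwargs.items())))
        if key not in cache:
            script, cfg, rec = rendered(name)
            cache[key] = (script, cfg, ps.decode(rec, **kwargs))
        return cache[key]

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
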