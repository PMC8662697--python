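import numpy as np
import pytest
from hypothesis import settings

import hepatocal as hc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bank():
    """Lazily computed, session-cached scenario runs.

    Full scenario integrations take a few seconds each; many tests compare
    the same handful of scenarios, so results are shared across the session.
    ``get(name, gij, **overrides)`` applies overrides to the systemic
    parameter block or the top-level config before running.
    """
    cache = {}

    def get(name, gij=5.0, **overrides):
        key = (name, gij, tuple(sorted(overrides.items())))
        if key not in cache:
            cfg = hc.preset(name, gij=gij)
            for attr, val in overrides.items():
                if hasattr(cfg, attr):
                    setattr(cfg, attr, val)
                elif hasattr(cfg.systemic, attr):
                    setattr(cfg.systemic, attr, val)
                elif hasattr(cfg.metabolism, attr):
                    setattr(cfg.metabolism, attr, val)
                else:
                    raise AttributeError(attr)
            cache[key] = hc.run_scenario(cfg)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def short_human():
    """A single abbreviated human/strong-coupling run for engine checks."""
    cfg = hc.preset("human", 5.0)
    cfg.t_end = 1500.0
    return hc.run_scenario(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
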