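import pytest

import dcmkit as dk


@pytest.fixture(scope="session")
def study_patterns():
    return {name: dk.build_pattern(name) for name in dk.STUDY_PATTERN_NAMES}


@pytest.fixture(scope="session")
def wellmixed_sim(study_patterns):
    """Noise-free run in the perfectly mixed limit (huge diffusive exchange)."""
    cfg = dk.SimulationConfig(
        pattern=study_patterns["maltose"], noise_cv=0.0, exchange_base=1e6, seed=1
    )
    return dk.simulate(cfg)


@pytest.fixture(scope="session")
def static_isolated_sim(study_patterns):
    """Static pattern with zero exchange: no transport out of segment 1."""
    cfg = dk.SimulationConfig(
        pattern=study_patterns["static"], noise_cv=0.0, exchange_base=0.0, seed=1
    )
    return dk.simulate(cfg)


@pytest.fixture(scope="session")
def maltose_sim(study_patterns):
    """Noise-free run under study-default transport settings."""
    cfg = dk.SimulationConfig(pattern=study_patterns["maltose"], noise_cv=0.0, seed=1)
    return dk.simulate(cfg)
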