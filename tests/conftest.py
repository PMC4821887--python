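import pytest

import cortexscreen as cs


@pytest.fixture(scope="session")
def tiny_screen():
    """One seeded small screen shared across tests: (config, annotation,
    design, truth, counts)."""
    cfg = cs.tiny_config(seed=1)
    ann, design, truth, counts = cs.simulate_screen(cfg)
    return cfg, ann, design, truth, counts


@pytest.fixture(scope="session")
def tiny_profiles(tiny_screen):
    cfg, ann, design, truth, counts = tiny_screen
    return cs.preprocess_pipeline(counts, ann, design)


@pytest.fixture(scope="session")
def tiny_clusters(tiny_profiles):
    return cs.discover_clusters(tiny_profiles)
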