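import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from gwasfunnel import GeneratorConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A small bundle with one planted candidate, shared across tests."""
    cfg = GeneratorConfig(n_snps=1_000, n_genes=50, n_chroms=3, n_planted=1)
    return generate_bundle(cfg, seed=11)


@pytest.fixture(scope="session")
def default_bundle():
    """A full-size bundle at the default study conditions."""
    return generate_bundle(GeneratorConfig(), seed=7)
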