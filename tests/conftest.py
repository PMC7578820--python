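import numpy as np
import pytest

from clinkg.schema import build_default_schema
from clinkg.synth import GeneratorConfig, build_lexicons, generate_corpus


@pytest.fixture(scope="session")
def schema():
    return build_default_schema()


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(GeneratorConfig(n_patients=30, seed=42, negation_prob=0.25))


@pytest.fixture(scope="session")
def lexicons():
    cfg = GeneratorConfig(n_patients=1, seed=42)
    return build_lexicons(cfg, np.random.default_rng(cfg.seed))
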