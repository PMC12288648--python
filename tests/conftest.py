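import numpy as np
import pytest

from respphen.backends import OracleBackend, default_templates
from respphen.synthetic import GeneratorConfig, default_lexicon, generate_cohort, record_for_concept


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture()
def oracle(lexicon):
    return OracleBackend(lexicon)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-patient cohort reused by read-only tests."""
    cfg = GeneratorConfig(n_patients=150, seed=42)
    return generate_cohort(cfg)


def records_from_concepts(pairs, encounter_id="E1"):
    """Build raw records from (concept text, offset) pairs."""
    return [record_for_concept(text, off, encounter_id) for text, off in pairs]


@pytest.fixture(scope="session")
def make_records():
    return records_from_concepts
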