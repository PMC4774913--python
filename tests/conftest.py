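import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # sentence_fixtures, metric_oracle

from biocoref import FixtureSpec, generate, load_configuration


@pytest.fixture(scope="session")
def spl_config():
    return load_configuration("spl")


@pytest.fixture(scope="session")
def discharge_config():
    return load_configuration("discharge")


@pytest.fixture(scope="session")
def protein_config():
    return load_configuration("protein")


@pytest.fixture()
def simple_fixture():
    """One pronominal-anaphora document."""
    return generate(FixtureSpec(anaphora=1, seed=7))


@pytest.fixture()
def mixed_fixture():
    """A document exercising every planted coreference type."""
    return generate(
        FixtureSpec(
            anaphora=6,
            cataphora=3,
            appositive=3,
            predicate_nominative=2,
            set_membership=1,
            distractors=1,
            seed=42,
        )
    )
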