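from importlib import resources

import pytest

from invivoannot import annotate_corpus, identify_corpus, seed_dictionary
from invivoannot.io import read_assays


@pytest.fixture(scope="session")
def seed_dict():
    return seed_dictionary()


@pytest.fixture(scope="session")
def worked_example_records():
    """The ten published example assay descriptions shipped as package data."""
    path = resources.files("invivoannot.data") / "worked_example_assays.tsv"
    with resources.as_file(path) as p:
        return read_assays(p)


@pytest.fixture(scope="session")
def worked_example_table(worked_example_records, seed_dict):
    accepted, _ = identify_corpus(worked_example_records)
    return annotate_corpus(accepted, seed_dict)
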