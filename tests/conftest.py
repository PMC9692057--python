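import pytest

from stickcontest.response import ParticipantRecord
from stickcontest.synth import GeneratorConfig, generate_records


@pytest.fixture
def toy_records():
    """Three hand-written participants covering both orders and groups."""
    return [
        ParticipantRecord(id="a", first_contestant="longer", speaker_rank1=9, evidence1=6, slider1=34.0),
        ParticipantRecord(id="b", first_contestant="shorter", speaker_rank1=2, evidence1=4, slider1=62.0),
        ParticipantRecord(id="c", first_contestant="longer", speaker_rank1=7, evidence1=8, slider1=70.0),
    ]


@pytest.fixture(scope="session")
def records_small():
    """A small generated dataset shared across fast tests."""
    return generate_records(GeneratorConfig(n_participants=60, seed=7))
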