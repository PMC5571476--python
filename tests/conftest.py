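import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from humaninscan.reference import HUMANIN_QUERY
from humaninscan.seqio import SequenceRecord, write_fasta


@pytest.fixture
def reference_record() -> SequenceRecord:
    """The bundled 73-base rCRS Humanin region as its own target."""
    return SequenceRecord(id="rcrs_humanin", bases=HUMANIN_QUERY)


@pytest.fixture
def fasta_writer(tmp_path):
    """Write records to a temporary FASTA file and return its path."""

    def _write(records, name="input.fasta"):
        path = tmp_path / name
        write_fasta(records, path)
        return path

    return _write
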