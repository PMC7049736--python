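import pytest
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from hypothesis import settings

from ptcmap.pipeline import score_panel
from ptcmap.regions import default_regions
from ptcmap.synth import synth_panel

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_alignment(rows: list[tuple[str, str]]) -> MultipleSeqAlignment:
    """Build a tiny aligned-FASTA-style alignment from (id, sequence) pairs."""
    return MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in rows]
    )


@pytest.fixture(scope="session")
def regions():
    return default_regions()


@pytest.fixture(scope="session")
def noiseless_bundle():
    return synth_panel(noise_cv=0.0, seed=11, n_alignment_records=60)


@pytest.fixture(scope="session")
def noiseless_results(noiseless_bundle):
    return score_panel(noiseless_bundle)


@pytest.fixture(scope="session")
def noisy_bundle():
    return synth_panel(noise_cv=0.1, seed=11, n_alignment_records=400)


@pytest.fixture(scope="session")
def noisy_results(noisy_bundle):
    return score_panel(noisy_bundle)
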