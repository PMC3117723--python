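import pytest

from sirnaseats import GeneRecord

# The three-gene demonstration collection used throughout: with n=3 the
# kernels AAT and ATC are shared between the second and third gene and
# everything else is gene-specific.
DEMO_SEQS = [("G1", "AGAGAGGC"), ("G2", "TCAATCCC"), ("G3", "AATAAATC")]


@pytest.fixture
def demo_genes():
    return [GeneRecord(gid, "", seq) for gid, seq in DEMO_SEQS]


@pytest.fixture
def demo_fasta(tmp_path):
    path = tmp_path / "demo.fasta"
    path.write_text("".join(f">{gid}\n{seq}\n" for gid, seq in DEMO_SEQS))
    return path
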