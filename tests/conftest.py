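import random

import pytest

from hypermut.seqio import SeqRecordN, ingest_aligned_fasta


def gapless_alignment(ref_seq: str, qry_seq: str, ref_id="ref", qry_id="qry"):
    """Pairwise alignment of two equal-length, already-aligned sequences."""
    (aln,) = ingest_aligned_fasta(
        [SeqRecordN(ref_id, ref_seq), SeqRecordN(qry_id, qry_seq)], ref_id
    )
    return aln


def random_dna(rng: random.Random, n: int, alphabet="ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


@pytest.fixture
def rng():
    return random.Random(20240917)
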