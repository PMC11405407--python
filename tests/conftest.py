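import numpy as np
import pytest

from spliceometab import SimulationConfig, TranscriptModel, generate_annotation


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=1, n_genes=20, weak_fraction=0.5)


@pytest.fixture(scope="session")
def small_annotation(sim_config):
    """20 genes (10 weak-donor), alternating strands, with genome + truth."""
    return generate_annotation(sim_config)


def make_transcript(exon_seqs, intron_seqs, strand="+", gene_id="T", pad=10):
    """Build a transcript + single-contig genome from explicit block sequences.

    Blocks are given in transcript orientation; for minus-strand genes the
    contig holds the reverse complement.
    """
    from spliceometab.annotation import reverse_complement

    assert len(exon_seqs) == len(intron_seqs) + 1
    tx = []
    for i, ex in enumerate(exon_seqs):
        tx.append(ex)
        if i < len(intron_seqs):
            tx.append(intron_seqs[i])
    tx_seq = "".join(tx)
    pad5 = "A" * pad
    contig = pad5 + (tx_seq if strand == "+" else reverse_complement(tx_seq)) + "A" * pad

    exon_lens = [len(e) for e in exon_seqs]
    intron_lens = [len(i) for i in intron_seqs]
    exons = []
    if strand == "+":
        pos = pad
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el + (intron_lens[i] if i < len(intron_lens) else 0)
    else:
        pos = pad
        for i in range(len(exon_lens) - 1, -1, -1):
            exons.append((pos, pos + exon_lens[i]))
            pos += exon_lens[i] + (intron_lens[i - 1] if i > 0 else 0)
        exons.sort()
    t = TranscriptModel(gene_id=gene_id, transcript_id=f"{gene_id}.T1",
                        chrom="chr_test", strand=strand, exons=exons)
    return t, {"chr_test": contig}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
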