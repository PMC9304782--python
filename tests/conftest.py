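"""Shared fixtures: the switch dictionary, a hand-built toy genome, and a
session-scoped synthetic study with a planted context signal."""

from types import SimpleNamespace

import numpy as np
import pytest

import crcs
from crcs.embedding import EmbeddingConfig, TupleGenConfig, corpus_tuples, train_embeddings
from crcs.models import GeneModel
from crcs.simulate import (
    GenomeSimConfig,
    VariantSimConfig,
    encode_variant_sets,
    simulate_genome,
    simulate_variants,
)


@pytest.fixture(scope="session")
def dictionary():
    return crcs.build_switch_dictionary()


@pytest.fixture(scope="session")
def toy_genome():
    """Tiny hand-built genome: one forward gene, one minus-strand two-exon
    gene whose spliced reverse complement reads ATGTAA."""
    #          0123456789012345678901234567
    chr1 = "CCCCATGGAAGTACCCC"  # gene F: exon (4, 13), CDS ATGGAAGTA
    # gene R on chr2: transcript CDS ATGTAA; genomic revcomp = TTACAT split
    # TTA | CAT around an intron
    chr2 = "GGTTAGGGGCATGG"  # exons (2,5)=TTA and (9,12)=CAT
    ref = {"chr1": chr1, "chr2": chr2}
    fwd = GeneModel("tF.1", "GENEF", "chr1", "+", ((4, 13),))
    rev = GeneModel("tR.1", "GENER", "chr2", "-", ((2, 5), (9, 12)))
    return SimpleNamespace(ref=ref, fwd=fwd, rev=rev, models=[fwd, rev])


@pytest.fixture(scope="session")
def signal_study(dictionary):
    """Synthetic two-class study with a strong planted context signal
    (beta = 0.9) plus a small trained embedding matrix."""
    ref, models = simulate_genome(GenomeSimConfig(n_genes=60, seed=7))
    res = simulate_variants(
        ref, models, VariantSimConfig(n_per_class=200, beta=0.9, seed=7)
    )
    seqs, labels = encode_variant_sets(res, models, dictionary)
    tuples = corpus_tuples(seqs, TupleGenConfig(seed=1))
    emb = train_embeddings(
        tuples,
        EmbeddingConfig(embedding_length=24, epochs=8, seed=1),
        dict_fingerprint=dictionary.fingerprint,
    )
    return SimpleNamespace(
        ref=ref, models=models, result=res, seqs=seqs, labels=labels, emb=emb
    )
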