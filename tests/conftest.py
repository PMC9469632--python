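import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from cmic import (
    CmicPipeline,
    EmbeddingTable,
    SyntheticSpec,
    cross_validate,
    generate_dataset,
    make_embedding_table,
)
from cmic.config import SCALED_DOWN_EMBEDDING_MODE, scaled_down_configs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_table(rng):
    """Small random embedding table over a handful of 2-mers, D=4."""
    vocab = ["AA", "AC", "AG", "AT", "CA", "CC", "GG", "GT", "TT"]
    return EmbeddingTable({t: rng.normal(size=4) for t in vocab}, 4)


def _run_cv(seqs, table, seg, tr, seeds):
    out = []
    for seed in seeds:
        pipe = CmicPipeline(table, seg, tr,
                            embedding_mode=SCALED_DOWN_EMBEDDING_MODE)
        cv = cross_validate(seqs, pipe, k=3, seed=seed)
        out.append(cv.summary["per_cgi"])
    return out


@pytest.fixture(scope="session")
def scaled_experiment():
    """The desk-scale synthetic recovery experiment, run once per session.

    150/60 CGI-like sequences with planted 10-mer motifs (3 copies each),
    3-fold CGI-stratified CV under the scaled-down study conditions, for
    three seeds at N=50 and three at N=1 (the no-augmentation control).
    """
    seg, emb, tr = scaled_down_configs()
    seqs, _ = generate_dataset(SyntheticSpec(seed=0))

    table50 = make_embedding_table(seqs, "splitDNA2vec", seg, emb)
    reports50 = _run_cv(seqs, table50, seg, tr, seeds=(1, 2, 3))

    seg1 = replace(seg, n_replicates=1)
    emb1 = replace(emb, corpus_replicates=1)
    table1 = make_embedding_table(seqs, "splitDNA2vec", seg1, emb1)
    reports1 = _run_cv(seqs, table1, seg1, tr, seeds=(1, 2, 3))

    return {"n50": reports50, "n1": reports1}


@pytest.fixture(scope="session")
def null_experiment():
    """Same protocol with motif_copies=0: the classes are exchangeable."""
    seg, emb, tr = scaled_down_configs()
    seqs, _ = generate_dataset(SyntheticSpec(motif_copies=0, seed=0))
    table = make_embedding_table(seqs, "splitDNA2vec", seg, emb)
    return _run_cv(seqs, table, seg, tr, seeds=(1,))[0]
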