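import numpy as np
import pytest

import flavopan as fp
from flavopan import simulate as sim


@pytest.fixture(scope="session")
def small_bundle():
    """Noise-free synthetic genome set: 6 genomes, 30 core families."""
    return sim.simulate_genome_set(
        n_genomes=6, core_size=30, kappa=12, alpha=0.6, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def make_hit(q, s, identity=80.0, length=100, evalue=1e-50, qlen=100, slen=100):
    return fp.SimilarityHit(
        query_id=q,
        subject_id=s,
        percent_identity=identity,
        aligned_length=length,
        evalue=evalue,
        bitscore=200.0,
        query_length=qlen,
        subject_length=slen,
    )


def clique_hits(genes, **kw):
    """Symmetric all-vs-all hits among a gene set."""
    return [make_hit(q, s, **kw) for q in genes for s in genes if q != s]
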