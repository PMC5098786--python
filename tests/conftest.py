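import numpy as np
import pandas as pd
import pytest

from koinfer.refdb import GenomeRecord, ReferenceDatabase
from koinfer.synthetic import SyntheticSpec, generate_community, generate_reference
from koinfer.tables import OtuTable


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(
        n_genomes=6, n_kos=30, n_otus=12, n_samples=4, divergence=0.0,
        rep_len=250, seed=11,
    )


@pytest.fixture(scope="session")
def small_ref(small_spec):
    """A 6-genome synthetic reference plus generator bookkeeping."""
    return generate_reference(small_spec)


@pytest.fixture(scope="session")
def exact_community(small_spec, small_ref):
    """Divergence-0 community whose reps are exact windows of reference 16S."""
    db, _ = small_ref
    return generate_community(db, small_spec)


@pytest.fixture(scope="session")
def toy_db():
    """Two handcrafted genomes with known 16S sequences and copy numbers."""
    rng = np.random.default_rng(7)
    seq_a = random_seq(rng, 1450)
    seq_b = random_seq(rng, 1520)
    genomes = {
        "gA": GenomeRecord(
            genome_id="gA", rrna_seqs=(seq_a,),
            ko_copies={"K00001": 4, "K00002": 1},
        ),
        "gB": GenomeRecord(
            genome_id="gB", rrna_seqs=(seq_b, seq_b),
            ko_copies={"K00002": 6, "K00003": 2},
        ),
    }
    return ReferenceDatabase(genomes=genomes)


def make_otu_table(values, otu_ids=None, sample_ids=None) -> OtuTable:
    arr = np.asarray(values, dtype=float)
    otu_ids = otu_ids or [f"OTU{i + 1}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(arr.shape[1])]
    return OtuTable(pd.DataFrame(arr, index=otu_ids, columns=sample_ids))
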