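import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import hebkit as hk

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def population():
    """A compact simulated F5 population shared by read-only tests."""
    return hk.simulate_population(hk.SimConfig(n_triads=240, seed=7))


@pytest.fixture(scope="session")
def heb(population):
    return hk.heb_table(population.tpm, population.triads)


@pytest.fixture()
def tiny_triads():
    """Two triads with hand-set coordinates for interval/annotation tests."""
    triads = pd.DataFrame(
        {"gene_A": ["gA1", "gA2"], "gene_B": ["gB1", "gB2"],
         "gene_D": ["gD1", "gD2"]},
        index=pd.Index(["t1", "t2"], name="triad_id"),
    )
    genes = pd.DataFrame(
        {
            "chrom": ["chr1A", "chr1A", "chr1B", "chr1B", "chr1D", "chr1D"],
            "start": [1000, 1400, 1000, 5000, 1000, 5000],
            "end": [2000, 2400, 2000, 6000, 2000, 6000],
            "subgenome": ["A", "A", "B", "B", "D", "D"],
        },
        index=pd.Index(["gA1", "gA2", "gB1", "gB2", "gD1", "gD2"],
                       name="gene_id"),
    )
    return hk.TriadTable(triads, genes)


def make_genotype_matrix(calls: dict, depth: int | dict = 30,
                         chrom="chr1A", start_pos=100):
    """Build a GenotypeMatrix from {snp_id: {sample: call}} dicts."""
    calls_df = pd.DataFrame(calls).T
    calls_df.index.name = "snp_id"
    if isinstance(depth, int):
        depth_df = pd.DataFrame(depth, index=calls_df.index,
                                columns=calls_df.columns)
    else:
        depth_df = pd.DataFrame(depth).T.reindex(calls_df.index)
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(start_pos,
                                          start_pos + len(calls_df)),
         "gene": pd.array([pd.NA] * len(calls_df), dtype="object")},
        index=calls_df.index,
    )
    return hk.GenotypeMatrix(snps, calls_df, depth_df)
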