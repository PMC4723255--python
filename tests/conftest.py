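import numpy as np
import pytest

from radmarker import fixtures
from radmarker.pileup import read_pileup


@pytest.fixture(scope="session")
def toy_spec():
    return fixtures.SimSpec(
        seed=11,
        n_chroms=2,
        chrom_length=60_000,
        n_genes=6,
        n_divergent_snps=30,
        n_divergent_indels=8,
        mean_depth=20.0,
        error_rate=0.01,
    )


@pytest.fixture(scope="session")
def toy_dataset(toy_spec, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("toy_sim")
    paths = fixtures.simulate(toy_spec, outdir)
    return paths


@pytest.fixture(scope="session")
def toy_sites(toy_dataset):
    a = {(s.chrom, s.pos): s for s in read_pileup(toy_dataset["pileup_a"])}
    b = {(s.chrom, s.pos): s for s in read_pileup(toy_dataset["pileup_b"])}
    return a, b


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
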