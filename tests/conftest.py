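import numpy as np
import pandas as pd
import pytest

from bayesr.io import RawGenotypes, SnpInfo
from bayesr.model import ChainConfig
from bayesr.sampler import run_chain
from bayesr.simulate import ArchitectureSpec, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_raw(counts, chrom=None, pos=None):
    """Build a RawGenotypes from a small integer matrix."""
    counts = np.asarray(counts, dtype=np.int8)
    n, p = counts.shape
    snps = SnpInfo(
        ids=np.array([f"rs{j}" for j in range(p)]),
        chrom=np.asarray(chrom if chrom is not None else ["1"] * p, dtype=str),
        pos=np.asarray(pos if pos is not None else 1000 * (1 + np.arange(p)), dtype=np.int64),
        allele1=np.full(p, "A"),
        allele2=np.full(p, "C"),
    )
    fam = pd.DataFrame({"fid": [f"F{i}" for i in range(n)],
                        "iid": [f"I{i}" for i in range(n)]})
    return RawGenotypes(counts=counts, sample_ids=fam, snps=snps)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest three-class simulation shared across chain tests."""
    rng = np.random.default_rng(777)
    spec = ArchitectureSpec(class_counts=(2, 20, 100), h2_target=0.5)
    raw, std, y, truth = simulate_dataset(400, 600, spec, rng, n_chromosomes=4)
    return std, y, truth


@pytest.fixture(scope="session")
def fitted_samples(small_dataset):
    """One short but converged chain on the shared dataset."""
    std, y, _ = small_dataset
    cfg = ChainConfig(n_iter=3000, burn_in=1000, thin=4, seed=99)
    return run_chain(std.W, y, config=cfg, chrom=std.snps.chrom)
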