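import numpy as np
import pandas as pd
import pytest

from gsmrkit import SummaryDataset


def make_dataset(
    name,
    betas,
    ses,
    snp_ids=None,
    pvals=None,
    eafs=None,
    a1="A",
    a2="G",
    n=10000,
    bp=None,
    chrom=None,
    trait_type="quantitative",
):
    """Small hand-rolled summary dataset with self-consistent p-values."""
    from scipy import stats

    m = len(betas)
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if pvals is None:
        pvals = np.maximum(2 * stats.norm.sf(np.abs(betas / ses)), 5e-324)
    if snp_ids is None:
        snp_ids = [f"rs{i + 1}" for i in range(m)]
    if eafs is None:
        eafs = [0.3] * m
    a1 = [a1] * m if isinstance(a1, str) else a1
    a2 = [a2] * m if isinstance(a2, str) else a2
    return SummaryDataset.from_arrays(
        name, trait_type,
        snp_id=snp_ids, effect_allele=a1, other_allele=a2,
        eaf=eafs, beta=betas, se=ses, pval=pvals, n=[n] * m,
        chrom=chrom, bp=bp,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_ma(tmp_path):
    """A 3-row .ma file on disk."""
    path = tmp_path / "tiny.ma"
    path.write_text(
        "SNP A1 A2 freq b se p N\n"
        "rs1 A G 0.30 0.10 0.02 5.7e-07 10000\n"
        "rs2 C T 0.45 -0.05 0.02 0.0124 10000\n"
        "rs3 G A 0.10 0.00 0.03 1.0 10000\n"
    )
    return path
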