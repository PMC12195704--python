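import numpy as np
import pytest

from mrscreen import HarmonizedPair, VariantAssociation
from mrscreen.harmonize import Action
from mrscreen.sumstats import normal_pvalue


def make_variant(
    vid="rs1",
    chrom="1",
    pos=1_000_000,
    ea="G",
    oa="A",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pval=None,
    n=20_000,
):
    return VariantAssociation(
        variant_id=vid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se,
        pval=pval if pval is not None else normal_pvalue(beta, se), n=n,
    )


def make_pair(vid="rs1", beta_exp=0.1, se_exp=0.01, beta_out=0.02, se_out=0.01,
              eaf_exp=0.3, eaf_out=0.3, n_exp=30_000, n_out=20_000):
    return HarmonizedPair(
        variant_id=vid, effect_allele="G", other_allele="A",
        beta_exp=beta_exp, se_exp=se_exp, beta_out=beta_out, se_out=se_out,
        eaf_exp=eaf_exp, eaf_out=eaf_out, action=Action.AS_IS,
        n_exp=n_exp, n_out=n_out,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def five_pairs():
    """Fixed K=5 instrument set with mild heterogeneity."""
    bx = [0.10, 0.12, 0.15, 0.11, 0.13]
    by = [0.021, 0.023, 0.078, 0.020, 0.055]
    sy = [0.010, 0.012, 0.011, 0.009, 0.013]
    sx = [0.005, 0.006, 0.005, 0.005, 0.006]
    return [
        make_pair(vid=f"rs{i}", beta_exp=bx[i], se_exp=sx[i],
                  beta_out=by[i], se_out=sy[i])
        for i in range(5)
    ]
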