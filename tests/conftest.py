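import numpy as np
import pytest

from mrpipe.sumstats_io import GwasPanel, HarmonisedSet, VariantAssociation
from mrpipe.synthetic_gwas import SimulationConfig, simulate_triplet


def make_record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                beta=0.1, se=0.02, pval=1e-9, n=10_000):
    return VariantAssociation(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pval=pval, n=n,
    )


def make_panel(records, trait_id="trait", trait_type="continuous", sample_size=None):
    if sample_size is None:
        sample_size = max(r.n for r in records)
    return GwasPanel(
        trait_id=trait_id, trait_type=trait_type,
        records=tuple(records), sample_size=sample_size,
    )


def make_hset(beta_exp, se_exp, beta_out, se_out, n_exp=50_000, n_out=50_000):
    k = len(beta_exp)
    return HarmonisedSet(
        snp_ids=tuple(f"rs{i}" for i in range(k)),
        beta_exp=np.asarray(beta_exp, float),
        se_exp=np.asarray(se_exp, float),
        beta_out=np.asarray(beta_out, float),
        se_out=np.asarray(se_out, float),
        eaf=np.full(k, 0.3),
        n_exp=np.full(k, n_exp),
        n_out=np.full(k, n_out),
    )


@pytest.fixture
def clean_triplet():
    """Moderate-effect triplet with no pleiotropy and no allele noise."""
    return simulate_triplet(
        SimulationConfig(n_snps=30, theta_direct=0.2, seed=7)
    )


@pytest.fixture
def mediation_triplet():
    """Triplet with a genuine mediated pathway and strong instruments."""
    return simulate_triplet(
        SimulationConfig(
            n_snps=30, theta_direct=0.1, alpha=0.5, b_med=0.2,
            exposure_effect_sd=0.15, med_effect_sd=0.1, seed=11,
        )
    )
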