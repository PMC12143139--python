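import numpy as np
import pandas as pd
import pytest

import xcierosion as x
from xcierosion import ase, simulate as sim


@pytest.fixture(scope="session")
def small_config():
    return x.SimConfig(
        n_x_genes=80,
        n_autosomal_genes=120,
        erosion_degrees=(0.0, 0.9),
        n_replicates=2,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return x.build_x_landscape(small_config)


@pytest.fixture(scope="session")
def small_expression(small_truth):
    return x.simulate_expression(small_truth)


def snps_from_truth(truth):
    """Materialize the generator's SNPs as phased records (hapB = Xi)."""
    return [
        x.PhasedSnp(
            chrom=r.chrom,
            pos=r.pos,
            ref_allele=r.ref,
            alt_allele=r.alt,
            hapA_allele=(r.ref if r.alt_on_xi else r.alt),
            hapB_allele=(r.alt if r.alt_on_xi else r.ref),
            snp_id=r.snp_id,
            gene_id=r.gene_id,
        )
        for r in truth.snps.itertuples(index=False)
    ]


@pytest.fixture(scope="session")
def small_profiles(small_truth, small_expression):
    _, allelic, _ = small_expression
    return ase.profiles_from_counts(allelic, snps_from_truth(small_truth))


def line_of(sample: str) -> str:
    return sample.rsplit("_r", 1)[0]
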