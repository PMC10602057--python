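"""Shared fixtures: one synthetic dataset with a fitted factor model.

The expensive pieces (panel generation, LDSC matrices, factor discovery)
are session-scoped so every test module can reuse them.
"""

import numpy as np
import pytest

from gibnet import factors, ldsc, simulate
from gibnet.sumstats import SnpRecord


@pytest.fixture(scope="session")
def demo_truth():
    return simulate.TruthConfig(seed=3, injected_effects=(("rs500", 0, 0.05),))


@pytest.fixture(scope="session")
def demo_dataset(demo_truth):
    return simulate.generate_dataset(demo_truth)


@pytest.fixture(scope="session")
def demo_gencov(demo_dataset):
    ds = demo_dataset
    return {
        subset: ldsc.build_gencov_matrix(ds.panel, ds.ldscores, subset)
        for subset in ("odd", "even", "all")
    }


@pytest.fixture(scope="session")
def demo_model(demo_gencov):
    selected, candidates = factors.run_factor_discovery(
        demo_gencov["odd"], demo_gencov["even"], k_range=range(1, 7)
    )
    return selected


@pytest.fixture(scope="session")
def demo_corr_even(demo_gencov):
    return factors.standardize_to_correlation(demo_gencov["even"])


def make_record(snp_id="rs1", a1="A", a2="G", n=1000.0, z=1.0, chrom=1, bp=1000, maf=0.25):
    return SnpRecord(snp_id=snp_id, a1=a1, a2=a2, n=n, z=z, chrom=chrom, bp=bp, maf=maf)


@pytest.fixture
def record_factory():
    return make_record
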