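import numpy as np
import pandas as pd
import pytest

from sepstrat.datatypes import ExpressionMatrix
from sepstrat.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Compact cohort: full sample count, thinned probe/SNP panels."""
    return SimConfig(
        seed=11,
        n_samples=265,
        n_probes=3000,
        n_snps=1200,
        n_de_probes=350,
        n_cis_eqtl=80,
        n_trans_eqtl=10,
        n_group_specific=10,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_expression(values, prefix="P", chrom="chr1"):
    """Wrap a raw matrix in an ExpressionMatrix with synthetic annotation."""
    values = np.asarray(values, float)
    n_probes, n_samples = values.shape
    return ExpressionMatrix(
        values=values,
        probe_ids=np.array([f"{prefix}{i:05d}" for i in range(n_probes)], dtype=object),
        probe_chrom=np.array([chrom] * n_probes, dtype=object),
        probe_start=np.arange(1, n_probes + 1) * 1000,
        sample_ids=np.array([f"S{i:04d}" for i in range(n_samples)], dtype=object),
    )


@pytest.fixture()
def two_blob_expression(rng):
    """120 samples in two 10-sigma-separated Gaussian blobs on 50 probes."""
    n1, n2, p = 50, 70, 50
    a = rng.normal(0.0, 1.0, (p, n1))
    b = rng.normal(10.0, 1.0, (p, n2))
    truth = np.array([0] * n1 + [1] * n2)
    return make_expression(np.hstack([a, b])), truth
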