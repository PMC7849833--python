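import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from regsnv.io_formats import GeneModel, SNVRecord
from regsnv.synthetic_data import SimConfig, simulate_cohort

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact cohort exercising every feature class."""
    return SimConfig(
        n_samples=80, n_genes=120, n_probes=60,
        n_effect_genes_expr=6, n_effect_genes_meth=4,
        n_cna_confounded=3, n_sv_confounded=3,
        carrier_fraction=0.1, seed=42,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_cohort(small_config)


@pytest.fixture
def plus_gene() -> GeneModel:
    return GeneModel(
        gene_id="gplus", symbol="GP", chrom="chr1", strand="+",
        tx_start=10_000, tx_end=16_000,
        exons=[(10_000, 10_600), (12_200, 12_800), (15_400, 16_000)],
        cds_start=10_300, cds_end=15_700,
    )


@pytest.fixture
def minus_gene() -> GeneModel:
    return GeneModel(
        gene_id="gminus", symbol="GM", chrom="chr1", strand="-",
        tx_start=5_000, tx_end=6_000,
        exons=[(5_000, 5_300), (5_700, 6_000)],
        cds_start=5_100, cds_end=5_900,
    )


def make_snv(sample, chrom, pos, ref="A", alt="C") -> SNVRecord:
    return SNVRecord(sample, chrom, pos, ref, alt)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
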