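import numpy as np
import pytest

from gwasnet.glm import logistic_scan
from gwasnet.simulate import SimulationConfig, simulate_cohort, simulate_study

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def tiny_config():
    """Small study: every stage runs in seconds."""
    return SimulationConfig(
        n_cases=(120, 120, 120), n_controls=(120, 120, 120),
        n_snps=300, n_genes=30, ld_block_size=10, ld_rho=0.6,
        n_planted_modules=2, planted_module_size=4, planted_or=2.0,
        snp_keep_fraction=1.0, missing_rate=0.02, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_study(tiny_config)


@pytest.fixture(scope="session")
def null_scan():
    """Null cohort (no planted effect, independent SNPs) and its Wald scan.

    Shared by the P-value uniformity and genomic-inflation checks.
    """
    cfg = SimulationConfig(
        n_cases=2000, n_controls=2000, n_snps=10_000, n_genes=1000,
        ld_rho=0.0, planted_or=1.0, missing_rate=0.0,
        snp_keep_fraction=1.0, batch_effect_sd=0.0, seed=41,
    )
    data = simulate_cohort(cfg, 0)
    scan = logistic_scan(data.dosage(impute=False), data.phenotype)
    return data, scan
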