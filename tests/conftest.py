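import numpy as np
import pandas as pd
import pytest

from pgsem.simulate import (CohortSpec, TrueArchitecture, make_gwas_suite,
                            simulate_ld_panel)
from pgsem.sumstats import SumStats


@pytest.fixture(scope="session")
def tiny_panel():
    """5 blocks of 10 SNPs, mixed correlations, 50 SNPs total."""
    return simulate_ld_panel(block_sizes=[10] * 5, rhos=[0.0, 0.3, 0.5, 0.7, 0.85],
                             m=50, seed=42)


@pytest.fixture(scope="session")
def small_suite():
    """A small but realistic two-trait suite shared by read-only tests."""
    panel = simulate_ld_panel(block_sizes=[20] * 25, rhos=[0.0, 0.4, 0.6, 0.8, 0.2] * 5,
                              m=500, seed=7)
    Lam = np.array([[0.75], [0.70]])
    Psi = 1.0 - (Lam @ Lam.T).diagonal()
    arch = TrueArchitecture(Lambda=Lam, Psi=Psi, h2=np.array([0.4, 0.4]))
    specs = [CohortSpec(trait=0, n=4000), CohortSpec(trait=1, n=4000)]
    return make_gwas_suite(panel, arch, specs, seed=7)


def make_sumstats(n_snps=10, seed=0, **overrides) -> SumStats:
    """Hand-buildable sumstats table with consistent z/p."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    beta = overrides.pop("BETA", rng.normal(0, 0.05, n_snps))
    se = overrides.pop("SE", np.full(n_snps, 0.02))
    z = np.asarray(beta) / np.asarray(se)
    table = pd.DataFrame({
        "SNP": [f"rs{i + 1}" for i in range(n_snps)],
        "CHR": 1,
        "BP": 1 + 5000 * np.arange(n_snps),
        "A1": "A",
        "A2": "G",
        "BETA": beta,
        "SE": se,
        "P": np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
        "N": 10000,
        "MAF": rng.uniform(0.05, 0.5, n_snps).round(3),
    })
    for col, val in overrides.items():
        table[col] = val
    return SumStats(table, trait=f"toy{seed}")
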