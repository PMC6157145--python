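import numpy as np
import pandas as pd
import pytest

from methepi.data import (
    CovariateTable,
    GenotypeMatrix,
    MethylationPair,
    TriglyceridePanel,
)
from methepi.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale cohort parameters for fast end-to-end tests."""
    return SimulationConfig(n_subjects=200, n_cpgs=400, n_genes=150,
                            n_categories=12, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture
def toy_panel():
    """Complete 5-subject TG panel with simple values."""
    frame = pd.DataFrame(
        {
            "tg1": [100.0, 120.0, 90.0, 150.0, 110.0],
            "tg2": [105.0, 118.0, 95.0, 140.0, 112.0],
            "tg3": [80.0, 100.0, 85.0, 120.0, 95.0],
            "tg4": [82.0, 98.0, 88.0, 118.0, 93.0],
        },
        index=pd.Index([f"S{i}" for i in range(1, 6)], name="sample_id"),
    )
    return TriglyceridePanel(frame)


def make_methylation(beta_pre, beta_post, sample_prefix="S", cpg_prefix="cg"):
    beta_pre = np.atleast_2d(np.asarray(beta_pre, dtype=float))
    beta_post = np.atleast_2d(np.asarray(beta_post, dtype=float))
    n, p = beta_pre.shape
    return MethylationPair(
        [f"{sample_prefix}{i}" for i in range(n)],
        [f"{cpg_prefix}{j}" for j in range(p)],
        beta_pre,
        beta_post,
    )


def make_genotypes(dosage, genes, mafs=None, sample_ids=None):
    """GenotypeMatrix from a plain dosage array and per-SNP gene labels."""
    dosage = np.asarray(dosage, dtype=float)
    n, k = dosage.shape
    snp_ids = [f"snp{j + 1}" for j in range(k)]
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    if mafs is None:
        mafs = [0.3] * k
    info = pd.DataFrame(
        {
            "chr": ["16"] * k,
            "pos": 1000 + 10 * np.arange(k),
            "gene": list(genes),
            "alleles": ["A/G"] * k,
            "maf": mafs,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(
        pd.DataFrame(dosage, index=pd.Index(sample_ids, name="sample_id"),
                     columns=snp_ids),
        info,
    )


def make_covariates(n, rng, sample_ids=None):
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    return CovariateTable(
        pd.DataFrame(
            {
                "avg_pre_tg": rng.uniform(60, 250, n),
                "age": rng.integers(20, 80, n).astype(float),
                "center": rng.choice(["MN", "UT"], n),
                "current_smoker": rng.integers(0, 2, n).astype(float),
                "sex": rng.integers(0, 2, n).astype(float),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
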