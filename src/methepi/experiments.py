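"""Replicated operating-characteristic studies of the epistasis scan.

These routines measure, by Monte-Carlo replication over fresh synthetic
cohorts, the two properties the targeted scan is designed around:

* family-wise type-I error control at the Bonferroni threshold when no
  interaction exists, and
* power to detect a planted interaction-only signal while both
  constituent SNPs remain non-significant in single-locus tests.

They are used by the validation suite and the reproduction script, and
are available to users who want to re-run the calibration at other
parameter values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import CovariateTable, GenotypeMatrix
from .epistasis import epistasis_scan
from .simulate import (
    SimulationConfig,
    simulate_covariates,
    simulate_genotypes,
    simulate_phenotype_epistasis,
)

__all__ = ["null_scan_fwer", "planted_pair_recovery"]


def _replicate_inputs(config: SimulationConfig, rng: np.random.Generator):
    """Fresh genotypes + covariates for one scan replicate."""
    n = config.n_subjects
    genoA = simulate_genotypes(
        config.snp_mafs_geneA, n, rng, gene=config.gene_a, snp_prefix="a"
    )
    genoB = simulate_genotypes(
        config.snp_mafs_geneB, n, rng, gene=config.gene_b, snp_prefix="b",
        sample_ids=genoA.sample_ids,
    )
    cov = simulate_covariates(
        n, rng, rng.uniform(60, 250, n), genoA.sample_ids
    )
    geno = GenotypeMatrix(
        pd.concat([genoA.dosage, genoB.dosage], axis=1),
        pd.concat([genoA.snp_info, genoB.snp_info]),
    )
    return genoA, genoB, geno, cov


def _marginal_snp_p(y: pd.Series, g: np.ndarray, cov: CovariateTable) -> float:
    """Two-sided p for the dosage slope in y ~ 1 + covariates + g."""
    X = np.column_stack(
        [np.ones(len(y)), cov.design_matrix().to_numpy(dtype=float), g]
    )
    coef, _, _, _ = np.linalg.lstsq(X, y.to_numpy(dtype=float), rcond=None)
    resid = y.to_numpy(dtype=float) - X @ coef
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    t = coef[-1] / se
    return float(2 * stats.t.sf(abs(t), df=df))


def null_scan_fwer(
    n_reps: int = 500,
    seed: int = 0,
    config: SimulationConfig | None = None,
    alpha: float = 0.05,
) -> dict:
    """Family-wise rejection rate of the scan with no genetic effect.

    Each replicate draws fresh genotypes, covariates and a phenotype with
    ``beta_int = 0`` (covariate effects plus noise only), scans all
    cross-gene pairs, and records whether any pair clears alpha/m.  The
    Bonferroni guarantee bounds the expected rate by alpha.
    """
    config = config or SimulationConfig(seed=seed)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    rejections = 0
    m = None
    for child in children:
        rng = np.random.default_rng(child)
        genoA, genoB, geno, cov = _replicate_inputs(config, rng)
        pair = (genoA.snp_ids[0], genoB.snp_ids[0])
        y = simulate_phenotype_epistasis(
            geno, cov, pair, 0.0, config.noise_sd, rng
        )
        table = epistasis_scan(y, genoA, genoB, cov, alpha=alpha)
        m = table.attrs["m"]
        if table["significant"].any():
            rejections += 1
    return {
        "fwer": rejections / n_reps,
        "n_reps": n_reps,
        "m": m,
        "alpha": alpha,
    }


def planted_pair_recovery(
    n_reps: int = 200,
    seed: int = 0,
    config: SimulationConfig | None = None,
    alpha: float = 0.05,
    marginal_bonferroni_m: int | None = None,
) -> dict:
    """Power and marginal-suppression rates at the planted interaction.

    Per replicate: plant ``config.interaction_beta`` on the pair formed
    by the first SNP of each gene, scan, and record (a) whether that pair
    attains the minimum p *and* clears the Bonferroni threshold, and (b)
    whether both SNPs' single-locus tests stay above the marginal
    Bonferroni level alpha / (|A| + |B|).
    """
    config = config or SimulationConfig(seed=seed)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    top_and_sig = 0
    marginals_null = 0
    for child in children:
        rng = np.random.default_rng(child)
        genoA, genoB, geno, cov = _replicate_inputs(config, rng)
        pair = (genoA.snp_ids[0], genoB.snp_ids[0])
        y = simulate_phenotype_epistasis(
            geno, cov, pair, config.interaction_beta, config.noise_sd, rng
        )
        table = epistasis_scan(y, genoA, genoB, cov, alpha=alpha)
        top = table.iloc[0]
        if (top.snp_a, top.snp_b) == pair and bool(top.significant):
            top_and_sig += 1
        m_marg = marginal_bonferroni_m or (
            len(genoA.snp_ids) + len(genoB.snp_ids)
        )
        cutoff = alpha / m_marg
        if all(
            _marginal_snp_p(y, geno.dosage[snp].to_numpy(dtype=float), cov)
            > cutoff
            for snp in pair
        ):
            marginals_null += 1
    return {
        "top_and_significant_rate": top_and_sig / n_reps,
        "marginal_nonsignificant_rate": marginals_null / n_reps,
        "n_reps": n_reps,
        "beta_int": config.interaction_beta,
        "alpha": alpha,
    }
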