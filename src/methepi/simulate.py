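"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a pharmacoepigenetic trial of ~680 subjects: four
triglyceride visits (two pre-, two post-treatment) with high within-block
correlations, paired pre/post methylation over configurable numbers of
CpG sites with a treatment shift at a chosen fraction of sites, SNP
dosages for two candidate genes sampled under Hardy–Weinberg equilibrium
at fixed minor-allele frequencies, standard covariates, and a phenotype
carrying a *pure* epistatic signal: an interaction between one SNP from
each gene built on centred dosages, so each SNP's additive marginal
effect is zero by construction.

Every planted signal is recorded in the cohort's ``truth`` record so that
downstream recovery can be scored.  All randomness flows from the single
configured seed through ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .data import (
    CovariateTable,
    CpGAnnotation,
    GeneSetDatabase,
    GenotypeMatrix,
    MethylationPair,
    TriglyceridePanel,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_genotypes",
    "simulate_triglyceride_panel",
    "simulate_methylation_pair",
    "simulate_phenotype_epistasis",
    "simulate_annotation_and_genesets",
    "simulate_covariates",
    "simulate_cohort",
]

# Candidate-gene MAFs for the scan defaults: the four FTO and three ALKBH5
# minor-allele frequencies used in the targeted analysis, padded with an
# even grid (gene A) and two mid-range values (gene B) to reach the
# 68 + 5 complete SNPs the scan operates on.
_GENE_A_CORE_MAFS = (0.34, 0.41, 0.29, 0.12)
_GENE_B_CORE_MAFS = (0.18, 0.45, 0.24)


def default_gene_a_mafs() -> list[float]:
    grid = np.round(np.linspace(0.05, 0.5, 64), 3)
    return list(_GENE_A_CORE_MAFS) + [float(v) for v in grid]


def default_gene_b_mafs() -> list[float]:
    return list(_GENE_B_CORE_MAFS) + [0.30, 0.38]


#: modest fixed covariate effects on the log-TG-ratio phenotype
DEFAULT_COVARIATE_EFFECTS = {
    "intercept": -0.18,
    "avg_pre_tg": -4e-4,   # per mg/dL
    "age": 1e-3,           # per year
    "center": 0.02,        # second centre vs first
    "current_smoker": 0.03,
    "sex": -0.02,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the emulated study conditions: 680 subjects,
    within-block TG visit correlations 0.90 (pre) and 0.91 (post), 68 + 5
    candidate-gene SNPs at the published minor-allele frequencies, 45% of
    CpG sites shifted by treatment, and an interaction-only genetic
    effect of 0.14 log-ratio units per centred-dosage product against a
    residual noise SD of 0.2.  CpG count defaults to 10^4 (the full
    463,995-site scale is available by setting ``n_cpgs``).
    """

    n_subjects: int = 680
    n_cpgs: int = 10_000
    frac_shifted_cpgs: float = 0.45
    shift_effect: float = 0.3        # logit-scale mean shift at affected sites
    tg_visit_corr_pre: float = 0.90
    tg_visit_corr_post: float = 0.91
    snp_mafs_geneA: list[float] = field(default_factory=default_gene_a_mafs)
    snp_mafs_geneB: list[float] = field(default_factory=default_gene_b_mafs)
    interaction_beta: float = 0.14   # phenotype units per centred-dosage product
    noise_sd: float = 0.2            # residual phenotype SD
    missing_visit_rate: float = 0.05
    seed: int = 0
    gene_a: str = "FTO"
    gene_b: str = "ALKBH5"
    n_genes: int = 800
    n_categories: int = 50
    enriched_category_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs must be >= 1")
        if not 0 <= self.frac_shifted_cpgs <= 1:
            raise ValueError("frac_shifted_cpgs must lie in [0, 1]")
        for name in ("tg_visit_corr_pre", "tg_visit_corr_post"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        for name in ("snp_mafs_geneA", "snp_mafs_geneB"):
            for maf in getattr(self, name):
                if not 0 < maf <= 0.5:
                    raise ValueError(f"{name}: MAF {maf} outside (0, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.missing_visit_rate < 0.5:
            raise ValueError("missing_visit_rate must lie in [0, 0.5)")


@dataclass
class SyntheticCohort:
    """A complete synthetic data set plus the truth record for scoring."""

    tg_panel: TriglyceridePanel
    meth: MethylationPair
    genotypes: GenotypeMatrix
    covariates: CovariateTable
    annotation: CpGAnnotation
    genesets: GeneSetDatabase
    truth: dict
    config: SimulationConfig

    @property
    def sample_ids(self) -> pd.Index:
        return self.tg_panel.sample_ids


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_ids(n: int) -> pd.Index:
    width = len(str(n))
    return pd.Index([f"S{i + 1:0{width}d}" for i in range(n)], name="sample_id")


def simulate_genotypes(
    mafs,
    n: int,
    seed,
    gene: str = "GENE",
    chrom: str = "1",
    start_pos: int = 1_000_000,
    snp_prefix: str | None = None,
    sample_ids: pd.Index | None = None,
) -> GenotypeMatrix:
    """HWE dosages: each SNP i.i.d. Binomial(2, maf) across n subjects.

    Metadata carries the input MAF and synthetic chr/pos/gene/allele
    labels; no missing values are produced.
    """
    mafs = [float(m) for m in mafs]
    if any(not 0 < m <= 0.5 for m in mafs):
        bad = [m for m in mafs if not 0 < m <= 0.5]
        raise ValueError(f"MAF must lie in (0, 0.5]; got {bad[:3]}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    prefix = snp_prefix or f"{gene.lower()}_snp"
    snp_ids = [f"{prefix}{i + 1:03d}" for i in range(len(mafs))]
    dosage = rng.binomial(2, np.asarray(mafs)[None, :], size=(n, len(mafs)))
    if sample_ids is None:
        sample_ids = _sample_ids(n)
    info = pd.DataFrame(
        {
            "chr": chrom,
            "pos": start_pos + 5000 * np.arange(len(mafs)),
            "gene": gene,
            "alleles": "A/G",
            "maf": mafs,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(
        pd.DataFrame(dosage.astype(float), index=sample_ids, columns=snp_ids), info
    )


def _paired_visits(
    shared: np.ndarray, rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two visits sharing ``shared`` with cross-visit correlation ``rho``."""
    var_s = float(np.var(shared))
    var_e = max(var_s, 1e-12) * (1 - rho) / rho
    e = rng.normal(0.0, np.sqrt(var_e), size=(2, len(shared)))
    return shared + e[0], shared + e[1]


def simulate_triglyceride_panel(
    config: SimulationConfig,
    seed=None,
    log_ratio: np.ndarray | None = None,
) -> TriglyceridePanel:
    """Four-visit TG panel with the configured within-block correlations.

    Visits are generated on the log scale (guaranteeing positivity) as a
    subject-level value plus visit noise whose variance is set so the
    population within-block correlation equals the target.  ``log_ratio``,
    when given, is the subject-level post/pre log-ratio signal (e.g. the
    planted epistatic phenotype); otherwise an independent response is
    drawn.  Missing visits are introduced at ``missing_visit_rate`` per
    visit, but never both visits of a block, so every subject keeps at
    least one observed pre- and one post-treatment value.
    """
    rng = _rng(config.seed if seed is None else seed)
    n = config.n_subjects
    base = rng.normal(np.log(110.0), np.sqrt(0.20), size=n)  # subject log TG level
    l1, l2 = _paired_visits(base, config.tg_visit_corr_pre, rng)
    if log_ratio is None:
        log_ratio = rng.normal(-0.18, 0.15, size=n)
    post_shared = base + np.asarray(log_ratio, dtype=float)
    l3, l4 = _paired_visits(post_shared, config.tg_visit_corr_post, rng)
    frame = pd.DataFrame(
        np.exp(np.column_stack([l1, l2, l3, l4])),
        index=_sample_ids(n),
        columns=["tg1", "tg2", "tg3", "tg4"],
    )
    rate = config.missing_visit_rate
    if rate > 0:
        for cols in (["tg1", "tg2"], ["tg3", "tg4"]):
            # at most one visit per block removed: P(each visit missing) = rate
            hit = rng.random(n) < 2 * rate
            which = rng.integers(0, 2, size=n)
            for j, col in enumerate(cols):
                frame.loc[hit & (which == j), col] = np.nan
    return TriglyceridePanel(frame)


def simulate_methylation_pair(config: SimulationConfig, seed=None) -> tuple[
    MethylationPair, list[str]
]:
    """Paired pre/post beta matrices with a treatment shift at some sites.

    Per site, each subject carries a latent logit-methylation level (site
    mean plus subject scatter); pre- and post-treatment measurements add
    independent measurement noise (SD 0.1 logit units) to that shared
    level, so with no shift the two visits are exchangeable and the
    paired null holds exactly.  A random ``frac_shifted_cpgs`` subset of
    sites additionally receives a logit-scale post-treatment mean shift
    of ``shift_effect`` with random sign.  Returns the pair and the list
    of shifted CpG ids (the truth).
    """
    rng = _rng(config.seed if seed is None else seed)
    n, p = config.n_subjects, config.n_cpgs
    width = len(str(p))
    cpg_ids = pd.Index([f"cg{i + 1:0{width}d}" for i in range(p)], name="cpg_id")
    mu = rng.normal(0.0, 1.3, size=p)           # site logit means
    subj_sd = rng.uniform(0.2, 0.6, size=p)     # between-subject scatter
    core = mu[None, :] + rng.normal(0.0, 1.0, size=(n, p)) * subj_sd[None, :]
    n_shift = int(round(config.frac_shifted_cpgs * p))
    shifted_idx = rng.choice(p, size=n_shift, replace=False)
    delta = np.zeros(p)
    delta[shifted_idx] = config.shift_effect * rng.choice([-1.0, 1.0], size=n_shift)
    x_pre = core + rng.normal(0.0, 0.1, size=(n, p))
    x_post = core + delta[None, :] + rng.normal(0.0, 0.1, size=(n, p))
    meth = MethylationPair(
        _sample_ids(n), cpg_ids, special.expit(x_pre), special.expit(x_post)
    )
    shifted_ids = cpg_ids[np.sort(shifted_idx)].tolist()
    return meth, shifted_ids


def simulate_covariates(
    n: int, seed, avg_pre_tg: np.ndarray, sample_ids: pd.Index | None = None
) -> CovariateTable:
    """Age, centre, smoking and sex with trial-typical distributions."""
    rng = _rng(seed)
    frame = pd.DataFrame(
        {
            "avg_pre_tg": np.asarray(avg_pre_tg, dtype=float),
            "age": np.clip(rng.normal(49.0, 12.0, size=n), 18, 90).round(0),
            "center": rng.choice(["MN", "UT"], size=n),
            "current_smoker": rng.binomial(1, 0.18, size=n),
            "sex": rng.binomial(1, 0.5, size=n),
        },
        index=sample_ids if sample_ids is not None else _sample_ids(n),
    )
    return CovariateTable(frame)


def covariate_linear_predictor(
    covariates: CovariateTable, effects: dict | None = None
) -> np.ndarray:
    eff = dict(DEFAULT_COVARIATE_EFFECTS if effects is None else effects)
    f = covariates.frame
    centers = sorted(f["center"].astype(str).unique())
    center_ind = (f["center"].astype(str) != centers[0]).to_numpy(dtype=float)
    return (
        eff["intercept"]
        + eff["avg_pre_tg"] * f["avg_pre_tg"].to_numpy(dtype=float)
        + eff["age"] * f["age"].to_numpy(dtype=float)
        + eff["center"] * center_ind
        + eff["current_smoker"] * f["current_smoker"].to_numpy(dtype=float)
        + eff["sex"] * f["sex"].to_numpy(dtype=float)
    )


def simulate_phenotype_epistasis(
    genotypes: GenotypeMatrix,
    covariates: CovariateTable | None,
    pair: tuple[str, str],
    beta_int: float,
    noise_sd: float,
    seed,
    covariate_effects: dict | None = None,
) -> pd.Series:
    """Phenotype with a pure (interaction-only) two-locus genetic effect.

    y = covariate effects + beta_int * (gA - mean(gA)) * (gB - mean(gB))
        + Normal(0, noise_sd).

    Centring the dosages makes the product uncorrelated with each dosage
    (under cross-gene independence), so each SNP's additive marginal
    effect is ~0 in the population: the signal is detectable only through
    the interaction term.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    snp_a, snp_b = pair
    for snp in pair:
        if snp not in genotypes.snp_ids:
            raise KeyError(f"unknown SNP id {snp!r}")
    gene_a = genotypes.snp_info.at[snp_a, "gene"]
    gene_b = genotypes.snp_info.at[snp_b, "gene"]
    if gene_a == gene_b:
        raise ValueError(
            f"pair must span two genes; both SNPs are on {gene_a!r}"
        )
    rng = _rng(seed)
    a = genotypes.dosage[snp_a].to_numpy(dtype=float)
    b = genotypes.dosage[snp_b].to_numpy(dtype=float)
    signal = beta_int * (a - a.mean()) * (b - b.mean())
    base = (
        covariate_linear_predictor(covariates, covariate_effects)
        if covariates is not None
        else 0.0
    )
    y = base + signal + rng.normal(0.0, noise_sd, size=len(a))
    return pd.Series(y, index=genotypes.sample_ids, name="y")


def simulate_annotation_and_genesets(
    n_cpgs: int,
    n_genes: int,
    n_categories: int,
    enriched_category_fraction: float,
    seed,
    cpg_ids=None,
) -> tuple[CpGAnnotation, GeneSetDatabase, dict]:
    """CpG->gene annotation plus a gene-set database with one planted signal.

    Each CpG maps to 0, 1 or 2 genes (multi-gene CpGs occur, and genes
    collect multiple CpGs); categories are random gene subsets.  The
    first ~10% of genes form a designated *signal* pool, and one planted
    category draws ``enriched_category_fraction`` of its members from
    that pool, so an over-representation analysis of the signal pool
    should rank it first.  Returns (annotation, database, truth) where
    truth records the signal genes and the enriched category id.
    """
    if n_genes < 1 or n_categories < 1:
        raise ValueError("n_genes and n_categories must be >= 1")
    if not 0 <= enriched_category_fraction <= 1:
        raise ValueError("enriched_category_fraction must lie in [0, 1]")
    rng = _rng(seed)
    genes = np.array([f"GENE{i + 1:04d}" for i in range(n_genes)])
    n_signal = max(1, n_genes // 10)
    signal_genes = genes[:n_signal]
    background = genes[n_signal:] if n_genes > n_signal else genes

    if cpg_ids is None:
        width = len(str(n_cpgs))
        cpg_ids = [f"cg{i + 1:0{width}d}" for i in range(n_cpgs)]
    cpg_ids = pd.Index(cpg_ids, name="cpg_id")
    counts = rng.choice([0, 1, 2], size=len(cpg_ids), p=[0.1, 0.7, 0.2])
    gene_lists = [
        tuple(rng.choice(genes, size=k, replace=False)) if k else ()
        for k in counts
    ]
    annotation = CpGAnnotation(
        pd.DataFrame(
            {
                "chr": rng.integers(1, 23, size=len(cpg_ids)).astype(str),
                "pos": rng.integers(1, 2**27, size=len(cpg_ids)),
                "genes": gene_lists,
            },
            index=cpg_ids,
        )
    )

    categories: dict[str, frozenset] = {}
    for i in range(n_categories - 1):
        size = int(rng.integers(10, max(11, min(60, n_genes))))
        size = min(size, n_genes)
        categories[f"CAT{i + 1:03d}"] = frozenset(
            rng.choice(genes, size=size, replace=False)
        )
    planted_size = min(40, n_genes)
    k_signal = min(int(round(enriched_category_fraction * planted_size)), n_signal)
    planted = list(rng.choice(signal_genes, size=k_signal, replace=False))
    pool = [g for g in background if g not in planted]
    k_bg = min(planted_size - k_signal, len(pool))
    planted += list(rng.choice(np.array(pool), size=k_bg, replace=False))
    categories["CAT_PLANTED"] = frozenset(planted)

    db = GeneSetDatabase("synthetic", categories, frozenset(genes))
    truth = {
        "signal_genes": [str(g) for g in signal_genes],
        "enriched_category": "CAT_PLANTED",
    }
    return annotation, db, truth


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort; every planted signal lands in ``truth``.

    All components share the same sample ids in the same order.  The
    phenotype signal is planted between the first SNP of each gene and is
    carried into the TG panel: the post-treatment log level equals the
    pre-treatment subject level plus the epistatic log-ratio signal, so
    the phenotype module recovers it (up to visit noise).
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(6)

    n = config.n_subjects
    sample_ids = _sample_ids(n)
    genoA = simulate_genotypes(
        config.snp_mafs_geneA, n, np.random.default_rng(seeds[0]),
        gene=config.gene_a, chrom="16", start_pos=53_800_000,
        snp_prefix=f"{config.gene_a.lower()}_", sample_ids=sample_ids,
    )
    genoB = simulate_genotypes(
        config.snp_mafs_geneB, n, np.random.default_rng(seeds[1]),
        gene=config.gene_b, chrom="17", start_pos=18_190_000,
        snp_prefix=f"{config.gene_b.lower()}_", sample_ids=sample_ids,
    )
    genotypes = GenotypeMatrix(
        pd.concat([genoA.dosage, genoB.dosage], axis=1),
        pd.concat([genoA.snp_info, genoB.snp_info]),
    )
    pair = (genoA.snp_ids[0], genoB.snp_ids[0])

    # pre-treatment visits drive the avg_pre_tg covariate, which feeds the
    # phenotype, which in turn shapes the post-treatment visits
    rng_tg = np.random.default_rng(seeds[2])
    base = rng_tg.normal(np.log(110.0), np.sqrt(0.20), size=n)
    l1, l2 = _paired_visits(base, config.tg_visit_corr_pre, rng_tg)
    avg_pre = (np.exp(l1) + np.exp(l2)) / 2.0
    covariates = simulate_covariates(
        n, np.random.default_rng(seeds[3]), avg_pre, sample_ids
    )
    y_signal = simulate_phenotype_epistasis(
        genotypes, covariates, pair,
        config.interaction_beta, config.noise_sd,
        np.random.default_rng(seeds[4]),
    )
    l3, l4 = _paired_visits(
        base + y_signal.to_numpy(), config.tg_visit_corr_post, rng_tg
    )
    frame = pd.DataFrame(
        np.exp(np.column_stack([l1, l2, l3, l4])),
        index=sample_ids, columns=["tg1", "tg2", "tg3", "tg4"],
    )
    rate = config.missing_visit_rate
    if rate > 0:
        for cols in (["tg1", "tg2"], ["tg3", "tg4"]):
            hit = rng_tg.random(n) < 2 * rate
            which = rng_tg.integers(0, 2, size=n)
            for j, col in enumerate(cols):
                frame.loc[hit & (which == j), col] = np.nan
    tg_panel = TriglyceridePanel(frame)

    meth, shifted = simulate_methylation_pair(
        config, np.random.default_rng(seeds[5])
    )
    annotation, genesets, ann_truth = simulate_annotation_and_genesets(
        config.n_cpgs, config.n_genes, config.n_categories,
        config.enriched_category_fraction,
        np.random.default_rng(np.random.SeedSequence(config.seed + 104729)),
        cpg_ids=meth.cpg_ids,
    )

    truth = {
        "shifted_cpgs": shifted,
        "interacting_pair": pair,
        "interaction_beta": config.interaction_beta,
        **ann_truth,
    }
    return SyntheticCohort(
        tg_panel=tg_panel,
        meth=meth,
        genotypes=genotypes,
        covariates=covariates,
        annotation=annotation,
        genesets=genesets,
        truth=truth,
        config=config,
    )
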