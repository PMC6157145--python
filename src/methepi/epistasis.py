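"""Targeted cross-gene SNP x SNP epistasis scan via likelihood-ratio tests.

For every pair of SNPs with one member in each of two candidate genes
(here the two RNA m6A demethylases, FTO and ALKBH5), two nested Gaussian
linear models are compared:

    base:  y ~ 1 + covariates + gA + gB
    full:  y ~ 1 + covariates + gA + gB + gA*gB

with additive (0/1/2 minor-allele dosage) coding and a single product
interaction term.  The likelihood-ratio statistic for Gaussian OLS
nesting is lambda = n * ln(RSS_base / RSS_full), referred to a chi-square
with 1 df.  Within-gene pairs are never tested; the Bonferroni family is
the cross-gene pair count m = |A| x |B|.

The scan shares one covariate QR decomposition across all pairs
(Frisch–Waugh–Lovell residualisation), which leaves every RSS — and hence
every statistic — identical to the naive per-pair fit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import CovariateTable, DataError, GenotypeMatrix
from .diffmeth import bonferroni_threshold

__all__ = [
    "completeness_filter",
    "cross_gene_pairs",
    "fit_interaction_lrt",
    "epistasis_scan",
    "genotype_stratified_summaries",
    "CrossGeneEpistasisScan",
    "EpistasisScanResults",
]

logger = logging.getLogger(__name__)

#: numerical floor below which a residualised column is treated as collinear
_RANK_TOL = 1e-9


def completeness_filter(geno: GenotypeMatrix, samples) -> GenotypeMatrix:
    """Restrict to the given samples, keeping complete polymorphic SNPs.

    SNPs with any missing dosage among the samples are dropped, as are
    monomorphic SNPs (logged); the scan then needs no per-pair missing
    handling.
    """
    samples = pd.Index(samples)
    if len(samples) == 0:
        raise ValueError("sample list must be non-empty")
    if not samples.isin(geno.sample_ids).all():
        missing = samples[~samples.isin(geno.sample_ids)].tolist()
        raise DataError(f"samples absent from genotype matrix: {missing[:5]}")
    dosage = geno.dosage.loc[samples]
    complete = dosage.notna().all(axis=0)
    polymorphic = dosage.nunique(dropna=True) > 1
    dropped_mono = dosage.columns[complete & ~polymorphic].tolist()
    if dropped_mono:
        logger.info("completeness_filter: dropped monomorphic SNPs %s", dropped_mono)
    keep = dosage.columns[complete & polymorphic]
    return GenotypeMatrix(dosage[keep], geno.snp_info.loc[keep])


def cross_gene_pairs(geneA_snps, geneB_snps) -> list[tuple[str, str]]:
    """Cartesian product of the two SNP lists, (A-index, then B-index) order.

    Within-gene pairs are never formed; the lists must be disjoint.
    """
    a, b = list(geneA_snps), list(geneB_snps)
    overlap = set(a) & set(b)
    if overlap:
        raise ValueError(f"SNP lists overlap: {sorted(overlap)[:5]}")
    return list(itertools.product(a, b))


def _design(covariates: CovariateTable | None, index: pd.Index) -> np.ndarray:
    n = len(index)
    if covariates is None:
        return np.ones((n, 1))
    if not covariates.sample_ids.equals(index):
        raise DataError("covariates are not sample-aligned with the phenotype")
    x = covariates.design_matrix().to_numpy(dtype=float)
    return np.column_stack([np.ones(n), x])


def fit_interaction_lrt(
    y: pd.Series,
    gA: pd.Series,
    gB: pd.Series,
    covariates: CovariateTable | None = None,
) -> dict:
    """LRT of the 1-df product interaction for a single cross-gene pair.

    Returns a record with keys snp_a, snp_b, lrt_stat, df, p, beta_int,
    n_used, status.  Monomorphic input SNPs yield a skipped-pair record
    (status "skipped_monomorphic"); a rank-deficient full design (the
    interaction column collinear with the base model) yields a degenerate
    record with p = 1.
    """
    if not (gA.index.equals(y.index) and gB.index.equals(y.index)):
        raise DataError("phenotype and dosages are not sample-aligned")
    rec = {
        "snp_a": gA.name, "snp_b": gB.name,
        "lrt_stat": np.nan, "df": 1, "p": np.nan, "beta_int": np.nan,
        "n_used": len(y), "status": "ok",
    }
    a = gA.to_numpy(dtype=float)
    b = gB.to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        rec["status"] = "skipped_monomorphic"
        return rec
    n = len(y)
    base = np.column_stack([_design(covariates, y.index), a, b])
    k_base = base.shape[1]
    if n < k_base + 2:
        raise DataError(f"n = {n} too small for {k_base}-parameter base model")
    full = np.column_stack([base, a * b])
    yv = y.to_numpy(dtype=float)
    coef_b, rss_b = _ols_rss(base, yv)
    coef_f, rss_f = _ols_rss(full, yv)
    if np.linalg.matrix_rank(full) < full.shape[1]:
        rec.update(lrt_stat=0.0, p=1.0, beta_int=0.0, status="degenerate")
        return rec
    rss_f = min(rss_f, rss_b)  # guard tiny negative improvements from roundoff
    lrt = n * np.log(rss_b / rss_f) if rss_f > 0 else np.inf
    rec.update(
        lrt_stat=float(lrt),
        p=float(stats.chi2.sf(lrt, df=1)),
        beta_int=float(coef_f[-1]),
    )
    return rec


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return coef, float(res[0])
    fitted = X @ coef
    return coef, float(((y - fitted) ** 2).sum())


def epistasis_scan(
    y: pd.Series,
    genoA: GenotypeMatrix,
    genoB: GenotypeMatrix,
    covariates: CovariateTable | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """LRT over every cross-gene pair, Bonferroni-flagged at alpha/m.

    Inputs should already have passed :func:`completeness_filter`.
    Returns one record per pair sorted by p ascending (ties by
    (snp_a, snp_b)); ``attrs`` carries m, the threshold and alpha.

    All pairs share a single covariate residualisation: with Q an
    orthonormal basis of [1 | covariates], each pair's base RSS is the RSS
    of (I-QQ')y on the residualised dosage columns and the full model adds
    the residualised product column, which reproduces the naive nested-OLS
    RSS values exactly.
    """
    pairs = cross_gene_pairs(genoA.snp_ids, genoB.snp_ids)
    m = len(pairs)
    threshold = bonferroni_threshold(alpha, m) if m else np.nan
    if not (genoA.sample_ids.equals(y.index) and genoB.sample_ids.equals(y.index)):
        raise DataError("genotypes are not sample-aligned with the phenotype")

    n = len(y)
    Xc = _design(covariates, y.index)
    q, _ = np.linalg.qr(Xc)
    k_cov = Xc.shape[1]

    def resid(mat: np.ndarray) -> np.ndarray:
        return mat - q @ (q.T @ mat)

    yv = y.to_numpy(dtype=float)
    ry = resid(yv[:, None])[:, 0]
    A = genoA.dosage.to_numpy(dtype=float)
    B = genoB.dosage.to_numpy(dtype=float)
    rA, rB = resid(A), resid(B)

    records = []
    for ia, ib in itertools.product(range(A.shape[1]), range(B.shape[1])):
        snp_a = genoA.snp_ids[ia]
        snp_b = genoB.snp_ids[ib]
        rec = {
            "snp_a": snp_a, "snp_b": snp_b, "lrt_stat": np.nan, "df": 1,
            "p": np.nan, "beta_int": np.nan, "n_used": n, "status": "ok",
        }
        if np.ptp(A[:, ia]) == 0 or np.ptp(B[:, ib]) == 0:
            rec["status"] = "skipped_monomorphic"
            records.append(rec)
            continue
        Zb = np.column_stack([rA[:, ia], rB[:, ib]])
        inter = resid((A[:, ia] * B[:, ib])[:, None])[:, 0]
        Zf = np.column_stack([Zb, inter])
        _, rss_b = _ols_rss(Zb, ry)
        coef_f, rss_f = _ols_rss(Zf, ry)
        # interaction column collinear with base => no testable 1-df term
        proj = Zb @ np.linalg.lstsq(Zb, inter, rcond=None)[0]
        if np.linalg.norm(inter - proj) <= _RANK_TOL * max(np.linalg.norm(inter), 1.0):
            rec.update(lrt_stat=0.0, p=1.0, beta_int=0.0, status="degenerate")
            records.append(rec)
            continue
        rss_f = min(rss_f, rss_b)
        lrt = n * np.log(rss_b / rss_f) if rss_f > 0 else np.inf
        rec.update(
            lrt_stat=float(lrt),
            p=float(stats.chi2.sf(lrt, df=1)),
            beta_int=float(coef_f[-1]),
        )
        records.append(rec)

    table = pd.DataFrame.from_records(records)
    table["significant"] = (table["status"] == "ok") & (table["p"] <= threshold)
    table = table.sort_values(
        ["p", "snp_a", "snp_b"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    table.attrs.update(
        {"m": m, "alpha": alpha, "threshold": threshold, "k_covariates": k_cov}
    )
    return table


def genotype_stratified_summaries(
    y: pd.Series, gA: pd.Series, gB: pd.Series
) -> pd.DataFrame:
    """Phenotype summaries within genotype strata of a SNP pair.

    Emits marginal strata (0/1/2 copies of the minor allele for each SNP)
    and the nine joint strata; the joint table, read along either margin,
    gives the distributions conditioned each way.  Strata with no subjects
    appear with count 0 and NaN summaries.
    """
    if not (gA.index.equals(y.index) and gB.index.equals(y.index)):
        raise DataError("phenotype and dosages are not sample-aligned")
    yv = y.to_numpy(dtype=float)
    a = gA.to_numpy(dtype=float).astype(int)
    b = gB.to_numpy(dtype=float).astype(int)
    rows = []

    def describe(mask: np.ndarray) -> dict:
        sub = yv[mask]
        if sub.size == 0:
            return {"count": 0, "mean": np.nan, "median": np.nan,
                    "q1": np.nan, "q3": np.nan}
        return {
            "count": int(sub.size),
            "mean": float(sub.mean()),
            "median": float(np.median(sub)),
            "q1": float(np.percentile(sub, 25)),
            "q3": float(np.percentile(sub, 75)),
        }

    for da in (0, 1, 2):
        rows.append({"stratum": "marginal_a", "gA": da, "gB": np.nan,
                     **describe(a == da)})
    for db in (0, 1, 2):
        rows.append({"stratum": "marginal_b", "gA": np.nan, "gB": db,
                     **describe(b == db)})
    for da in (0, 1, 2):
        for db in (0, 1, 2):
            rows.append({"stratum": "joint", "gA": da, "gB": db,
                         **describe((a == da) & (b == db))})
    out = pd.DataFrame(rows)
    out.attrs["snp_a"] = gA.name
    out.attrs["snp_b"] = gB.name
    return out


class CrossGeneEpistasisScan:
    """Model: targeted SNP x SNP interaction scan between two genes.

    Parameters
    ----------
    y : Series
        Drug-response phenotype (log TG ratio), indexed by sample id.
    genotypes : GenotypeMatrix
        Dosages for both genes; gene membership is read from
        ``snp_info["gene"]``.
    covariates : CovariateTable or None
        Base-model covariates (average pre-treatment TG, age, center,
        smoking, sex by default); None fits intercept-only bases.
    gene_a, gene_b : str
        The two gene labels to scan between.
    """

    def __init__(
        self,
        y: pd.Series,
        genotypes: GenotypeMatrix,
        covariates: CovariateTable | None,
        gene_a: str,
        gene_b: str,
    ):
        geno = completeness_filter(genotypes, y.index)
        self.y = y
        self.genoA = geno.by_gene(gene_a)
        self.genoB = geno.by_gene(gene_b)
        if self.genoA.dosage.shape[1] == 0 or self.genoB.dosage.shape[1] == 0:
            raise DataError(
                f"no complete polymorphic SNPs for one of {gene_a!r}, {gene_b!r}"
            )
        self.covariates = covariates
        self.gene_a, self.gene_b = gene_a, gene_b

    def fit(self, alpha: float = 0.05) -> "EpistasisScanResults":
        table = epistasis_scan(
            self.y, self.genoA, self.genoB, self.covariates, alpha=alpha
        )
        return EpistasisScanResults(
            table=table,
            gene_a=self.gene_a,
            gene_b=self.gene_b,
            snp_info=pd.concat([self.genoA.snp_info, self.genoB.snp_info]),
            model=self,
        )


@dataclass
class EpistasisScanResults:
    """Ranked cross-gene LRT results with Bonferroni flags."""

    table: pd.DataFrame
    gene_a: str
    gene_b: str
    snp_info: pd.DataFrame
    model: CrossGeneEpistasisScan = field(repr=False, default=None)

    @property
    def m(self) -> int:
        return self.table.attrs["m"]

    @property
    def threshold(self) -> float:
        return self.table.attrs["threshold"]

    @property
    def significant_pairs(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def annotated_table(self) -> pd.DataFrame:
        """Result table joined with SNP metadata (alleles, MAF, location, gene)."""
        out = self.table.copy()
        for side in ("a", "b"):
            info = self.snp_info.reindex(out[f"snp_{side}"]).reset_index(drop=True)
            out[f"alleles_{side}"] = info["alleles"].to_numpy()
            out[f"maf_{side}"] = info["maf"].to_numpy()
            out[f"location_{side}"] = (
                info["chr"].astype(str) + ":" + info["pos"].astype(int).astype(str)
            ).to_numpy()
        return out

    def stratified_summaries(self, snp_a: str, snp_b: str) -> pd.DataFrame:
        mdl = self.model
        return genotype_stratified_summaries(
            mdl.y, mdl.genoA.dosage[snp_a], mdl.genoB.dosage[snp_b]
        )

    def plot_stratified(self, snp_a: str, snp_b: str, path) -> None:
        """Boxplots of the phenotype by genotype: marginals plus conditionals."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        mdl = self.model
        yv = mdl.y.to_numpy(dtype=float)
        a = mdl.genoA.dosage[snp_a].to_numpy(dtype=float).astype(int)
        b = mdl.genoB.dosage[snp_b].to_numpy(dtype=float).astype(int)
        fig, axes = plt.subplots(2, 2, figsize=(10, 7))
        for ax, g, name in ((axes[0, 0], a, snp_a), (axes[1, 0], b, snp_b)):
            ax.boxplot([yv[g == d] for d in (0, 1, 2)], tick_labels=["0", "1", "2"])
            ax.set_title(f"phenotype by {name} dosage")
        for ax, gout, gin, nin in (
            (axes[0, 1], a, b, snp_b),
            (axes[1, 1], b, a, snp_a),
        ):
            data, labels = [], []
            for dout in (0, 1, 2):
                for din in (0, 1, 2):
                    data.append(yv[(gout == dout) & (gin == din)])
                    labels.append(f"{dout}|{din}")
            ax.boxplot(data, tick_labels=labels)
            ax.tick_params(axis="x", labelsize=7)
            ax.set_title(f"conditioned on {nin} dosage")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    def summary(self, top: int = 5) -> str:
        lines = [
            f"Cross-gene epistasis scan: {self.gene_a} x {self.gene_b}",
            f"  SNPs: {self.model.genoA.dosage.shape[1]} x "
            f"{self.model.genoB.dosage.shape[1]} = {self.m} pairs tested",
            f"  Bonferroni threshold (alpha={self.table.attrs['alpha']:g}): "
            f"{self.threshold:.6e}",
            f"  significant pairs: {len(self.significant_pairs)}",
        ]
        for _, row in self.table.head(top).iterrows():
            lines.append(
                f"  {row.snp_a} x {row.snp_b}: LRT={row.lrt_stat:.3f} "
                f"p={row.p:.3e} beta_int={row.beta_int:.4f} [{row.status}]"
            )
        return "\n".join(lines)
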