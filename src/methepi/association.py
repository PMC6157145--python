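"""Per-CpG association between the drug-response phenotype and methylation.

For each differentially methylated site the single-predictor linear model

    y ~ intercept + log(beta_post / beta_pre)

is fit by ordinary least squares, and the slope's two-sided t-test
(n - 2 df) provides the association p-value.  Results carry genomic
coordinates so they can be rendered directly as a Manhattan plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataError, MethylationPair
from .diffmeth import bonferroni_threshold

__all__ = [
    "methylation_log_ratio_predictor",
    "fit_site_models",
    "CpGAssociation",
    "CpGAssociationResults",
    "manhattan_table",
]


def methylation_log_ratio_predictor(meth: MethylationPair) -> np.ndarray:
    """Per-sample, per-site ln(beta_post / beta_pre); finite by clamping."""
    return np.log(meth.beta_post) - np.log(meth.beta_pre)


def fit_site_models(
    y: pd.Series, predictors: np.ndarray, site_ids, sample_ids=None
) -> pd.DataFrame:
    """Simple OLS of the phenotype on each site's methylation log ratio.

    ``predictors`` is samples x sites, row-aligned with ``y`` (if
    ``sample_ids`` is given it must equal y's index, in order).  Returns a
    DataFrame indexed by site id with columns slope, se, t_stat, df, p,
    degenerate.  Constant-predictor sites are flagged degenerate with
    slope 0 and p = 1.
    """
    predictors = np.asarray(predictors, dtype=float)
    n = predictors.shape[0]
    if n < 3:
        raise DataError(f"site models need >= 3 samples; got {n}")
    if len(y) != n:
        raise DataError("phenotype and predictor matrix have different sample counts")
    if sample_ids is not None and not pd.Index(sample_ids).equals(y.index):
        raise DataError("phenotype and predictors are not sample-aligned")

    yv = y.to_numpy(dtype=float)
    yc = yv - yv.mean()
    xc = predictors - predictors.mean(axis=0, keepdims=True)
    sxx = (xc**2).sum(axis=0)
    sxy = xc.T @ yc
    degenerate = sxx <= 0.0
    sxx_safe = np.where(degenerate, 1.0, sxx)
    slope = np.where(degenerate, 0.0, sxy / sxx_safe)
    # residual sum of squares of y on (1, x): syy - slope^2 * sxx
    syy = float((yc**2).sum())
    rss = np.maximum(syy - slope**2 * sxx, 0.0)
    df = n - 2
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / sxx_safe)
        t = np.where(se > 0, slope / np.where(se > 0, se, 1.0), np.inf * np.sign(slope))
    t = np.where(degenerate, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    p = np.where(degenerate, 1.0, p)
    p = np.where(np.isnan(p), np.finfo(float).tiny, p)  # perfect fits: machine floor
    return pd.DataFrame(
        {
            "slope": slope,
            "se": np.where(degenerate, np.nan, se),
            "t_stat": t,
            "df": np.full(len(sxx), df, dtype=int),
            "p": p,
            "degenerate": degenerate,
        },
        index=pd.Index(site_ids),
    )


def manhattan_table(results: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Plot-ready association table sorted by (chr, pos).

    Adds a -log10(p) column and the -log10 threshold line value; the
    number of sites exceeding the threshold is stored in
    ``table.attrs["n_above_threshold"]``.
    """
    if not {"chr", "pos", "p"} <= set(results.columns):
        raise DataError("manhattan table needs chr, pos and p columns")
    table = results.sort_values(["chr", "pos"], kind="mergesort").copy()
    with np.errstate(divide="ignore"):
        table["neg_log10_p"] = -np.log10(table["p"])
    table["threshold_line"] = -np.log10(threshold)
    table.attrs["n_above_threshold"] = int((table["p"] <= threshold).sum())
    return table


class CpGAssociation:
    """Model: phenotype ~ methylation log ratio, one simple OLS per site.

    Sites should be restricted to the differential-methylation pass list
    before fitting (two-stage filter); pass the filtered
    :class:`~methepi.data.MethylationPair` or use ``site_ids``.

    A covariate-adjusted variant is available by passing a numeric
    covariate design via ``covariates`` (off by default; the headline
    analysis uses a single predictor).
    """

    def __init__(
        self,
        y: pd.Series,
        meth: MethylationPair,
        annotation: pd.DataFrame | None = None,
        covariates: pd.DataFrame | None = None,
    ):
        if not pd.Index(meth.sample_ids).equals(y.index):
            raise DataError("phenotype and methylation samples are misaligned")
        self.y = y
        self.meth = meth
        self.annotation = annotation
        self.covariates = covariates

    def fit(self, alpha: float = 0.05) -> "CpGAssociationResults":
        r = methylation_log_ratio_predictor(self.meth)
        if self.covariates is not None:
            q, _ = np.linalg.qr(
                np.column_stack(
                    [np.ones(len(self.y)), self.covariates.to_numpy(dtype=float)]
                )
            )
            resid = lambda m: m - q @ (q.T @ m)  # noqa: E731
            ry = pd.Series(resid(self.y.to_numpy(dtype=float)), index=self.y.index)
            table = fit_site_models(ry, resid(r), self.meth.cpg_ids)
        else:
            table = fit_site_models(self.y, r, self.meth.cpg_ids, self.meth.sample_ids)
        if self.annotation is not None:
            ann = self.annotation.reindex(table.index)
            table["chr"] = ann["chr"]
            table["pos"] = ann["pos"]
        threshold = bonferroni_threshold(alpha, len(table))
        return CpGAssociationResults(table, alpha=alpha, threshold=threshold)


@dataclass
class CpGAssociationResults:
    """Per-site slopes, standard errors and p-values for y ~ log ratio."""

    table: pd.DataFrame
    alpha: float
    threshold: float

    @property
    def n_tested(self) -> int:
        return len(self.table)

    @property
    def n_genomewide_significant(self) -> int:
        return int((self.table["p"] <= self.threshold).sum())

    def manhattan_table(self) -> pd.DataFrame:
        return manhattan_table(self.table, self.threshold)

    def plot_manhattan(self, path) -> None:
        """Render a basic Manhattan plot (points by position, threshold line)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        table = self.manhattan_table()
        fig, ax = plt.subplots(figsize=(9, 3.2))
        offset = 0.0
        ticks, labels = [], []
        for chrom, grp in table.groupby("chr", sort=True):
            x = offset + np.arange(len(grp))
            ax.scatter(x, grp["neg_log10_p"], s=4)
            ticks.append(offset + len(grp) / 2)
            labels.append(str(chrom))
            offset += len(grp)
        ax.axhline(-np.log10(self.threshold), color="red", lw=0.8, ls="--")
        ax.set_xticks(ticks, labels)
        ax.set_xlabel("chromosome")
        ax.set_ylabel(r"$-\log_{10} p$")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    def summary(self) -> str:
        return "\n".join(
            [
                "Phenotype ~ methylation log-ratio association",
                f"  sites tested:             {self.n_tested}",
                f"  Bonferroni threshold:     {self.threshold:.6e}",
                f"  genome-wide significant:  {self.n_genomewide_significant}",
            ]
        )
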