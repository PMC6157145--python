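"""Genome-scale differential methylation by paired t-tests.

Per CpG site, the per-subject difference d = beta_post - beta_pre is
tested with a one-sample t-test (t = mean(d) / (sd(d)/sqrt(n)), n-1 df,
two-sided), and sites are filtered at a Bonferroni threshold alpha/m over
the m tested sites.  The test operates on raw beta differences by
default; an M-value (logit-scale) variant is available via ``logit=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, special

from .data import DataError, MethylationPair

__all__ = [
    "bonferroni_threshold",
    "paired_ttest_all_sites",
    "filter_significant_sites",
    "PairedDifferentialMethylation",
    "DiffMethResults",
]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha/m controlling family-wise error over m tests.

    Returned at full floating-point precision; rounding for display (e.g.
    to 3 significant figures) is a presentation concern.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1); got {alpha}")
    m = int(m)
    if m < 1:
        raise ValueError(f"hypothesis count m must be >= 1; got {m}")
    return alpha / m


def paired_ttest_all_sites(meth: MethylationPair, logit: bool = False) -> pd.DataFrame:
    """Vectorised paired t-tests of post vs pre methylation at every site.

    Returns a DataFrame indexed by cpg_id with columns t_stat, df, p,
    degenerate.  Zero-variance sites (all subjects share one difference
    value) carry no usable evidence and are flagged degenerate with p = 1.
    """
    n = meth.n_samples
    if n < 2:
        raise DataError(f"paired t-test needs >= 2 samples; got {n}")
    if logit:
        d = special.logit(meth.beta_post) - special.logit(meth.beta_pre)
    else:
        d = meth.beta_post - meth.beta_pre
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(degenerate, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {
            "t_stat": t,
            "df": np.full(meth.n_cpgs, n - 1, dtype=int),
            "p": p,
            "degenerate": degenerate,
        },
        index=meth.cpg_ids,
    )


def filter_significant_sites(results: pd.DataFrame, threshold: float) -> list[str]:
    """CpG ids with p <= threshold among non-degenerate sites, input order kept."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must lie in [0, 1]; got {threshold}")
    passes = (~results["degenerate"]) & (results["p"] <= threshold)
    if threshold == 0:  # nothing can pass an impossible filter
        passes &= False
    return results.index[passes].tolist()


class PairedDifferentialMethylation:
    """Model: paired pre/post differential methylation over all CpG sites.

    Parameters
    ----------
    meth : MethylationPair
        Aligned pre- and post-treatment beta matrices.
    logit : bool
        Test logit-transformed betas (M-values) instead of raw betas.
    """

    def __init__(self, meth: MethylationPair, logit: bool = False):
        self.meth = meth
        self.logit = logit

    def fit(self, alpha: float = 0.05) -> "DiffMethResults":
        table = paired_ttest_all_sites(self.meth, logit=self.logit)
        threshold = bonferroni_threshold(alpha, len(table))
        table = table.copy()
        table["passes"] = (~table["degenerate"]) & (table["p"] <= threshold)
        return DiffMethResults(table, alpha=alpha, threshold=threshold)


@dataclass
class DiffMethResults:
    """Per-site paired-t results with the Bonferroni filter applied."""

    table: pd.DataFrame
    alpha: float
    threshold: float

    @property
    def n_tested(self) -> int:
        return len(self.table)

    @property
    def significant_sites(self) -> list[str]:
        return self.table.index[self.table["passes"]].tolist()

    @property
    def n_significant(self) -> int:
        return int(self.table["passes"].sum())

    def summary(self) -> str:
        lines = [
            "Paired differential methylation (pre vs post treatment)",
            f"  CpG sites tested:      {self.n_tested}",
            f"  alpha (family-wise):   {self.alpha:g}",
            f"  Bonferroni threshold:  {self.threshold:.6e}",
            f"  sites passing:         {self.n_significant}",
            f"  degenerate sites:      {int(self.table['degenerate'].sum())}",
        ]
        return "\n".join(lines)
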