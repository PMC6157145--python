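"""Gene-list curation and hypergeometric over-representation analysis (ORA).

The signal gene list is the union of gene symbols annotated to CpG sites
that survive the differential-methylation filter and show nominal
association (p <= p_cut) with the phenotype.  Each gene-set category is
then tested one-sided for over-representation: with a reference universe
of N genes of which K belong to the category, and a signal list of n
genes of which O fall in the category, the raw p-value is the upper tail
P(X >= O) of the hypergeometric distribution; E = n*K/N is the expected
overlap and R = O/E the enrichment ratio.  Depletion is not tested.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import CpGAnnotation, GeneSetDatabase

__all__ = [
    "curate_gene_list",
    "hypergeometric_ora",
    "enrichment_ratio",
    "adjust_pvalues",
    "OverRepresentation",
    "EnrichmentResults",
]


def enrichment_ratio(observed: float, expected: float) -> float:
    """R = O/E, the observed/expected overlap ratio (0 when E = 0)."""
    if expected < 0 or observed < 0:
        raise ValueError("counts must be non-negative")
    return observed / expected if expected > 0 else 0.0

logger = logging.getLogger(__name__)


def curate_gene_list(
    assoc: pd.DataFrame, annotation: CpGAnnotation, p_cut: float = 0.05
) -> frozenset[str]:
    """Union of gene symbols over annotated sites with association p <= p_cut.

    ``assoc`` is the per-site association table (indexed by cpg_id, with a
    ``p`` column), already restricted to differentially methylated sites.
    Sites absent from the annotation are skipped and counted in a log
    message, not an error.  Raising ``p_cut`` can only grow the result.
    """
    if not 0 <= p_cut <= 1:
        raise ValueError(f"p_cut must lie in [0, 1]; got {p_cut}")
    hits = assoc.index[assoc["p"] <= p_cut]
    known = annotation.frame.index
    missing = hits.difference(known)
    if len(missing):
        logger.info(
            "curate_gene_list: %d of %d significant sites lack annotation; skipped",
            len(missing), len(hits),
        )
    genes: set[str] = set()
    for cpg in hits.intersection(known):
        genes.update(annotation.genes_for(cpg))
    return frozenset(genes)


def hypergeometric_ora(gene_set, db: GeneSetDatabase) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per category.

    The gene set is intersected with the database reference before
    testing.  Returns a DataFrame indexed by category_id with columns
    C (reference genes in category), O (observed overlap), E (expected),
    R (= O/E, 0 when E = 0) and raw_p, sorted by raw_p ascending with
    ties broken by category id.  An empty intersection yields an empty
    frame with a warning.
    """
    universe = db.reference
    drawn = frozenset(gene_set) & universe
    n, N = len(drawn), len(universe)
    if n == 0:
        logger.warning("hypergeometric_ora: gene set does not intersect the reference")
        return pd.DataFrame(columns=["C", "O", "E", "R", "raw_p"])
    rows = []
    for cat_id in sorted(db.categories):
        members = db.categories[cat_id]
        K = len(members)
        O = len(drawn & members)
        E = n * K / N
        R = O / E if E > 0 else 0.0
        raw_p = float(stats.hypergeom.sf(O - 1, N, K, n))
        rows.append((cat_id, K, O, E, R, min(raw_p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["category_id", "C", "O", "E", "R", "raw_p"]
    ).set_index("category_id")
    table = table.sort_values("raw_p", kind="mergesort")  # stable: id breaks ties
    table.attrs["n_drawn"] = n
    table.attrs["n_reference"] = N
    return table


def adjust_pvalues(raw, method: str = "BH") -> np.ndarray:
    """Multiple-test adjustment; order of output matches order of input.

    ``method``: "BH" (Benjamini–Hochberg step-up, monotone, capped at 1)
    or "bonferroni" (min(1, m*p)).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        return raw
    if np.any((raw < 0) | (raw > 1)) or not np.isfinite(raw).all():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "fdr_bh": "fdr_bh", "bonferroni": "bonferroni"}.get(
        method.lower()
    )
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(raw, method=key)[1]


class OverRepresentation:
    """Model: over-representation of a gene list in a gene-set database.

    The database reference universe is intersected with ``universe`` (the
    annotation's gene universe) when given, the standard construction for
    user-supplied GMT files.
    """

    def __init__(self, gene_set, db: GeneSetDatabase, universe=None):
        self.gene_set = frozenset(gene_set)
        self.db = db.restricted_to(universe) if universe is not None else db
        self.db = GeneSetDatabase(  # drop categories emptied by restriction
            self.db.db_name,
            {k: v for k, v in self.db.categories.items() if v},
            self.db.reference,
        )

    def fit(self, method: str = "BH") -> "EnrichmentResults":
        table = hypergeometric_ora(self.gene_set, self.db)
        if len(table):
            table = table.copy()
            table["adj_p"] = adjust_pvalues(table["raw_p"].to_numpy(), method)
        else:
            table["adj_p"] = []
        return EnrichmentResults(table, self.db.db_name, method)


class EnrichmentResults:
    """Ranked per-category enrichment statistics."""

    def __init__(self, table: pd.DataFrame, db_name: str, method: str):
        self.table = table
        self.db_name = db_name
        self.method = method

    @property
    def top_category(self) -> str | None:
        return None if self.table.empty else self.table.index[0]

    def summary(self, top: int = 5) -> str:
        head = [
            f"Over-representation analysis against {self.db_name!r} "
            f"({len(self.table)} categories, {self.method} adjustment)",
            f"  genes drawn from reference: {self.table.attrs.get('n_drawn', 'NA')}"
            f" / universe {self.table.attrs.get('n_reference', 'NA')}",
        ]
        shown = self.table.head(top)
        for cat, row in shown.iterrows():
            head.append(
                f"  {cat}: C={int(row.C)} O={int(row.O)} E={row.E:.2f} "
                f"R={row.R:.2f} raw_p={row.raw_p:.3e} adj_p={row.adj_p:.3e}"
            )
        return "\n".join(head)
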