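"""Core data containers for the methylation-informed epistasis pipeline.

Each container wraps a pandas/numpy structure, validates its invariants at
construction, and knows nothing about how it was produced (simulation or
file import) — the analysis models in :mod:`methepi.diffmeth`,
:mod:`methepi.association`, :mod:`methepi.enrichment` and
:mod:`methepi.epistasis` consume these types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: clamp bound for methylation beta values, keeps logits finite
BETA_EPS = 1e-6

TG_COLUMNS = ["tg1", "tg2", "tg3", "tg4"]
PRE_VISITS = ["tg1", "tg2"]
POST_VISITS = ["tg3", "tg4"]

COVARIATE_COLUMNS = ["avg_pre_tg", "age", "center", "current_smoker", "sex"]


class DataError(ValueError):
    """Raised when a container's invariants are violated."""


@dataclass
class TriglyceridePanel:
    """Per-subject triglyceride levels (mg/dL) at four visits.

    Visits 1–2 are pre-treatment, 3–4 post-treatment.  Missing values are
    NaN; every subject must have at least one observed visit in each block,
    and all observed values must be positive.
    """

    frame: pd.DataFrame  # index sample_id, columns tg1..tg4

    def __post_init__(self) -> None:
        missing_cols = [c for c in TG_COLUMNS if c not in self.frame.columns]
        if missing_cols:
            raise DataError(f"triglyceride panel missing columns {missing_cols}")
        self.frame = self.frame[TG_COLUMNS].astype(float)
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].tolist()
            raise DataError(f"duplicate sample ids: {dupes[:5]}")
        obs = self.frame.to_numpy()
        if np.any(obs[np.isfinite(obs)] <= 0):
            raise DataError("observed triglyceride values must be positive")
        pre_ok = self.frame[PRE_VISITS].notna().any(axis=1)
        post_ok = self.frame[POST_VISITS].notna().any(axis=1)
        bad = self.frame.index[~(pre_ok & post_ok)]
        if len(bad):
            raise DataError(
                "subjects lacking any observed pre- or post-treatment visit: "
                f"{bad.tolist()[:5]}"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    def is_complete(self) -> bool:
        return bool(self.frame.notna().all().all())


@dataclass
class MethylationPair:
    """Paired pre/post methylation beta matrices (samples x CpG sites).

    Betas are proportions; values are clamped into [BETA_EPS, 1 - BETA_EPS]
    so logits and log ratios stay finite.
    """

    sample_ids: pd.Index
    cpg_ids: pd.Index
    beta_pre: np.ndarray
    beta_post: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = pd.Index(self.sample_ids)
        self.cpg_ids = pd.Index(self.cpg_ids)
        self.beta_pre = np.asarray(self.beta_pre, dtype=float)
        self.beta_post = np.asarray(self.beta_post, dtype=float)
        shape = (len(self.sample_ids), len(self.cpg_ids))
        if self.beta_pre.shape != shape or self.beta_post.shape != shape:
            raise DataError(
                f"beta matrices must both have shape {shape}; got "
                f"{self.beta_pre.shape} and {self.beta_post.shape}"
            )
        if not (np.isfinite(self.beta_pre).all() and np.isfinite(self.beta_post).all()):
            raise DataError("methylation betas must be finite (no missing values)")
        self.beta_pre = np.clip(self.beta_pre, BETA_EPS, 1 - BETA_EPS)
        self.beta_post = np.clip(self.beta_post, BETA_EPS, 1 - BETA_EPS)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    def subset_sites(self, cpg_ids) -> "MethylationPair":
        idx = self.cpg_ids.get_indexer(pd.Index(cpg_ids))
        if (idx < 0).any():
            missing = pd.Index(cpg_ids)[idx < 0].tolist()
            raise DataError(f"unknown CpG ids: {missing[:5]}")
        return MethylationPair(
            self.sample_ids, pd.Index(cpg_ids),
            self.beta_pre[:, idx], self.beta_post[:, idx],
        )


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix plus per-SNP metadata.

    ``dosage`` is samples x SNPs with values in {0, 1, 2} or NaN (missing).
    ``snp_info`` is indexed by snp_id with columns chr, pos (1-based),
    gene, alleles, maf.
    """

    dosage: pd.DataFrame
    snp_info: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosage.columns.equals(pd.Index(self.snp_info.index)):
            raise DataError("dosage columns must match snp_info index (same order)")
        vals = self.dosage.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if not np.isin(finite, [0.0, 1.0, 2.0]).all():
            raise DataError("dosages must be 0, 1, 2 or missing")
        maf = self.snp_info["maf"].to_numpy(dtype=float)
        if np.any((maf <= 0) | (maf > 0.5)):
            raise DataError("MAF must lie in (0, 0.5]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosage.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosage.columns

    def by_gene(self, gene: str) -> "GenotypeMatrix":
        keep = self.snp_info.index[self.snp_info["gene"] == gene]
        return GenotypeMatrix(self.dosage[keep], self.snp_info.loc[keep])


@dataclass
class CovariateTable:
    """Subject-level covariates for the epistasis base model.

    Columns: avg_pre_tg (mg/dL), age (years), center (categorical),
    current_smoker (0/1), sex (0/1).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COVARIATE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DataError(f"covariate table missing columns {missing}")
        self.frame = self.frame[COVARIATE_COLUMNS].copy()
        for c in ("avg_pre_tg", "age", "current_smoker", "sex"):
            self.frame[c] = self.frame[c].astype(float)
        self.frame["center"] = self.frame["center"].astype(str)
        if self.frame[COVARIATE_COLUMNS].isna().any().any():
            raise DataError("covariate table contains missing values")

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    def design_matrix(self, columns=None) -> pd.DataFrame:
        """Numeric design (no intercept): categorical center as indicator contrasts."""
        cols = list(columns) if columns is not None else COVARIATE_COLUMNS
        parts = []
        for c in cols:
            if c == "center":
                dummies = pd.get_dummies(
                    self.frame["center"].astype(str), prefix="center", drop_first=True
                ).astype(float)
                parts.append(dummies)
            else:
                parts.append(self.frame[[c]].astype(float))
        return pd.concat(parts, axis=1)


@dataclass
class CpGAnnotation:
    """CpG -> gene(s) mapping with genomic coordinates.

    ``frame`` is indexed by cpg_id with columns chr, pos, genes, where
    ``genes`` is a tuple of unique gene symbols (possibly empty; CpGs may
    map to more than one gene).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        for c in ("chr", "pos", "genes"):
            if c not in self.frame.columns:
                raise DataError(f"annotation missing column {c}")
        cleaned = []
        for genes in self.frame["genes"]:
            seen: list[str] = []
            for g in genes:
                g = str(g).strip()
                if not g:
                    raise DataError("empty gene symbol in annotation")
                if g not in seen:
                    seen.append(g)
            cleaned.append(tuple(seen))
        self.frame = self.frame.copy()
        self.frame["genes"] = cleaned

    @property
    def cpg_ids(self) -> pd.Index:
        return self.frame.index

    def genes_for(self, cpg_id: str) -> tuple[str, ...]:
        return self.frame.at[cpg_id, "genes"]

    @property
    def universe(self) -> frozenset[str]:
        """All gene symbols appearing anywhere in the annotation."""
        out: set[str] = set()
        for genes in self.frame["genes"]:
            out.update(genes)
        return frozenset(out)


@dataclass
class GeneSetDatabase:
    """Named collection of gene categories plus its reference universe.

    Every category is a subset of ``reference``; by default the reference
    is the union of all category members (standard over-representation
    practice when no explicit universe is supplied).
    """

    db_name: str
    categories: dict[str, frozenset[str]]
    reference: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.categories = {
            str(k): frozenset(map(str, v)) for k, v in self.categories.items()
        }
        if self.reference is None:
            union: set[str] = set()
            for genes in self.categories.values():
                union.update(genes)
            self.reference = frozenset(union)
        else:
            self.reference = frozenset(map(str, self.reference))
            for name, genes in self.categories.items():
                if not genes <= self.reference:
                    raise DataError(
                        f"category {name!r} is not a subset of the reference universe"
                    )

    def restricted_to(self, universe) -> "GeneSetDatabase":
        """Intersect the database with an external gene universe."""
        uni = frozenset(universe) & self.reference
        cats = {k: v & uni for k, v in self.categories.items()}
        return GeneSetDatabase(self.db_name, cats, uni)
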