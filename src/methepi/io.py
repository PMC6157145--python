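"""Readers and writers for the pipeline's native file formats.

All tabular files are UTF-8, tab-separated, Unix newlines.  Readers
validate the schema and point at the offending line/column on failure;
writers emit a canonical column order with fixed decimal formatting
(p-values in scientific notation with 6 significant figures) so repeated
runs are byte-identical.

Formats
-------
- TG panel: sample_id, tg1..tg4 (empty field = missing)
- phenotype: sample_id, y
- methylation matrix: header row of CpG ids, first column sample_id
- dosage matrix: header row of SNP ids, first column sample_id
- SNP metadata: snp_id, chr, pos, gene, alleles, maf
- covariates: sample_id, avg_pre_tg, age, center, current_smoker, sex
- annotation manifest: cpg_id, chr, pos, genes (semicolon-joined)
- gene sets: standard GMT (name, description, member genes...)
- VCF import (optional, via cyvcf2): GT converted to minor-allele dosage
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    COVARIATE_COLUMNS,
    CovariateTable,
    CpGAnnotation,
    DataError,
    GeneSetDatabase,
    GenotypeMatrix,
    MethylationPair,
    TG_COLUMNS,
    TriglyceridePanel,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"
_P_FMT = "{:.5e}"  # 6 significant figures, scientific


class ParseError(ValueError):
    """Malformed input file; the message names the line and column."""


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _require_columns(frame: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: header missing required columns {missing}")


def _require_numeric(frame: pd.DataFrame, cols, path) -> pd.DataFrame:
    out = frame.copy()
    for col in cols:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {out[col].iloc[row]!r} in column "
                f"{col!r}, line {row + 2}"
            )
        out[col] = converted
    return out


def _require_unique_index(frame: pd.DataFrame, path, what="sample id") -> None:
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        row = int(np.flatnonzero(frame.index == dup)[-1])
        raise ParseError(f"{path}: duplicate {what} {dup!r} at line {row + 2}")


# ---------------------------------------------------------------- TG panel

def read_tg_panel(path) -> TriglyceridePanel:
    frame = _read_tsv(path, dtype={"sample_id": str})
    _require_columns(frame, ["sample_id"] + TG_COLUMNS, path)
    frame = _require_numeric(frame, TG_COLUMNS, path)
    frame = frame.set_index("sample_id")
    _require_unique_index(frame, path)
    try:
        return TriglyceridePanel(frame)
    except DataError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_tg_panel(panel: TriglyceridePanel, path) -> None:
    panel.frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep="",
                       index_label="sample_id")


# --------------------------------------------------------------- phenotype

def read_phenotype(path) -> pd.Series:
    frame = _read_tsv(path, dtype={"sample_id": str})
    _require_columns(frame, ["sample_id", "y"], path)
    frame = _require_numeric(frame, ["y"], path).set_index("sample_id")
    _require_unique_index(frame, path)
    return frame["y"]


def write_phenotype(y: pd.Series, path) -> None:
    y.rename("y").to_frame().to_csv(
        path, sep="\t", float_format=_FLOAT_FMT, index_label="sample_id"
    )


# ------------------------------------------------------------- methylation

def _read_matrix(path) -> pd.DataFrame:
    frame = _read_tsv(path, index_col=0)
    frame.index = frame.index.astype(str)
    _require_unique_index(frame, path)
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            converted = pd.to_numeric(frame[col], errors="coerce")
            bad = converted.isna() & frame[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"{path}: non-numeric value in column {col!r}, line {row + 2}"
                )
            frame[col] = converted
    return frame


def read_methylation_pair(pre_path, post_path) -> MethylationPair:
    pre = _read_matrix(pre_path)
    post = _read_matrix(post_path)
    if not pre.index.equals(post.index) or not pre.columns.equals(post.columns):
        raise ParseError(
            f"{pre_path} and {post_path}: sample ids / CpG ids do not match"
        )
    if pre.isna().any().any() or post.isna().any().any():
        raise ParseError(f"{pre_path}/{post_path}: missing methylation values")
    return MethylationPair(pre.index, pre.columns, pre.to_numpy(), post.to_numpy())


def write_methylation_pair(meth: MethylationPair, pre_path, post_path) -> None:
    for mat, path in ((meth.beta_pre, pre_path), (meth.beta_post, post_path)):
        pd.DataFrame(mat, index=meth.sample_ids, columns=meth.cpg_ids).to_csv(
            path, sep="\t", float_format=_FLOAT_FMT, index_label="sample_id"
        )


# --------------------------------------------------------------- genotypes

def read_genotypes(dosage_path, snp_info_path) -> GenotypeMatrix:
    dosage = _read_matrix(dosage_path).astype(float)
    info = _read_tsv(snp_info_path, dtype={"snp_id": str, "chr": str})
    _require_columns(info, ["snp_id", "chr", "pos", "gene", "alleles", "maf"],
                     snp_info_path)
    info = _require_numeric(info, ["pos", "maf"], snp_info_path)
    info = info.set_index("snp_id")
    _require_unique_index(info, snp_info_path, what="SNP id")
    if set(dosage.columns) != set(info.index):
        raise ParseError(
            f"{dosage_path}: SNP columns do not match {snp_info_path} entries"
        )
    info = info.loc[dosage.columns]
    try:
        return GenotypeMatrix(dosage, info)
    except DataError as exc:
        raise ParseError(f"{dosage_path}: {exc}") from exc


def write_genotypes(geno: GenotypeMatrix, dosage_path, snp_info_path) -> None:
    geno.dosage.to_csv(dosage_path, sep="\t", float_format="%g", na_rep="",
                       index_label="sample_id")
    geno.snp_info.to_csv(snp_info_path, sep="\t", float_format=_FLOAT_FMT,
                         index_label="snp_id")


# -------------------------------------------------------------- covariates

def read_covariates(path) -> CovariateTable:
    frame = _read_tsv(path, dtype={"sample_id": str, "center": str})
    _require_columns(frame, ["sample_id"] + COVARIATE_COLUMNS, path)
    frame = _require_numeric(
        frame, ["avg_pre_tg", "age", "current_smoker", "sex"], path
    )
    frame = frame.set_index("sample_id")
    _require_unique_index(frame, path)
    try:
        return CovariateTable(frame)
    except DataError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_covariates(cov: CovariateTable, path) -> None:
    cov.frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT,
                     index_label="sample_id")


# -------------------------------------------------------------- annotation

def read_annotation(path) -> CpGAnnotation:
    frame = _read_tsv(path, dtype={"cpg_id": str, "chr": str, "genes": str})
    _require_columns(frame, ["cpg_id", "chr", "pos", "genes"], path)
    frame = _require_numeric(frame, ["pos"], path).set_index("cpg_id")
    _require_unique_index(frame, path, what="CpG id")
    genes = [
        tuple(g for g in str(raw).split(";") if g)
        if isinstance(raw, str) and raw
        else ()
        for raw in frame["genes"].fillna("")
    ]
    frame = frame.drop(columns="genes")
    frame["genes"] = genes
    return CpGAnnotation(frame)


def write_annotation(ann: CpGAnnotation, path) -> None:
    out = ann.frame.copy()
    out["genes"] = [";".join(g) for g in out["genes"]]
    out.to_csv(path, sep="\t", index_label="cpg_id")


# --------------------------------------------------------------------- GMT

def read_gmt(path, db_name: str | None = None) -> GeneSetDatabase:
    categories: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} tab-separated "
                    "fields; GMT requires name, description and >= 1 gene"
                )
            name = fields[0]
            if name in categories:
                raise ParseError(f"{path}: duplicate category {name!r} "
                                 f"at line {lineno}")
            categories[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetDatabase(db_name or Path(path).stem, categories)


def write_gmt(db: GeneSetDatabase, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in sorted(db.categories):
            genes = "\t".join(sorted(db.categories[name]))
            fh.write(f"{name}\t{db.db_name}\t{genes}\n")


# --------------------------------------------------------------------- VCF

def read_vcf_dosage(path, gene_by_snp: dict | None = None) -> GenotypeMatrix:
    """Import a VCF as a minor-allele dosage matrix.

    The minor allele is defined by in-sample allele frequency, with ties
    broken toward the ALT allele; multi-allelic records are skipped with
    a warning (the skipped count lands in ``dosage.attrs['n_skipped']``).
    Missing genotypes become NaN.  Requires cyvcf2.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError("VCF import requires the cyvcf2 package") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids, info_rows = [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            logger.warning("read_vcf_dosage: skipping multi-allelic record %s:%s",
                           rec.CHROM, rec.POS)
            continue
        snp_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
        gts = rec.genotype.array()[:, :2].astype(float)
        gts[gts < 0] = np.nan
        alt_dosage = gts.sum(axis=1)
        total = 2 * np.isfinite(alt_dosage).sum()
        alt_freq = np.nansum(alt_dosage) / total if total else 0.0
        if alt_freq <= 0.5:  # ALT is minor (ties toward ALT)
            dosage, maf = alt_dosage, alt_freq
            minor = rec.ALT[0]
        else:
            dosage, maf = 2.0 - alt_dosage, 1.0 - alt_freq
            minor = rec.REF
        rows.append(dosage)
        ids.append(snp_id)
        info_rows.append(
            {
                "chr": rec.CHROM,
                "pos": rec.POS,
                "gene": (gene_by_snp or {}).get(snp_id, "NA"),
                "alleles": f"{rec.REF}/{rec.ALT[0]}",
                "maf": max(maf, 1e-12),
                "minor_allele": minor,
            }
        )
    if not rows:
        raise ParseError(f"{path}: no usable biallelic records")
    dosage = pd.DataFrame(
        np.column_stack(rows),
        index=pd.Index(samples, name="sample_id"),
        columns=pd.Index(ids, name="snp_id"),
    )
    info = pd.DataFrame(info_rows, index=pd.Index(ids, name="snp_id"))
    geno = GenotypeMatrix(dosage, info)
    geno.dosage.attrs["n_skipped"] = n_skipped
    return geno


# ------------------------------------------------------------ result files

def _format_p(frame: pd.DataFrame, cols) -> pd.DataFrame:
    out = frame.copy()
    for col in cols:
        if col in out.columns:
            out[col] = [_P_FMT.format(v) if np.isfinite(v) else "NA"
                        for v in out[col].astype(float)]
    return out


def write_diffmeth_results(table: pd.DataFrame, path) -> None:
    out = _format_p(table.reset_index(names="cpg_id"), ["p"])
    cols = ["cpg_id", "t_stat", "df", "p", "degenerate", "passes"]
    out[[c for c in cols if c in out.columns]].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def write_assoc_results(table: pd.DataFrame, path) -> None:
    out = _format_p(table.reset_index(names="cpg_id"), ["p"])
    cols = ["cpg_id", "chr", "pos", "slope", "se", "t_stat", "df", "p",
            "degenerate", "neg_log10_p", "threshold_line"]
    out[[c for c in cols if c in out.columns]].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def write_enrichment_results(table: pd.DataFrame, path) -> None:
    out = _format_p(table.reset_index(), ["raw_p", "adj_p"])
    cols = ["category_id", "C", "O", "E", "R", "raw_p", "adj_p"]
    out[[c for c in cols if c in out.columns]].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def write_epistasis_results(table: pd.DataFrame, path) -> None:
    out = _format_p(table, ["p"])
    cols = ["snp_a", "snp_b", "alleles_a", "maf_a", "location_a",
            "alleles_b", "maf_b", "location_b", "lrt_stat", "df", "p",
            "beta_int", "n_used", "status", "significant"]
    out[[c for c in cols if c in out.columns]].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_list(path) -> frozenset[str]:
    with open(path, encoding="utf-8") as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_truth(truth: dict, path) -> None:
    """Planted-signal record as a two-column key/value TSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("key\tvalue\n")
        for key, value in truth.items():
            if isinstance(value, (list, tuple)):
                value = ";".join(map(str, value))
            fh.write(f"{key}\t{value}\n")


def write_cohort(cohort, outdir) -> dict[str, str]:
    """Write every cohort component in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tg_panel": outdir / "tg_panel.tsv",
        "meth_pre": outdir / "methylation_pre.tsv",
        "meth_post": outdir / "methylation_post.tsv",
        "dosage": outdir / "genotype_dosage.tsv",
        "snp_info": outdir / "snp_info.tsv",
        "covariates": outdir / "covariates.tsv",
        "annotation": outdir / "cpg_annotation.tsv",
        "genesets": outdir / "genesets.gmt",
        "truth": outdir / "truth.tsv",
    }
    write_tg_panel(cohort.tg_panel, paths["tg_panel"])
    write_methylation_pair(cohort.meth, paths["meth_pre"], paths["meth_post"])
    write_genotypes(cohort.genotypes, paths["dosage"], paths["snp_info"])
    write_covariates(cohort.covariates, paths["covariates"])
    write_annotation(cohort.annotation, paths["annotation"])
    write_gmt(cohort.genesets, paths["genesets"])
    write_truth(cohort.truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
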