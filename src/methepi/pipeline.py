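"""End-to-end pipeline: simulate -> phenotype -> differential methylation
-> per-CpG association -> gene-list curation + ORA -> epistasis scan.

Each stage consumes the previous stage's files, so stages can be re-run
independently; a machine-readable run report records per-stage input and
output counts, the thresholds used and wall time.  Identical config and
seed produce byte-identical result files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io
from .association import CpGAssociation
from .data import DataError
from .diffmeth import PairedDifferentialMethylation
from .enrichment import OverRepresentation, curate_gene_list
from .epistasis import CrossGeneEpistasisScan
from .phenotype import compute_log_tg_ratio, impute_missing_visits
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "phenotype", "diffmeth", "assoc", "enrich", "epistasis")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    ``workdir`` holds both the input files (written by the simulate stage
    or supplied by the user) and the stage outputs.  ``stages`` selects
    which stages run; each stage requires its predecessors' files to
    exist.
    """

    workdir: str = "methepi_run"
    stages: tuple[str, ...] = ALL_STAGES
    alpha: float = 0.05
    curation_p_cut: float = 0.05
    adjust_method: str = "BH"
    gene_a: str = "FTO"
    gene_b: str = "ALKBH5"
    use_covariates: bool = True
    seed: int = 0
    simulation: SimulationConfig = None  # type: ignore[assignment]
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.curation_p_cut <= 1:
            raise ValueError("curation_p_cut must lie in [0, 1]")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)

    # ---- serialization (round-trip stable) ----
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        sim = d.get("simulation")
        if isinstance(sim, dict):
            d["simulation"] = SimulationConfig(**sim)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class _Paths:
    work: Path

    def __getattr__(self, name: str) -> Path:
        files = {
            "tg_panel": "tg_panel.tsv",
            "meth_pre": "methylation_pre.tsv",
            "meth_post": "methylation_post.tsv",
            "dosage": "genotype_dosage.tsv",
            "snp_info": "snp_info.tsv",
            "covariates": "covariates.tsv",
            "annotation": "cpg_annotation.tsv",
            "genesets": "genesets.gmt",
            "truth": "truth.tsv",
            "phenotype": "phenotype.tsv",
            "diffmeth": "diffmeth_results.tsv",
            "pass_list": "diffmeth_pass.txt",
            "assoc": "assoc_results.tsv",
            "manhattan": "manhattan.tsv",
            "manhattan_png": "manhattan.png",
            "gene_list": "gene_list.txt",
            "enrichment": "enrichment_results.tsv",
            "epistasis": "epistasis_results.tsv",
            "strata": "genotype_strata.tsv",
            "strata_png": "genotype_strata.png",
            "report": "report.json",
        }
        if name in files:
            return self.work / files[name]
        raise AttributeError(name)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DataError(
            f"stage {stage!r} requires {path.name}, which does not exist in "
            f"{path.parent} — run the producing stage first"
        )
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run report dict."""
    work = Path(config.workdir)
    work.mkdir(parents=True, exist_ok=True)
    paths = _Paths(work)
    logging.basicConfig(level=logging.INFO)
    report: dict = {"config": config.to_dict(), "stages": {}}

    def record(stage: str, t0: float, **counts) -> None:
        report["stages"][stage] = {
            "wall_seconds": round(time.perf_counter() - t0, 3), **counts
        }
        logger.info("stage %s: %s", stage, counts)

    if "simulate" in config.stages:
        t0 = time.perf_counter()
        cohort = simulate_cohort(config.simulation)
        io.write_cohort(cohort, work)
        record(
            "simulate", t0,
            n_subjects=cohort.config.n_subjects,
            n_cpgs=cohort.meth.n_cpgs,
            n_snps=len(cohort.genotypes.snp_ids),
            n_shifted_cpgs=len(cohort.truth["shifted_cpgs"]),
        )

    if "phenotype" in config.stages:
        t0 = time.perf_counter()
        panel = io.read_tg_panel(_require(paths.tg_panel, "phenotype"))
        complete = impute_missing_visits(panel)
        y = compute_log_tg_ratio(complete)
        io.write_phenotype(y, paths.phenotype)
        n_imputed = int(panel.frame.isna().sum().sum())
        record("phenotype", t0, n_subjects=len(y), n_imputed_visits=n_imputed)

    if "diffmeth" in config.stages:
        t0 = time.perf_counter()
        meth = io.read_methylation_pair(
            _require(paths.meth_pre, "diffmeth"),
            _require(paths.meth_post, "diffmeth"),
        )
        res = PairedDifferentialMethylation(meth).fit(alpha=config.alpha)
        io.write_diffmeth_results(res.table, paths.diffmeth)
        with open(paths.pass_list, "w", encoding="utf-8", newline="\n") as fh:
            fh.writelines(f"{c}\n" for c in res.significant_sites)
        record(
            "diffmeth", t0,
            n_tested=res.n_tested, threshold=res.threshold,
            n_passing=res.n_significant,
        )

    if "assoc" in config.stages:
        t0 = time.perf_counter()
        y = io.read_phenotype(_require(paths.phenotype, "assoc"))
        meth = io.read_methylation_pair(
            _require(paths.meth_pre, "assoc"), _require(paths.meth_post, "assoc")
        )
        with open(_require(paths.pass_list, "assoc"), encoding="utf-8") as fh:
            pass_sites = [line.strip() for line in fh if line.strip()]
        ann = io.read_annotation(_require(paths.annotation, "assoc"))
        meth_sub = meth.subset_sites(pass_sites)
        res = CpGAssociation(
            y.loc[meth.sample_ids], meth_sub, annotation=ann.frame
        ).fit(alpha=config.alpha)
        io.write_assoc_results(res.table, paths.assoc)
        mh = res.manhattan_table()
        io.write_assoc_results(mh, paths.manhattan)
        if config.make_plots:
            res.plot_manhattan(paths.manhattan_png)
        record(
            "assoc", t0,
            n_input_sites=len(pass_sites), n_tested=res.n_tested,
            threshold=res.threshold,
            n_genomewide_significant=res.n_genomewide_significant,
        )

    if "enrich" in config.stages:
        t0 = time.perf_counter()
        assoc = _read_assoc(paths, "enrich")
        ann = io.read_annotation(_require(paths.annotation, "enrich"))
        db = io.read_gmt(_require(paths.genesets, "enrich"))
        genes = curate_gene_list(assoc, ann, p_cut=config.curation_p_cut)
        io.write_gene_list(genes, paths.gene_list)
        ora = OverRepresentation(genes, db, universe=ann.universe).fit(
            method=config.adjust_method
        )
        io.write_enrichment_results(ora.table, paths.enrichment)
        record(
            "enrich", t0,
            n_assoc_sites=len(assoc), n_curated_genes=len(genes),
            n_categories=len(ora.table),
            top_category=ora.top_category,
        )

    if "epistasis" in config.stages:
        t0 = time.perf_counter()
        y = io.read_phenotype(_require(paths.phenotype, "epistasis"))
        geno = io.read_genotypes(
            _require(paths.dosage, "epistasis"),
            _require(paths.snp_info, "epistasis"),
        )
        cov = (
            io.read_covariates(_require(paths.covariates, "epistasis"))
            if config.use_covariates
            else None
        )
        scan = CrossGeneEpistasisScan(
            y, geno, cov, config.gene_a, config.gene_b
        ).fit(alpha=config.alpha)
        io.write_epistasis_results(scan.annotated_table(), paths.epistasis)
        top = scan.table.iloc[0]
        strata = scan.stratified_summaries(top.snp_a, top.snp_b)
        strata.to_csv(paths.strata, sep="\t", index=False, float_format="%.10g")
        if config.make_plots:
            scan.plot_stratified(top.snp_a, top.snp_b, paths.strata_png)
        record(
            "epistasis", t0,
            n_snps_gene_a=scan.model.genoA.dosage.shape[1],
            n_snps_gene_b=scan.model.genoB.dosage.shape[1],
            m=scan.m, threshold=scan.threshold,
            n_significant=int(len(scan.significant_pairs)),
            top_pair=[top.snp_a, top.snp_b],
        )

    with open(paths.report, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _read_assoc(paths: _Paths, stage: str):
    import pandas as pd

    frame = pd.read_csv(_require(paths.assoc, stage), sep="\t")
    frame["p"] = frame["p"].astype(float)
    return frame.set_index("cpg_id")
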