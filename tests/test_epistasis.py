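"""Cross-gene LRT epistasis scan: pair handling, statistics, summaries."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from methepi.data import DataError
from methepi.epistasis import (
    CrossGeneEpistasisScan,
    completeness_filter,
    cross_gene_pairs,
    epistasis_scan,
    fit_interaction_lrt,
    genotype_stratified_summaries,
)
from methepi.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_covariates,
    simulate_genotypes,
    simulate_phenotype_epistasis,
)

from conftest import make_covariates, make_genotypes


def small_scan_inputs(seed=5, n=250, with_cov=True):
    genoA = simulate_genotypes([0.34, 0.2, 0.45], n, seed, gene="FTO",
                               snp_prefix="a")
    genoB = simulate_genotypes([0.18, 0.3], n, seed + 1, gene="ALKBH5",
                               snp_prefix="b")
    rng = np.random.default_rng(seed + 2)
    cov = make_covariates(n, rng, sample_ids=genoA.sample_ids) if with_cov else None
    y = pd.Series(rng.normal(size=n), index=genoA.sample_ids, name="y")
    return y, genoA, genoB, cov


class TestCompletenessFilter:
    def test_identity_when_complete_and_polymorphic(self, rng):
        geno = make_genotypes(rng.integers(0, 3, size=(20, 4)),
                              genes=["FTO"] * 4)
        out = completeness_filter(geno, geno.sample_ids)
        pd.testing.assert_frame_equal(out.dosage, geno.dosage)

    def test_single_missing_genotype_drops_snp(self, rng):
        dosage = rng.integers(0, 3, size=(15, 3)).astype(float)
        dosage[4, 1] = np.nan
        geno = make_genotypes(dosage, genes=["FTO"] * 3)
        out = completeness_filter(geno, geno.sample_ids)
        assert out.snp_ids.tolist() == ["snp1", "snp3"]

    def test_toy_six_snp_enumeration(self, rng):
        dosage = rng.integers(0, 3, size=(12, 6)).astype(float)
        dosage[0, 1] = np.nan          # missing
        dosage[5, 4] = np.nan          # missing
        dosage[:, 2] = 1.0             # monomorphic
        geno = make_genotypes(dosage, genes=["FTO"] * 6)
        out = completeness_filter(geno, geno.sample_ids)
        assert out.snp_ids.tolist() == ["snp1", "snp4", "snp6"]

    def test_empty_sample_list_rejected(self, rng):
        geno = make_genotypes(rng.integers(0, 3, size=(5, 2)), genes=["FTO"] * 2)
        with pytest.raises(ValueError):
            completeness_filter(geno, [])


class TestCrossGenePairs:
    @pytest.mark.parametrize("na, nb, expected", [(68, 5, 340), (51, 5, 255)])
    def test_published_pair_counts(self, na, nb, expected):
        pairs = cross_gene_pairs([f"a{i}" for i in range(na)],
                                 [f"b{i}" for i in range(nb)])
        assert len(pairs) == expected
        assert pairs[0] == ("a0", "b0") and pairs[nb] == ("a1", "b0")

    def test_empty_list_gives_no_pairs(self):
        assert cross_gene_pairs([], ["b1"]) == []

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            cross_gene_pairs(["x", "y"], ["y", "z"])


class TestInteractionLRT:
    def test_matches_statsmodels_nested_ols(self):
        # oracle: explicit base/full OLS fits and n*ln(RSS_b/RSS_f)
        y, genoA, genoB, cov = small_scan_inputs(seed=9)
        gA = genoA.dosage.iloc[:, 0]
        gB = genoB.dosage.iloc[:, 0]
        rec = fit_interaction_lrt(y, gA, gB, cov)
        X = np.column_stack(
            [np.ones(len(y)), cov.design_matrix().to_numpy(dtype=float),
             gA.to_numpy(), gB.to_numpy()]
        )
        base = sm.OLS(y.to_numpy(), X).fit()
        full = sm.OLS(
            y.to_numpy(),
            np.column_stack([X, gA.to_numpy() * gB.to_numpy()]),
        ).fit()
        lrt_ref = len(y) * np.log(base.ssr / full.ssr)
        assert rec["lrt_stat"] == pytest.approx(lrt_ref, rel=1e-8)
        assert rec["p"] == pytest.approx(stats.chi2.sf(lrt_ref, 1), rel=1e-8)
        assert rec["beta_int"] == pytest.approx(full.params[-1], rel=1e-8)
        assert rec["status"] == "ok"

    def test_chi2_tail_equals_normal_identity(self):
        # chi-square-1 upper tail at lambda equals 2*Phi(-sqrt(lambda))
        y, genoA, genoB, cov = small_scan_inputs(seed=2)
        rec = fit_interaction_lrt(
            y, genoA.dosage.iloc[:, 1], genoB.dosage.iloc[:, 1], cov
        )
        assert rec["p"] == pytest.approx(
            2 * stats.norm.sf(np.sqrt(rec["lrt_stat"])), rel=1e-10
        )

    def test_monomorphic_snp_skipped(self):
        y, genoA, genoB, cov = small_scan_inputs(seed=3)
        flat = pd.Series(np.ones(len(y)), index=y.index, name="mono")
        rec = fit_interaction_lrt(y, genoA.dosage.iloc[:, 0], flat, cov)
        assert rec["status"] == "skipped_monomorphic"
        assert np.isnan(rec["p"])

    def test_collinear_interaction_degenerate(self):
        rng = np.random.default_rng(0)
        n = 60
        g = rng.integers(0, 2, size=n).astype(float)  # binary dosage
        idx = pd.Index([f"S{i}" for i in range(n)])
        y = pd.Series(rng.normal(size=n), index=idx)
        gA = pd.Series(g, index=idx, name="a1")
        gB = pd.Series(g, index=idx, name="b1")  # product == gA == gB
        rec = fit_interaction_lrt(y, gA, gB, None)
        assert rec["status"] == "degenerate"
        assert rec["p"] == 1.0 and rec["lrt_stat"] == 0.0


class TestScan:
    def test_scan_agrees_with_per_pair_fits(self):
        # the shared-residualisation scan must reproduce the naive
        # per-pair nested fits exactly
        y, genoA, genoB, cov = small_scan_inputs(seed=7)
        table = epistasis_scan(y, genoA, genoB, cov).set_index(
            ["snp_a", "snp_b"]
        )
        assert len(table) == 6
        for snp_a in genoA.snp_ids:
            for snp_b in genoB.snp_ids:
                rec = fit_interaction_lrt(
                    y, genoA.dosage[snp_a], genoB.dosage[snp_b], cov
                )
                row = table.loc[(snp_a, snp_b)]
                assert row["lrt_stat"] == pytest.approx(rec["lrt_stat"], abs=1e-7)
                assert row["p"] == pytest.approx(rec["p"], rel=1e-6, abs=1e-12)
                assert row["beta_int"] == pytest.approx(rec["beta_int"], rel=1e-7)

    def test_emits_one_record_per_pair_sorted_by_p(self):
        cfg = SimulationConfig(seed=21, n_cpgs=50)
        cohort = simulate_cohort(cfg)
        y = simulate_phenotype_epistasis(
            cohort.genotypes, cohort.covariates, cohort.truth["interacting_pair"],
            cfg.interaction_beta, cfg.noise_sd, 99,
        )
        scan = CrossGeneEpistasisScan(
            y, cohort.genotypes, cohort.covariates, "FTO", "ALKBH5"
        ).fit()
        assert scan.m == 340
        assert len(scan.table) == 340
        p = scan.table["p"].to_numpy()
        assert np.all(np.diff(p[np.isfinite(p)]) >= 0)
        top = scan.table.iloc[0]
        assert (top.snp_a, top.snp_b) == cohort.truth["interacting_pair"]
        assert top.significant
        annotated = scan.annotated_table()
        assert {"alleles_a", "maf_b", "location_a"} <= set(annotated.columns)
        assert "340" in scan.summary()

    def test_lrt_close_to_partial_f_on_null(self):
        # asymptotic equivalence: |p_LRT - p_F| small for nearly all null pairs
        cfg = SimulationConfig(seed=31, n_cpgs=50, n_subjects=2000)
        cohort = simulate_cohort(cfg)
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(size=cfg.n_subjects),
                      index=cohort.sample_ids, name="y")
        scan = CrossGeneEpistasisScan(
            y, cohort.genotypes, cohort.covariates, "FTO", "ALKBH5"
        ).fit()
        k_base = scan.table.attrs["k_covariates"] + 2
        n = cfg.n_subjects
        lam = scan.table["lrt_stat"].to_numpy()
        rss_ratio = np.exp(lam / n)
        f_stat = (rss_ratio - 1) * (n - k_base - 1)
        p_f = stats.f.sf(f_stat, 1, n - k_base - 1)
        diff = np.abs(scan.table["p"].to_numpy() - p_f)
        assert np.quantile(diff, 0.99) <= 0.002


class TestStratifiedSummaries:
    def test_nine_subject_contingency(self):
        idx = pd.Index([f"S{i}" for i in range(9)])
        gA = pd.Series([0, 0, 0, 1, 1, 1, 2, 2, 2], index=idx, name="a")
        gB = pd.Series([0, 1, 2, 0, 1, 2, 0, 1, 2], index=idx, name="b")
        y = pd.Series(np.arange(9, dtype=float), index=idx)
        out = genotype_stratified_summaries(y, gA, gB)
        joint = out[out["stratum"] == "joint"]
        assert (joint["count"] == 1).all()
        assert joint.loc[
            (joint["gA"] == 1) & (joint["gB"] == 2), "mean"
        ].iloc[0] == pytest.approx(5.0)
        marg = out[out["stratum"] == "marginal_a"]
        assert marg["count"].tolist() == [3, 3, 3]

    def test_all_homozygous_major_single_cell(self):
        idx = pd.Index([f"S{i}" for i in range(7)])
        zero = pd.Series(np.zeros(7), index=idx, name="g")
        y = pd.Series(np.random.default_rng(1).normal(size=7), index=idx)
        out = genotype_stratified_summaries(y, zero, zero.rename("h"))
        joint = out[out["stratum"] == "joint"]
        assert joint["count"].sum() == 7
        assert joint.loc[(joint["gA"] == 0) & (joint["gB"] == 0),
                         "count"].iloc[0] == 7

    def test_constant_phenotype(self):
        idx = pd.Index([f"S{i}" for i in range(6)])
        g = pd.Series([0, 1, 2, 0, 1, 2], index=idx, name="g")
        y = pd.Series(np.full(6, 0.4), index=idx)
        out = genotype_stratified_summaries(y, g, g.rename("h"))
        filled = out[out["count"] > 0]
        assert np.allclose(filled["mean"], 0.4)
        assert np.allclose(filled["median"], 0.4)


class TestPlantedSignalProperties:
    def test_interaction_found_without_marginal_effects(self):
        # headline property: the planted pair clears Bonferroni while each
        # SNP's single-locus test stays unremarkable (short pilot; the
        # replicated version lives in the acceptance suite)
        cfg = SimulationConfig(seed=13, n_cpgs=50)
        cohort = simulate_cohort(cfg)
        pair = cohort.truth["interacting_pair"]
        y = simulate_phenotype_epistasis(
            cohort.genotypes, cohort.covariates, pair,
            cfg.interaction_beta, cfg.noise_sd, 7,
        )
        scan = CrossGeneEpistasisScan(
            y, cohort.genotypes, cohort.covariates, "FTO", "ALKBH5"
        ).fit()
        top = scan.table.iloc[0]
        assert (top.snp_a, top.snp_b) == pair and top.significant
        X0 = np.column_stack(
            [np.ones(len(y)),
             cohort.covariates.design_matrix().to_numpy(dtype=float)]
        )
        for snp in pair:
            g = cohort.genotypes.dosage[snp].to_numpy()
            fit = sm.OLS(y.to_numpy(), np.column_stack([X0, g])).fit()
            assert fit.pvalues[-1] > 0.05 / 73

    def test_null_interaction_uniform_pvalues(self):
        cfg = SimulationConfig(seed=41, n_cpgs=50)
        cohort = simulate_cohort(cfg)
        y = simulate_phenotype_epistasis(
            cohort.genotypes, cohort.covariates,
            cohort.truth["interacting_pair"], 0.0, cfg.noise_sd, 11,
        )
        scan = CrossGeneEpistasisScan(
            y, cohort.genotypes, cohort.covariates, "FTO", "ALKBH5"
        ).fit()
        assert len(scan.significant_pairs) == 0
        ks = stats.kstest(scan.table["p"].dropna(), "uniform")
        assert ks.pvalue > 0.001
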