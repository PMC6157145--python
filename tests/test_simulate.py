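"""Synthetic cohort generator: distributions, planted truth, determinism."""

import numpy as np
import pandas as pd
import pytest

from methepi import io
from methepi.simulate import (
    SimulationConfig,
    default_gene_a_mafs,
    default_gene_b_mafs,
    simulate_cohort,
    simulate_genotypes,
    simulate_methylation_pair,
    simulate_phenotype_epistasis,
    simulate_triglyceride_panel,
)


class TestGenotypes:
    def test_mean_dosage_matches_binomial_expectation(self):
        # E[dosage] = 2*maf = 1.0 at maf 0.5; 4 binomial SEs at n = 10^4
        geno = simulate_genotypes([0.5], 10_000, seed=1)
        se4 = 4 * np.sqrt(2 * 0.5 * 0.5 / 10_000)
        assert abs(geno.dosage.iloc[:, 0].mean() - 1.0) < max(se4, 0.03)

    def test_rare_allele_limit(self):
        geno = simulate_genotypes([1e-9], 100, seed=2)
        assert (geno.dosage.to_numpy() == 0).all()

    @pytest.mark.parametrize("bad", [0.0, -0.1, 0.6])
    def test_maf_domain(self, bad):
        with pytest.raises(ValueError):
            simulate_genotypes([bad], 10, seed=0)

    def test_n_domain(self):
        with pytest.raises(ValueError):
            simulate_genotypes([0.3], 0, seed=0)

    def test_default_maf_lists_carry_published_values(self):
        a, b = default_gene_a_mafs(), default_gene_b_mafs()
        assert len(a) == 68 and len(b) == 5
        assert {0.34, 0.41} <= set(a)
        assert {0.18, 0.24} <= set(b)
        assert all(0 < m <= 0.5 for m in a + b)

    def test_metadata_carries_inputs(self):
        geno = simulate_genotypes([0.2, 0.4], 50, seed=3, gene="FTO",
                                  chrom="16")
        assert geno.snp_info["maf"].tolist() == [0.2, 0.4]
        assert (geno.snp_info["gene"] == "FTO").all()
        assert not geno.dosage.isna().any().any()


class TestTriglyceridePanel:
    def test_no_missingness_gives_complete_positive_panel(self):
        cfg = SimulationConfig(n_subjects=300, missing_visit_rate=0.0, seed=4)
        panel = simulate_triglyceride_panel(cfg)
        assert panel.is_complete()
        assert (panel.frame.to_numpy() > 0).all()

    @pytest.mark.parametrize("which, rho", [("pre", 0.90), ("post", 0.91)])
    def test_visit_correlations_within_fisher_z_band(self, which, rho):
        cfg = SimulationConfig(n_subjects=5000, missing_visit_rate=0.0, seed=6)
        panel = simulate_triglyceride_panel(cfg)
        cols = ["tg1", "tg2"] if which == "pre" else ["tg3", "tg4"]
        logs = np.log(panel.frame[cols].to_numpy())
        r = np.corrcoef(logs[:, 0], logs[:, 1])[0, 1]
        half = 2.576 / np.sqrt(5000 - 3)  # 99% Fisher-z interval
        assert abs(np.arctanh(r) - np.arctanh(rho)) < half

    @pytest.mark.parametrize("rate", [0.1, 0.3, 0.45])
    def test_block_always_keeps_one_visit(self, rate):
        cfg = SimulationConfig(n_subjects=500, missing_visit_rate=rate, seed=7)
        panel = simulate_triglyceride_panel(cfg)
        pre_ok = panel.frame[["tg1", "tg2"]].notna().any(axis=1)
        post_ok = panel.frame[["tg3", "tg4"]].notna().any(axis=1)
        assert pre_ok.all() and post_ok.all()
        observed_rate = panel.frame.isna().to_numpy().mean()
        assert observed_rate == pytest.approx(rate, abs=0.05)

    def test_correlation_domain_checked(self):
        with pytest.raises(ValueError):
            SimulationConfig(tg_visit_corr_pre=1.0)


class TestMethylation:
    def test_betas_in_open_unit_interval(self):
        cfg = SimulationConfig(n_subjects=40, n_cpgs=200, seed=8)
        meth, _ = simulate_methylation_pair(cfg)
        for mat in (meth.beta_pre, meth.beta_post):
            assert (mat > 0).all() and (mat < 1).all()

    def test_truth_lists_exactly_the_shifted_fraction(self):
        cfg = SimulationConfig(n_subjects=30, n_cpgs=1000,
                               frac_shifted_cpgs=0.25, seed=9)
        meth, shifted = simulate_methylation_pair(cfg)
        assert len(shifted) == 250
        assert set(shifted) <= set(meth.cpg_ids)

    def test_frac_domain(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_shifted_cpgs=1.2)


class TestEpistaticPhenotype:
    def _cohort(self, seed=10):
        return simulate_cohort(SimulationConfig(seed=seed, n_cpgs=50))

    def test_null_interaction_independent_of_genotype(self):
        c = self._cohort()
        pair = c.truth["interacting_pair"]
        y = simulate_phenotype_epistasis(
            c.genotypes, c.covariates, pair, 0.0, 0.2, seed=1
        )
        prod = (
            c.genotypes.dosage[pair[0]] - c.genotypes.dosage[pair[0]].mean()
        ) * (c.genotypes.dosage[pair[1]] - c.genotypes.dosage[pair[1]].mean())
        r = np.corrcoef(y, prod)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(y))

    def test_fixed_seed_reproduces_vector(self):
        c = self._cohort()
        pair = c.truth["interacting_pair"]
        y1 = simulate_phenotype_epistasis(c.genotypes, c.covariates, pair,
                                          0.12, 0.2, seed=42)
        y2 = simulate_phenotype_epistasis(c.genotypes, c.covariates, pair,
                                          0.12, 0.2, seed=42)
        pd.testing.assert_series_equal(y1, y2)

    def test_unknown_snp_and_same_gene_pair_rejected(self):
        c = self._cohort()
        with pytest.raises(KeyError):
            simulate_phenotype_epistasis(c.genotypes, c.covariates,
                                         ("nope", "alkbh5_001"), 0.1, 0.2, 1)
        with pytest.raises(ValueError):
            simulate_phenotype_epistasis(c.genotypes, c.covariates,
                                         ("fto_001", "fto_002"), 0.1, 0.2, 1)

    def test_noise_sd_domain(self):
        c = self._cohort()
        with pytest.raises(ValueError):
            simulate_phenotype_epistasis(
                c.genotypes, c.covariates, c.truth["interacting_pair"],
                0.1, 0.0, 1,
            )


class TestCohort:
    def test_components_share_sample_ids(self, small_cohort):
        ids = small_cohort.tg_panel.sample_ids
        assert small_cohort.meth.sample_ids.equals(ids)
        assert small_cohort.genotypes.sample_ids.equals(ids)
        assert small_cohort.covariates.sample_ids.equals(ids)

    def test_truth_record_scores_recovery(self, small_cohort):
        truth = small_cohort.truth
        assert set(truth["shifted_cpgs"]) <= set(small_cohort.meth.cpg_ids)
        a, b = truth["interacting_pair"]
        assert a in small_cohort.genotypes.snp_ids
        assert b in small_cohort.genotypes.snp_ids
        assert truth["enriched_category"] in small_cohort.genesets.categories

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_subjects=60, n_cpgs=80, n_genes=40,
                               n_categories=5, seed=77)
        for d in ("one", "two"):
            io.write_cohort(simulate_cohort(cfg), tmp_path / d)
        for name in ("tg_panel.tsv", "methylation_pre.tsv", "genotype_dosage.tsv",
                     "covariates.tsv", "cpg_annotation.tsv", "genesets.gmt",
                     "truth.tsv"):
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name
            ).read_bytes()
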