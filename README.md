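# methepi

Methylation-informed discovery of cross-gene SNP×SNP epistasis for
pharmacoepigenetic trial designs.

Complex drug-response phenotypes are often shaped by interactions between
loci that show no detectable effect on their own. `methepi` implements a
complete workflow for hunting such interactions between two candidate
genes — here the two human RNA m⁶A demethylases *FTO* and *ALKBH5* — in a
clinical-trial design with paired pre/post-treatment triglyceride and
DNA-methylation measurements:

1. **Phenotype** — the drug response is
   `y = ln( mean(TG₃, TG₄) / mean(TG₁, TG₂) )`, the log ratio of average
   post- to pre-treatment triglycerides; missing visits are singly imputed
   by within-block linear regression on the paired visit.
2. **Differential methylation** — every CpG site is tested with a paired
   *t*-test of post vs pre beta values, `t = mean(d)/(sd(d)/√n)` with
   `n − 1` df, filtered at the Bonferroni threshold `α/m`.
3. **Per-CpG association** — for each surviving site, simple OLS of the
   phenotype on the methylation log ratio `ln(β_post/β_pre)`, with
   Manhattan-plot-ready output.
4. **Over-representation analysis** — genes annotated to associated sites
   form a signal list; each gene-set category (from user-supplied GMT
   files) is tested with the one-sided hypergeometric upper tail
   `P(X ≥ O)` given a reference universe of `N` genes, with `E = nK/N`,
   enrichment ratio `R = O/E`, and Benjamini–Hochberg (or Bonferroni)
   adjustment.
5. **Targeted epistasis scan** — for every cross-gene SNP pair (additively
   coded 0/1/2 minor-allele dosages, never within-gene pairs), nested
   Gaussian linear models with and without the product interaction are
   compared by the likelihood-ratio statistic
   `λ = n·ln(RSS_base/RSS_full)` against χ²₁, Bonferroni-controlled over
   the `|A|×|B|` pairs.

Because the motivating trial data are access-restricted, the package ships
a first-class synthetic-cohort generator (`methepi.simulate`) that
reproduces the relevant statistical structure — including a *pure*
epistatic phenotype planted on centred dosages so that each SNP's
marginal effect is zero by construction — plus a truth record for scoring
recovery.

## Worked example

```python
from methepi import CrossGeneEpistasisScan, PairedDifferentialMethylation
from methepi.phenotype import compute_log_tg_ratio, impute_missing_visits
from methepi.simulate import SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(seed=1))          # 680 subjects
y = compute_log_tg_ratio(impute_missing_visits(cohort.tg_panel))

print(PairedDifferentialMethylation(cohort.meth).fit(alpha=0.05).summary())
scan = CrossGeneEpistasisScan(y, cohort.genotypes, cohort.covariates,
                              "FTO", "ALKBH5").fit(alpha=0.05)
print(scan.summary(top=3))
```

prints

```
Paired differential methylation (pre vs post treatment)
  CpG sites tested:      10000
  alpha (family-wise):   0.05
  Bonferroni threshold:  5.000000e-06
  sites passing:         4500
  degenerate sites:      0
Cross-gene epistasis scan: FTO x ALKBH5
  SNPs: 68 x 5 = 340 pairs tested
  Bonferroni threshold (alpha=0.05): 1.470588e-04
  significant pairs: 1
  fto_001 x alkbh5_001: LRT=30.294 p=3.714e-08 beta_int=0.1486 [ok]
  fto_019 x alkbh5_001: LRT=13.530 p=2.348e-04 beta_int=-0.1178 [ok]
  fto_031 x alkbh5_001: LRT=10.999 p=9.114e-04 beta_int=-0.0952 [ok]
```

Reading this: 4500 of 10 000 simulated CpG sites are differentially
methylated at the family-wise threshold 0.05/10 000 (the generator shifts
45% of sites). The scan tests all 340 FTO×ALKBH5 dosage pairs; exactly
one — the planted pair `fto_001 × alkbh5_001`, with interaction
coefficient ≈ 0.149 log-ratio units per centred-dosage product — clears
the Bonferroni threshold 0.05/340 ≈ 1.47 × 10⁻⁴, while neither SNP is
significant marginally.

The same workflow is available from the shell:

```bash
methepi run-all --workdir demo_run --seed 1     # simulate + all stages
methepi report --workdir demo_run               # per-stage counts, thresholds
```

Every stage reads and writes plain TSV/GMT files (see
`methepi.io`), so real genotype (optionally VCF), methylation and
annotation data can be dropped into the same pipeline.

## Documentation

`docs/methods.md` describes the statistical model of every stage, the
synthetic-data generator and its defaults, numerical choices, and known
limitations.
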