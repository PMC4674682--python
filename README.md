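# popepimeth

Population epigenomics of human blood methylomes: differential methylation
between population groups, multi-population cis-meQTL mapping by Bayesian
model averaging, selection scans, and the enrichment statistics that connect
them — together with a synthetic cohort simulator that provides ground truth
for every stage.

## The problem

Comparative methylome studies of human populations — for example rainforest
hunter-gatherers and farmers sampled from contrasting habitats — ask three
linked questions:

1. **Which CpG sites differ in methylation between groups?**  Per site, the
   M-value M = log2(β/(1−β)) (β the methylated fraction) is modelled as
   `M ~ group + sex + age + cell proportions + ε`, with empirical-Bayes
   shrinkage of the residual variances: assuming s² ~ s0²·χ²_{d0}/d0 across
   probes, the posterior variance s̃² = (d0·s0² + d·s²)/(d0+d) yields a
   moderated t with d0+d degrees of freedom.  Sites are called at a
   Benjamini–Hochberg q < 0.01, optionally intersected with Δβ amplitude
   classes (>2 %, >5 %, >10 %).  Whole blood is a cell mixture, so cell-type
   proportions are first estimated per sample by non-negative least squares
   against reference leukocyte β profiles and rescaled to sum to one.

2. **How much of that variation is genetic?**  Every SNP within ±100 kb of a
   probe is tested in each population; the per-population effect estimates
   (β̂_s, se_s) enter a Wakefield approximate Bayes factor
   `ABF_s(W) = √(V_s/(V_s+W)) · exp(z_s²W / 2(V_s+W))`, and each
   *configuration* — the subset of populations in which the SNP is active —
   gets BF_c = Π_{s∈c} ABF_s averaged over a grid of prior effect variances
   W.  Genome-wide configuration weights w_c and the no-meQTL mass π0 are
   estimated by EM on `Σ log(π0 + (1−π0)Σ_c w_c BF_c)`; sites are called by
   Bayesian FDR (0.01), the reported SNP set is the smallest whose summed
   best-SNP posteriors reach 0.85, and an ANOVA
   `M ~ population + genotype + population×genotype` separates
   frequency-driven meQTLs from G×G/G×E interactions.

3. **Are the underlying variants under selection?**  Per SNP:
   Weir–Cockerham F_ST; the locus-specific branch length
   LSBL_A = (F_AB + F_AC − F_BC)/2; and iHS = ln(iHH_A/iHH_D), the log ratio
   of integrated extended-haplotype-homozygosity areas for ancestral- and
   derived-allele carriers, standardized within derived-allele-frequency
   bins of width 0.025.  Enrichment of top-5 % scores among meQTL SNPs is
   tested with a Cochran–Mantel–Haenszel test stratified by DAF bins of
   width 0.1, against LD-pruned (r² > 0.8) background SNPs within 20-kb
   probe windows.  Gene-level annotation uses a probe-count-bias-weighted
   Wallenius test and probe-matched GWAS-catalog resampling.

Real cohorts of this kind are controlled-access, so the package ships a
first-class simulator (`popepimeth.simulate`): Balding–Nichols allele
frequencies, founder-copying mosaic haplotypes with LD and optional sweeps,
and additive M-scale methylomes with population/habitat/meQTL/age/sex/cell
effects — all with recorded ground truth for calibration.

## Worked example

```python
import popepimeth as pm
from popepimeth.methio import filter_probes, estimate_cell_proportions, adjust_mvalues

design = pm.demo_design(seed=3, n_probes=1000, n_snps=4000, n_per_pop=60)
cohort = pm.simulate_cohort(design)

filtered, report = filter_probes(cohort.methyl, cohort.probe_annot)
panel_probes = cohort.probe_annot.index[cohort.probe_annot["cell_predictor"]]
props, _ = estimate_cell_proportions(cohort.methyl.subset_probes(panel_probes), cohort.panel)
cov = cohort.metadata.join(props)
terms = ["sex", "age"] + list(cohort.panel.cell_types)[:-1]

dm = pm.DifferentialMethylation(filtered, cov, ("population", "wRHG", "wAGR"), terms).fit()
print(dm.summary())

adjusted = adjust_mvalues(filtered, cov, terms)
scan = pm.CisMeqtlScan(adjusted, cohort.dosages, cohort.snp_annot,
                       cohort.probe_annot.loc[adjusted.probes], cov, covariate_terms=terms)
print(scan.fit().summary())
```

prints

```
Differential methylation (moderated t)
  comparison        : wRHG-vs-wAGR
  probes tested     : 980
  prior df d0       : 616
  prior variance s0²: 0.09281
  q threshold       : 0.01
  |Δβ| threshold    : 0.0
  DMS called        : 203

cis-meQTL scan (configuration Bayesian model averaging)
  SNPs after MAF filter : 3767
  cis pairs             : 14976
  sites tested          : 980
  pi0 (no-meQTL mass)   : 0.987
  sites called          : 47
  top configuration weights:
    wRHG+wAGR+fAGR           0.811
    wRHG                     0.124
    wAGR+fAGR                0.064
```

The 203 DMS are dominated by the planted population and habitat effects (the
simulator planted 150, plus meQTL-carrying probes whose allele frequencies
differ between groups); the meQTL scan calls 47 sites with most weight on
the all-population configuration, mirroring the planted mixture of shared
and population-specific effects.  The full pipeline — including selection
scans and enrichment — runs from a single entry point:

```bash
popepimeth run --out results_demo --seed 1
```

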