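# Methods

This note records the models implemented in `popepimeth`, their
assumptions, the defaults that matter, and the choices made where the
design was genuinely open.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Methylation scales and preprocessing

Methylation is carried as M-values, M = log2(β/(1−β)), the scale on which
array noise is closest to homoscedastic; β = 2^M/(2^M+1) is the exact
inverse and the two views round-trip to better than 1e−12.  β values of
exactly 0 or 1 are rejected (infinite M) rather than clipped.

Probe filtering removes, in order: probes flagged as cross-hybridizing,
probes on sex chromosomes, probes whose CpG or body carries a SNP at
frequency above 1 % in any study population, and the probes used as
cell-composition predictors.  The filter is idempotent and reports
per-rule counts.

Cell composition is estimated per sample by non-negative least squares of
the sample's β values against reference leukocyte profiles (granulocytes,
monocytes, B, CD4⁺ T, CD8⁺ T, NK), then rescaled to sum to one.  NNLS
makes negative coefficients impossible by construction; rescaling matches
the convention of reference-based blood deconvolution.  Covariate
adjustment residualizes M on sex, age and cell proportions (one proportion
dropped — they sum to one) while keeping each probe's intercept; the design
factor of interest is never residualized, so group contrasts stay unbiased.

## Differential methylation

Per probe, OLS of M on the two-group contrast plus nuisance covariates
gives (ΔM, s², d).  The variance prior s² ~ s0²·χ²_{d0}/d0 is fitted by
moment matching on log s²: e = log s² − ψ(d/2) + log(d/2) has mean
log s0² + ψ(d0/2) − log(d0/2) and excess variance ψ′(d0/2); the trigamma
equation is solved by Newton iteration, and a non-positive excess variance
means a degenerate prior (d0 = ∞, every posterior variance equal to s0²).
The moderated t uses d0 + d degrees of freedom (normal when d0 = ∞).  Two
documented limits are exact: d0 = 0 reproduces the ordinary t, d0 = ∞ a
pooled-variance z.  Calling is BH q < 0.01 over all tested probes,
optionally intersected with |Δβ| amplitude classes computed on β means
(the inference itself always runs on M).

**Overlap nulls.**  Methylation is spatially correlated over roughly 2 kb,
so the null for the overlap of two DMS sets resamples *patterns*, not
probes: the observed set's rank gaps along the position-sorted probe
universe are kept and the whole pattern is shifted by a circular offset
(rotation resampling).  Rank gaps rather than bp gaps are the default
because every rotation is then a valid probe set of identical size and
spacing; a bp-preserving variant (``unit="bp"``) is available but must
snap shifted positions onto existing probes, which can merge set members
where the array is sparse.  Empirical p-values use
the +1/(n+1) pseudocount, or exact enumeration over all offsets when
requested.  Because the overlap statistic is integer-valued, the reported
p is discrete and conservative (it includes tie mass); calibration tests
therefore check uniformity of the tie-corrected mid-p and
non-anti-conservativeness of the reported p.

## cis-meQTL mapping

Pairs are all probe–SNP combinations within ±100 kb on the same chromosome
(a 200-kb window centred on the probe, boundaries inclusive).  SNPs must
reach minor-allele frequency ≥ 0.10 in at least one population.  Within
each population, covariates (sex, age, cell proportions, first genotype
principal component) are projected out of both M and dosage once
(Frisch–Waugh), so each pair's slope and standard error come from simple
cross-products with n − k − 1 residual degrees of freedom.

Each configuration c (nonempty subset of populations) gets a Bayes factor
BF_c = grid-average over W of Π_{s∈c} ABF_s(W), the Wakefield approximate
Bayes factor with an independent N(0, W) effect prior per active
population; inactive populations contribute a factor of one.  The default
W grid is sd ∈ {0.1, 0.2, 0.4, 0.8} on the M scale.  Grid points far below
the sampling variance of the effect estimates were deliberately excluded:
with W ≲ V the "alternative" is numerically indistinguishable from the
null, the (π0, w) mixture loses identifiability, and the EM drains π0 into
near-null configuration mass.  The grid is a config parameter for users
whose effect scales differ.

π0 and the configuration weights are estimated jointly by EM on the
marginal likelihood; the log-likelihood is asserted non-decreasing and the
all-BFs-equal case is flagged degenerate rather than "solved".  A
conservative alternative π0 (fraction of pairs whose best configuration BF
is below 1) is available behind `pi0_method="conservative"`.

Site-level calling averages the configuration-averaged BFs over the site's
cis SNPs (uniform prior over SNPs), converts to a posterior null
probability, and walks sites in increasing posterior null while the
running mean stays at or below the FDR target (0.01).  The reported SNP
set is the smallest whose summed best-SNP posteriors reach 0.85.  When the
best SNPs disagree on configuration, two distinct configurations are
resolved in favour of the highest-posterior SNP; more than two drop the
site with a logged reason.  Known limitation: with modest signals
(per-population z ≈ 3), two-population configurations are sometimes
absorbed by the all-population configuration — the union configuration's
BF differs from the subset's only by one weak ABF factor, and the learned
weights amplify the imbalance.  Shared versus single-population
configurations separate cleanly at the same signal strength.

Interaction classification fits `M ~ C(pop) + g + C(pop):g` per called
site (type-II sums of squares, so imbalanced or empty dosage cells are
handled), BH-adjusts the interaction p across sites, and labels sites
G×G/G×E below 0.01, frequency-driven otherwise.  Variance explained is the
per-population R² of the dosage-only regression.

## Selection statistics

F_ST is the Weir–Cockerham variance-components estimator θ = a/(a+b+c)
with observed heterozygosity entering the within-population component;
negative estimates are retained and monomorphic-in-both SNPs are missing.
LSBL distributes the three pairwise F_ST values among branches,
LSBL_A = (F_AB + F_AC − F_BC)/2, so LSBL_A + LSBL_B = F_AB identically.

EHH at distance x is the probability that two random carrier haplotypes of
the core allele are identical at every SNP from the core to x; it is
computed by incremental partition refinement and is non-increasing by
construction.  iHH integrates EHH over physical distance (trapezoid rule)
outward in both directions, truncated at the first point where EHH drops
below 0.05; SNPs whose curve never reaches the cutoff before the
chromosome end, or that would integrate across a gap larger than 200 kb,
are skipped with a reason.  Unstandardized iHS = ln(iHH_A/iHH_D) is
standardized within derived-allele-frequency bins of width 0.025
(left-closed, last bin closed, n−1 denominator; bins with fewer than two
scores yield missing values).  Physical rather than genetic distance is
used throughout — the simulator has a uniform recombination landscape, so
the distinction is immaterial here; real-data users should note it.

LD pruning is the plink-style sliding window (50 SNPs, step 5, r² > 0.8),
removing the later-positioned SNP of any correlated pair — a fixed,
deterministic rule.  Top-tail flags mark scores at or above the empirical
95th percentile of non-missing values; ties at the quantile are all
flagged.

## Enrichment statistics

The 2×2 odds ratio uses in-region/out-of-region margins with
Haldane–Anscombe +0.5 on zero cells and a 1-df Pearson chi-square p.  The
stratified test is Mantel–Haenszel for the common OR
(Robins–Breslow–Greenland standard error) with Cochran's variance
(denominator n³) for the chi-square statistic, so a single stratum reduces
*exactly* to the Pearson chi-square; strata with a zero margin are dropped
and counted.  DAF strata default to pooled-population derived allele
frequency in bins of 0.1.

The PWM affinity score is a logistic-occupancy surrogate: per window (both
strands), 1/(1 + exp(ΔE/λ)) with ΔE the log-odds deficit to the best
possible window and λ = 1, summed over windows; a site is high-affinity
above the per-motif 95th percentile.  Category over-representation models
the probe-count selection bias with isotonic regression of target
membership on probes-per-gene, converts each category's mean bias ratio
into Wallenius noncentral hypergeometric odds, and reduces exactly to the
central hypergeometric when the odds are one.  GWAS tests: gene-based
resampling draws null gene sets stratified by probes-per-gene decile bins;
SNP-based resampling prunes the meQTL set, expands each SNP with its
r² > 0.8 partners within 500 kb, and compares the hit proportion against
resampled probe-proximal independent SNP sets.  All resampling p-values
carry the +1/(n+1) pseudocount.

## The synthetic cohort generator

The generator emulates exactly the structure the analysis assumes:
Balding–Nichols per-population frequencies (Beta around an ancestral
frequency, divergence F per population — defaults 0.04 for the
hunter-gatherer group, 0.02 for the farmer groups, of the order of the
genome-wide differentiation such cohorts show); founder-copying mosaic
haplotypes (12 founders, switch rate ρ = 1e−5 per bp, giving LD that
decays over tens of kb); hard-sweep injection by copying one haplotype
across a span in a carrier fraction; and additive M-scale methylomes with
probe baselines drawn from a bimodal mixture, sparse age/sex/cell
coefficients, planted group effects, planted per-dosage meQTL effects
active only in configured populations, and N(0, 0.3²) noise — 0.3 being a
typical residual M-value spread on blood arrays.  Cell-panel probes are
instead mixtures of the reference profiles (Dirichlet cell fractions
centred on whole-blood composition, concentration 60) plus β-scale noise.
Coordinates are 1-based inclusive internally; BED output converts to
0-based half-open.  One root seed feeds labelled independent streams, so
any stage can be replayed in isolation and identical designs are
bit-identical.

The demo design (5,000 probes, 20,000 SNPs, three populations of 60)
plants meQTLs at 8 % of probes with per-population variance explained
0.20 and DMS at 3 % of probes with ΔM 0.4–0.5 — prevalences and effect
sizes of the order blood-methylome studies report for clear cis-genetic
and between-group differences.  These sizes keep the full pipeline within
minutes on one CPU; they are the package's chosen study conditions, fixed
in `demo_design` and overridable per call.

What the simulator does *not* emulate — and hence what green tests do not
establish about real data: array chemistry and normalization artefacts,
batch effects, cell-type misspecification (the deconvolution panel is the
true generating panel), coalescent genealogies (the mosaic model gives
plausible but not demographically calibrated haplotype structure), and
genuine functional annotation (tracks, gene sets, PWMs and the GWAS
catalog are random).  Calibration and recovery results transfer to real
data only insofar as the additive covariate model holds there.

## Numerical conventions

Degenerate inputs are reported, not patched: zero-variance dosages mark a
population unusable for a pair; zero-spread or singleton DAF bins yield
missing standardized iHS; all-degenerate CMH strata return an undefined
result; empty targets return undefined odds ratios with a note.  Residual
variances of exactly zero in the moderation step gain an epsilon (1e−12)
with a warning.  EM convergence is a log-likelihood increase below 1e−6
with a 1000-iteration cap and a warning on non-convergence.  Ties in
tail-flagging and LD pruning resolve deterministically (all ties flagged;
later SNP removed).  Empirical p-values are never zero.
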