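# Methods

`panelgs` re-implements, end to end, the analysis chain used in genomic
prediction studies of structured inbred crop panels: genotype QC and
imputation of GBS markers, population structure, REML mixed models for
lattice field trials, whole-genome regression with cross-validation, marker
density experiments, and GO-term enrichment of marker-predicted effects.
Because panels of this kind are rarely deposited, the package includes a
synthetic-data generator that reproduces the statistical structure every
stage assumes, so the full pipeline runs and is tested offline.

## The synthetic panel

**Genotypes.** The panel is two sub-panels of inbred lines (default 100
each).  For each sub-panel, marker allele frequencies are drawn from a
Balding–Nichols model: given an ancestral frequency *p* ~ U(0.1, 0.9) and a
divergence parameter *F*st, the sub-panel frequency is Beta(*p*(1−*F*)/*F*,
(1−*p*)(1−*F*)/*F*).  Each sub-panel then gets a pool of founder haplotypes
(default 4) sampled at those frequencies, and every line is a founder mosaic:
within each chromosome the donor haplotype switches at Poisson-distributed
points (default 0.5 expected crossovers per chromosome).  Lines are fully
homozygous (inbred).  With zero divergence the sub-panels share a single
founder pool, making lines exchangeable.

The founder-pool size and switch rate are the levers controlling linkage
disequilibrium and relatedness.  The defaults are deliberately narrow/long:
panels of this kind show massive marker redundancy (windowed LD pruning at
r² > 0.2 typically discards ~90% of GBS SNPs) and within-panel predictive
abilities of 0.8+, both of which require long shared haplotype blocks.  At
desk scale (2,000 markers over 10 chromosomes of 60 Mbp) the defaults
reproduce that regime: pruning removes roughly half the markers, masked-call
imputation recovers >95% of genotypes, and noiseless cross-validated
prediction reaches ~0.97.  Real LD decay is not calibrated to any specific
panel — no quantitative decay target exists for it — so the mosaic's switch
rate should be treated as a free parameter.

**GBS corruption.** Per-marker missing rates are Beta(1.2, ·) with
configurable mean (default 0.346), giving the right-skewed profile typical of
GBS (median below mean).  Heterozygous-call artifacts are concentrated: a
small subset of markers (default 2%) receives het rates in [0.5, 0.95] —
mimicking spurious polymorphisms from duplicated regions — while the
background rate is set so the pooled het fraction matches the configured
mean (default 0.042).

**Annotation.** Non-overlapping gene intervals cover a configurable fraction
of the genome (default 0.30, mean length 3 kbp, log-normal).  Each gene
carries 1 + Poisson(2.3) GO terms (≤ 40), sampled with Zipf-like popularity
weights (exponent 1.2), producing the long-tailed cluster-size distribution
seen in real gene→GO maps (singletons up to clusters covering a substantial
share of all genic SNPs; mean terms per gene ≈ 3.3, median 3).

**Trait architecture.** A configurable number of QTL (default 400 of 2,000)
receive additive effects, Gaussian or sign-randomized Gamma.  Markers inside
genes annotated with a "planted" GO term have |effect| multiplied by a
configured factor — ground truth for validating the enrichment stage.  True
breeding values are exactly the −1/+1 dosage × effect product.

**Field trials.** Observations follow the standard multi-environment model

    y = μ + β·stand + γ·flowering + year + rep(year) + block(rep, year)
        + g + (g×year) + ε

on a resolvable 10×10 lattice (blocks nested in replicates, lines
re-randomized to blocks per replicate), three replicates, one or two years.
Crop stand is a truncated Poisson count; days to flowering is a line-level
covariate genetically correlated with the trait (default r = 0.4), so the
flowering adjustment in the analysis model is non-trivial — exactly as in
field practice, where the covariate deliberately absorbs flowering-related
genetic variation.  Default variance components (σg², σga², σrep², σblock²,
σe²) = (4, 1, 0.5, 0.5, 3) imply an entry-mean h² of 0.8 for a 2-year,
3-replicate trial, in the range of well-measured biomass traits.

What the generator does **not** emulate: sequencing reads, pedigree/selfing
structure, dominance or epistasis, spatial field trends beyond the block
term, LD decay calibrated to a reference panel, and GO-graph structure
(terms are independent labels).  Passing tests therefore demonstrate the
correctness and statistical behaviour of the analysis machinery under a
faithful but idealized panel, not performance guarantees on any particular
real data set.

## Genotype QC

Marker statistics (het fraction, missing fraction, MAF) are computed over
called genotypes only; markers with zero calls are flagged rather than
failing.  Markers above a heterozygosity threshold (default 0.10) are
removed, and surviving het calls are set to missing before imputation —
in a selfing diploid, residual hets at retained loci are treated as no-calls
rather than trusted genotypes (both the threshold and this behaviour are
exposed as options, since practice varies).

Imputation is window nearest-neighbour: for a missing call, the donor is the
line with the fewest mismatches over the mutually observed entries among the
W markers centred on the target (windows never span chromosomes).  Ties
break by majority call among tied donors, then by the panel-wide major
allele — deterministic given input order.  W is chosen from a candidate list
({5, 11, 21} by default) by self-masking cross-validation: 10% of observed
calls are masked and the W with the best recovery wins.  Observed calls are
never altered.

After imputation, markers with MAF **strictly below** 0.05 are removed
(a marker at exactly the threshold is kept), and genotypes are recoded
homozygous-reference → +1, homozygous-alternate → −1.  The orientation is a
fixed convention; flipping it flips the sign of all marker effects.

## Population structure

LD pruning is a greedy keep-first scan per chromosome: a marker is kept iff
its r² with every already-kept marker within 2 Mbp upstream is ≤ 0.20.
Keep-first makes the result deterministic and idempotent.  PCA is SVD of the
column-centred matrix, with per-component signs fixed by making the
largest-|loading| entry positive.  The Evanno ΔK summary consumes an
externally produced runs × K table of admixture log-likelihoods:
ΔK(K) = |m(K+1) − 2m(K) + m(K−1)| / s(K) with across-run mean and sample sd
(the Structure-Harvester convention); K values with zero sd are excluded
from the argmax.  The admixture MCMC itself is out of scope.

## Trial mixed models

Random terms (replicate, block, genotype) accept ID, DIAG, CS or US
structures over the year grouping; the residual accepts ID or DIAG.  CS is
parameterized as a main effect plus an independent level×year interaction —
for genotype these are σg² and σga², and the main-effect BLUP is the
across-year breeding value directly.  CS and US require ≥ 2 years: with one
year the main and interaction incidences coincide and the split is
unidentifiable, so the fit raises rather than returning an arbitrary
decomposition.

The restricted likelihood is maximized over transformed parameters (log
standard deviations; Cholesky factors for US) with L-BFGS-B plus an optional
Nelder-Mead polish (`polish=True`, used where closed-form accuracy matters;
the polish costs several times the quasi-Newton phase).  Fixed effects come
from GLS at the optimum, BLUPs from the mixed-model equations.  Fits are
validated against the balanced one-way ANOVA closed form (agreement ~1e-7)
and against lme4 on unbalanced two-year data (agreement to 4+ significant
digits on all components).  Non-convergence is flagged on the result, never
silent.  A constant covariate column (e.g. uniform crop stand) is dropped
rather than allowed to destroy the rank of X.

BIC = −2·logREML + t·ln(n_obs) with t the number of variance parameters;
only BIC *ordering* across candidates with identical fixed effects is used,
so the sample-size convention is not critical (n_obs chosen; configurable in
principle by editing one line).  Ties go to fewer parameters.  Heritability
uses the two standard entry-mean formulas, multi-year
h² = σg²/(σg² + σga²/m + σe²/(nr·m)) and single-year
h² = σg²/(σg² + σe²/nr).

Under DIAG/US genotype structures there is one BLUP per genotype-year; the
per-genotype breeding value is their arithmetic mean, recorded in the
result's `blup_combination` field.  Combined multi-sub-panel BLUP vectors
are concatenated without rescaling.

## Whole-genome regression

RRBLUP (y = 1μ + Mα + e, α ~ N(0, σα²I)) is fitted by REML on the eigenbasis
of K = MM′, profiling the variance ratio λ = σe²/σα² with a bounded scalar
search (log λ ∈ [−12, 12]); effects are α̂ = M′(K + λI)⁻¹(y − 1μ̂).  This is
algebraically identical to GBLUP with kernel MM′ and the same components,
which the tests verify to < 1e−8.  A constant response is a boundary case:
zero effects, flagged.

The Bayesian alphabet runs through one single-site Gibbs kernel (numba) with
residual updating, O(np) per sweep.  Priors: Bayes RR — common marker
variance, scaled-inv-χ²; Bayes A — per-marker scaled-inv-χ²(ν, S); Bayes B —
spike at zero with probability π plus the Bayes A slab; Bayes Cπ — spike
plus common-variance Gaussian slab; Bayesian Lasso — α|τ² ~ N(0, τ²σe²),
τ² ~ Exp(λ²/2), λ² ~ Gamma.  π is the spike (exactly-zero) probability,
sampled with a Beta(p₀π₀, p₀(1−π₀)) prior (π₀ = 0.5, p₀ = 10) unless fixed;
fixing π = 0 reduces Bayes B to Bayes A (used as an internal consistency
check), π = 1 kills all effects.  Default hyperparameters follow the common
rule of thumb: prior scales set so the implied marker-variance mass equals
half the phenotypic variance (R² = 0.5), ν = 5 for the scaled-t slabs, and a
Gamma(1.1, rate) prior on the Lasso λ² with the rate matched to the data.
All are overridable.  Chains are deterministic given the seed; default
length 40,000 with 20,000 burn-in (tests and desk-scale analyses use shorter
chains, whose posterior means are already stable for these data sizes).
Thinning defaults to 1 — posterior means are unaffected by thinning, only
storage.

## Evaluation

Predictive ability is the Pearson correlation between GEBVs and
phenotype-derived breeding values of held-out lines.  The headline CV number
is the mean of per-fold correlations; the pooled correlation over all
out-of-fold predictions is reported alongside (they agree within 0.05 on
balanced simulations).  Folds are seeded balanced partitions (200 lines →
10 folds of 20).  Across-set prediction guards against train/test line
overlap unless the across-year same-genotype scenario explicitly allows it.

The density experiments halve the marker count with ceiling rounding down to
the last level ≥ 16.  Random thinning draws 10 independent subsets per level
(the full-density level is a single deterministic draw, so it equals plain
CV exactly); one fold assignment is re-used across all levels.  Effect-guided
thinning ranks |α̂| *within each training fold* and keeps the top half
(ties by marker order), so marker selection never sees test data and marker
sets are nested across levels within a fold.

## Enrichment

Each SNP inside a gene (1-based inclusive endpoints; GFF3 and VCF agree on
coordinates, so no conversion is applied) inherits all the gene's GO terms;
SNPs in overlapping genes get the union.  Lookup is by interval tree, not a
genes × SNPs scan.  The SNPs matching a term form its cluster; the test
compares |effects| in the cluster against |effects| of **all** remaining
markers, genic or not, with a one-sided two-sample KS statistic
D = sup[F_rest − F_cluster] clipped at 0 (cluster stochastically larger),
evaluated on right-continuous ECDFs at the pooled points.  The p value is
the one-sided large-sample bound exp(−2D²mn/(m+n)); for tiny clusters
(min(m, n) ≤ 10 and ≤ 1e5 splits) an exact enumeration over all splits of
the pooled sample replaces it, and a Monte-Carlo permutation option exists
for diagnostics.  The exponential bound lacks a finite-sample correction and
can deviate from the permutation p by ~0.05 in the high-p region at n ≈ 50;
it is accurate where the significance decisions happen.  BH step-up FDR is
applied across all tested terms; adjusted p < 0.01 flags significance.  GO
terms are not propagated up the ontology graph — a SNP carries exactly the
terms annotated to its genes.

Power at desk scale: the planted-enrichment signal is clearly present in
the architecture's true effects (the x5 term reaches adjusted p < 1e-3 on
the default panel), but effects *re-estimated* from field-trial BLUPs are
attenuated — roughly in proportion to the response's accuracy — and at
~1,500 markers the KS statistic for the planted cluster then falls below
the 0.01 threshold.  The enrichment machinery's error control and power are
therefore validated on directly simulated effect vectors (200 null
replicates; 20 planted replicates), while the full-pipeline run reports the
attenuated result honestly.  With the marker counts of a real GBS panel
(10^5-10^6 SNPs, clusters of thousands), the same D values would be
overwhelmingly significant, which is why this design detects enrichment in
practice while the desk-scale pipeline does not.

## Numerical and design notes

* Degenerate inputs raise informative errors rather than returning NaNs:
  all-missing marker columns in imputation, empty KS samples, a GO cluster
  covering every marker (empty complement), single-run ΔK tables, CS/US
  with one year.
* The QC pipeline order (raw → imputed → final) is a state machine on the
  genotype container; out-of-order calls raise.
* Parameter-recovery experiments in the test suite switch the flowering
  covariate's effect off: with the default genetically correlated covariate,
  adjusting for flowering absorbs genetic variance (by design), which is the
  field rationale for the adjustment but confounds a recovery experiment.
* With 100 lines × 2 years, the cross-year covariance that separates σg²
  from σga² has a sampling SE of ~0.36 at (σg², σga², σe²) = (2, 1, 3), so
  "every component within 50% relative error" holds in roughly three
  quarters of replicates, not almost always; the tests assert the level the
  statistics supports (validated against lme4).
* Problem sizes in tests and the acceptance script (2,000 markers, 200
  lines, chains of 2,000–5,000 iterations) were chosen as the smallest sizes
  at which the checked properties are stable.
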