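# Methods

## Scope and model

The package implements a QTL-validation workflow for a maize MAGIC
population: simulate the breeding design and field trials, estimate
adjusted means and variance components, run a kinship-corrected GWAS on
each validation set, and decide per published QTL whether the new
evidence confirms it. Everything downstream of the simulator also works
on real HapMap/VCF genotypes and TSV phenotype tables.

## Synthetic MAGIC population

Founders are fully homozygous binary haplotypes, drawn independently per
locus and forced to be polymorphic across the founder set. RILs descend
through a balanced funnel (2-way → 4-way → 8-way crosses over a random
founder permutation per line) followed by single-seed descent.
Recombination uses the Haldane model: crossovers per chromosome per
meiosis are Poisson with mean equal to the map length in Morgans,
positions uniform on the genetic map, no interference — the simplest
model consistent with the absence of any stated alternative.

Defaults mirror the study design: 8 founders, 608 RILs, 6 selfing
generations (residual heterozygosity ≈ 0.5·(1/2)⁶ ≈ 0.8%), 10
chromosomes of 150 cM / 200 Mbp with constant cM/Mbp. The marker panel
is scaled down from the real 224k-SNP matrix (default 100 loci per
chromosome; the analysis drivers use 60) — LD decay, mosaic structure
and kinship behave correctly at this density while the whole pipeline
runs in seconds. Testers are unrelated homozygous haplotypes, since the
real tester is only characterized as an unrelated heterotic group;
hybrid dosages are RIL gamete + tester allele, with residual
heterozygous RIL loci transmitting a random allele.

Phenotypes: plot value = intercept + QTL effects (additive per
alternate-allele copy plus a dominance deviation for heterozygotes)
+ polygenic deviate + environment effect + G×E deviation + block effect
+ residual. The polygenic deviates of the two traits are drawn jointly
with a configurable genetic correlation (the drivers use −0.2, a mild
resistance/yield antagonism). `TraitSpec.vg` is the polygenic
*background* variance: planted QTLs add variance on top of it, so
simulated sets with planted QTLs show somewhat more genetic variance
than their preset. Presets carry the published variance components,
means and trial designs of the three sets (whole population, IVS, HVS);
one internal inconsistency of the source (printed Vg/Vp ratios that do
not match the printed components) is resolved in favour of the
components. Non-negative traits can be truncated at zero; truncation is
off by default because it biases variance-component recovery, and the
truncation rate is logged when enabled.

The generator reproduces the statistical structure the analysis assumes
— it does not model insect population dynamics, infestation
heterogeneity between plants, selection during line development, or
marker ascertainment. Passing tests therefore demonstrate correctness of
the estimators under the assumed model, not robustness to those
real-data features.

## Field-trial analysis

A dense multi-component REML engine (`magicqtl.reml`) fits
y = Xβ + Σ_k Z_k u_k + ε with independent variance components by
average-information steps with an active set at the zero boundary,
step-halving, and an EM fallback; convergence is |Δ log-likelihood| <
1e-8 within 200 iterations, and non-convergence raises an error carrying
the likelihood trace. Component standard errors come from the inverse AI
matrix at the optimum; negative solutions are floored at zero. The
engine is cross-checked against lme4 on a small fixture in the test
suite.

BLUEs use genotype as fixed (cell-means coding) with environment,
replicate-within-environment and block random; design factors whose
partition duplicates a coarser one are dropped to keep REML
identifiable, and on a complete single-environment, single-replicate
layout the estimator reduces exactly to raw means. Genotypes without any
record are reported as missing, never silently dropped. Variance
components use an intercept-only fixed part with genotype, environment,
G×E, replicate and block random; only Vg, V g×e and Vres are reported
(design factors are nuisance). A component is called significant when it
exceeds twice its standard error.

Family-mean heritability is h² = Vg / (Vg + Vg×e/e + Vres/(e·r)); *e*
counts environments actually phenotyped for the trait — tunnel length
exists only where borers do, so protected trials count for yield but not
for tunnel length (IVS tunnel: e=2, r=2; HVS tunnel: e=4, r=2). The SE
uses the delta method with the REML component covariance when available.
With all components zero, h² is reported as undefined rather than 0/0.

## GWAS

Kinship is the centered VanRaden matrix over mean-imputed dosages,
ridge-shifted to PSD if needed. The kinship actually used by the
original Tassel analysis is unreported; the common default was chosen,
and numerical p-value equality with the source is explicitly not a goal.
The null model is fitted by spectral decomposition of K with a 1-D REML
profile over σ²_g/σ²_e (coarse grid then bounded refinement), the full
restricted likelihood including the log|X'V⁻¹X| term. Scans hold these
components fixed (P3D) and test each SNP's additive dosage term by GLS
Wald F with n−2 denominator degrees of freedom. Compression (grouping of
individuals) is not implemented: no group count was reported, and with
compression off the model is the standard MLM that the P3D contract
describes. MAF filter 0.05 by default; filtered SNPs are returned in a
separate list, never silently omitted. At σ²_g = 0 the scan is exactly
the OLS F-test, which the tests verify to 1e-10.

## LD and validation

r² is the squared Pearson correlation of dosage vectors with pairwise
exclusion of missing calls (composite LD — well defined in hybrids where
phase is unknown, identical to haplotype r² on homozygous RILs, verified
against a haplotype-frequency oracle). Monomorphic pairs are undefined,
rendered "No" in reports, and fail the LD criterion.

The validation rule is applied strictly as stated: same SNP at
p < 0.02 (criterion 1, checked first), else a window SNP within
±2 Mbp inclusive with p < 0.02 and r² > 0.2 (strict inequalities).
Among fully qualifying window SNPs the candidate is chosen by smallest
p, then smallest distance, then position — the source does not specify
this tie-break. When no window SNP passes the LD test, the best
sub-threshold-p candidate is still reported as evidence with
`validated = False`. Multi-SNP QTLs validate if any member does, as
implied by the one-decision-per-QTL-block layout of the source tables.
Policy thresholds are user-adjustable, and decisions are monotone in all
three (property-tested): relaxing a threshold can never invalidate.

The bundled published cross-reference tables follow their column
contents rather than their captions (two captions are swapped in the
source), and distances are stored verbatim with thousands separators;
one printed distance cell disagrees with its own SNP identifiers by
1,668 bp and is excluded from the exact-distance check. Several narrated
validations in the source exceed the stated 2-Mbp window; this package
follows the stated rule, so its QTL-level counts (e.g. tunnel length
8/21 IVS, 10/21 HVS, 6 in both) are the strict-rule reference, not the
narrated headlines. Users can widen the window via the policy to explore
the narrated intervals.

Tail selection grows a symmetric rank k over both tails of both trait
distributions until the union reaches the target size, trimming the last
batch by extremity and breaking ties lexicographically — deterministic
given the BLUEs. The source states only that extremes of both
distributions were taken.

## Numerical choices and problem sizes

SNP positions are treated as opaque 1-based coordinates (no assembly
handling). Dosages are alternate-allele counts in {0,1,2} with a missing
code; RIL matrices warn above 5% heterozygous calls. Test and driver
simulations use 56–360 lines and 180–1000 markers — sizes chosen so the
full suite and the drivers complete in minutes while leaving every
estimator in its intended regime (the variance-recovery experiment uses
exactly the study's 64-genotype, 2-environment × 2-replicate layout).

## Known limitations

Single-stage BLUE estimation (not the two-stage lattice adjustment some
field programs use); no spatial row-column modelling; no multi-locus or
dominance-term GWAS; no haplotype phasing or D′; column-mean imputation
only. The whole-population heritabilities of the source (0.24, 0.46)
originate from a different, earlier experimental design and are not
reproducible from the published components with any integer (e, r); they
are carried in no computation here.
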