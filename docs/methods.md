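# Methods

`triadqtl` re-implements, as a tested pipeline, an integrative
systems-genetics analysis of meat-quality traits in a divergent-breed F2
pig cross: quantitative trait transcript (QTT) scanning, mixed-model eQTL
mapping with cis/trans classification, weighted co-expression network
analysis, and GWAS–eQTL–QTT "triad" colocalization for candidate-gene
nomination. Because no real dataset ships with the package, a synthetic
F2-cross generator with a fully recorded planted truth provides the data
for every benchmark; this note records the models, the defaults and why
they were chosen, and what the synthetic benchmarks do and do not show.

## The synthetic F2 cross

**Design.** Three generations: a few founder sires from line A and founder
dams from line B (defaults 2 and 17), an F1 generation (9 boars, 59 sows),
and `n_f2` F2 animals (default 500) produced from recorded boar × sow
matings grouped into 6 batches, with random sex. This mirrors the shape of
a classical F2 resource population.

**Genomes and meiosis.** SNPs are evenly spaced on each chromosome.
A fraction of SNPs (`fixed_diff_fraction`, default 0.3) is fixed for
opposite alleles in the two founder lines; the rest draw line-specific
frequencies from Beta(0.5, 0.5), giving a mix of fully and partially
informative markers. Founder haplotypes are drawn i.i.d. per SNP (no
within-line LD). Gametes place crossovers by a Poisson process on the
genetic map at `recomb_rate_cm_per_mb` (default 1 cM/Mb, the Haldane
no-interference model); F2 chromosomes are therefore mosaics of
founder-line haplotypes with the long-range LD characteristic of an F2.

The default desk genome is 5 chromosomes × 100 Mb × 1,000 SNPs. For
benchmarks where megabase-scale localization matters (cis windows, QTL
regions, eQTL peak placement) the test suite instead uses a pig-like map:
18 autosomes × 128 Mb at 1 cM/Mb (≈2,300 cM, ~5,000 markers). Total map
length controls how concentrated the genomic relationship matrix is and
how far association peaks wander from the causal site; a 500 cM toy
genome makes both effects unrealistically severe, while the 2,300 cM map
matches the recombination content of the organism the design emulates.

**Kinship in an F2 is not outbred kinship.** At line-fixed SNPs every F1
parent is the same heterozygote, so full sibs receive independent
Mendelian draws there: those loci contribute nothing to sib covariance
while still entering the GRM denominator. Simulated full-sib genomic
kinship is therefore ≈0.17–0.19 (not the outbred 0.5), with cross-family
pairs near 0. The tests assert the verified values.

**Expression.** Per transcript, a latent log-expression is a weighted sum
of standardized components — planted cis/trans dosage effects, a module
latent factor, sex, and batch — with weights √share and Gaussian noise
carrying the remaining share, so every planted share equals that
component's fraction of latent variance up to sampling error. Latents are
exponentiated around a log-normal baseline (log-mean ln 50, sd 1.2;
latent scale 0.5) and each sample is rescaled to one million tags
(tag-count TPM). Batch effects and sex directions are drawn per
transcript: a shift common to all transcripts is a library-size factor
that TPM normalization removes exactly, and would make batch adjustment
vacuous. Column normalization also couples transcripts through the
per-sample total; the coupling is negligible only when the planted
transcripts are a small part of the transcriptome, so benchmark fixtures
always carry a background transcriptome (hundreds of unplanted
transcripts). Analyses run on log(TPM + 1).

**Traits.** Each configured trait mixes standardized components weighted
by √share: mediator log-expression, a direct-QTL dosage, a polygenic
deviate drawn from N(0, K) with K the *realized* genomic kinship (so
variance-component recovery is a clean test), sex, batch, and noise. In
addition the muscle chemistry block is always simulated — glucose,
glycogen, glucose-6-phosphate and lactate around published-scale means —
GP is derived from it through the phenotypes module, and pH at 24 h
post-mortem is generated as a decreasing function of GP plus noise with a
target correlation of −0.39, matching the sign and magnitude reported for
this trait pair.

**What the generator does not emulate.** Sequence-level reality (reads,
tags, alignment), within-breed LD, X-dosage compensation, non-Gaussian
expression noise, genotyping error, and realistic per-trait missingness
patterns (independent missingness rates are exposed instead). Passing the
benchmarks shows the pipeline recovers what it assumes — linear effects,
Gaussian noise, known batch structure — not that it is robust to
real-data violations of those assumptions.

## Quality control

SNPs pass with call rate ≥ 0.9, MAF ≥ 0.05 and Hardy–Weinberg
equilibrium p ≥ 1e-5; samples pass with call rate ≥ 0.9 and trio
Mendelian error rate ≤ 0.05. Boundaries are inclusive on the pass side
because the removal rules are strict inequalities. HWE uses the 1-df
chi-square of observed vs expected genotype counts — adequate at n in the
hundreds and exactly oracle-checkable — and is applied to all F2 samples
even though a cross segregates non-randomly at the family level; in this
design the expected F2 genotype frequencies are in fact Hardy–Weinberg
proportions at the mid-parent allele frequency, so the test is only
mildly miscalibrated by family correlation. Expression QC keeps
transcripts with TPM > 0 in ≥ 50% of samples (a configurable stand-in for
an unstated rule). Tag-count TPM is count / sample-total × 1e6, with no
transcript-length term.

## Mixed-model association (the shared scan engine)

For each trait or transcript y the polygenic model
y = Xβ + g + e, g ~ N(0, σ²_g K), e ~ N(0, σ²_e I) is fitted once by
REML, where X carries intercept, sex and batch dummies and
K = ZZ′ / Σ 2p_j(1−p_j) is the VanRaden genomic relationship matrix
(column-centered dosages, missing → column mean, + 1e-6 ridge). The fit
is a 1-D bounded search on h² ∈ [0, 0.999] after one spectral
decomposition of K (shared across all vectors on the same sample set),
with σ² profiled analytically; a grid oracle pins the optimum in tests.

Every SNP is then tested against the fitted V̂ = σ̂²_g K + σ̂²_e I with the
score statistic T = (g_c′V̂⁻¹r)² / (g_c′V̂⁻¹g_c), where r are the GLS
residuals and g_c is the dosage with X projected out under the V̂⁻¹ inner
product — the classical two-step ("mmscore") strategy: variance
components once per vector, a cheap test per SNP. Missing dosages drop
samples for that SNP (mean imputation would bias T).

**Finite-sample reference.** Because V̂ carries the REML scale
σ̂² = RSS/(n−p), T equals (n−p) times the squared partial correlation of
SNP and phenotype in the whitened model. The reported p maps T onto
F(1, n−p−1), which reproduces the exact fixed-variance GLS F test — and,
for K = I, the Pearson t test — rather than the asymptotic χ²₁, which is
visibly anticonservative in the tail at n ≈ 100. The two references agree
as n grows; the statistic itself is unchanged.

Two residualization modes are exposed: `gls` (default; the polygenic term
stays in the residual, as the score test requires) and
`ols-after-polygenic` (BLUP of the polygenic effect subtracted, an
environmental residual) — the wording of the source method is ambiguous
on this point, so both are available and tests pin the default.

**Known power limitation (proximal contamination).** The GRM contains the
tested SNP's own LD block, so V̂ absorbs part of a strong cis signal and
the two-step test loses noncentrality relative to an independence test —
the classic conservatism of GRAMMAR-family methods, exacerbated when the
total map is short. This, together with peak wander under F2 long-range
LD (a genome-wide peak can sit several Mb from the causal SNP even for an
ideal test), is why cis-classification recovery of 10%-variance effects
plateaus near 85–90% and why the benchmarks use the pig-length map.

## Scans, eQTLs, hotspots

GWAS on traits and eQTL mapping on transcripts share the engine above.
Per transcript, the peak SNP (minimum p; ties broken by genomic order for
determinism) is an eQTL if p < 2.08e-5 — the published threshold, kept as
a configurable constant because its Bonferroni denominator is not
derivable from stated counts. A peak is *cis* if it lies on the gene's
chromosome within [TSS − 2.5 Mb, gene end + 2.5 Mb] (inclusive, 1-based;
the interval is strand-independent because TSS and gene end swap with
strand), else *trans*. Per-eSNP distinct-gene counts give the pleiotropy
summary; an eSNP with ≥ 2 genes is a hotspot.

## QTT analysis

Adjusted expression × adjusted trait Pearson correlations on
pairwise-complete samples, two-sided p from t with n−2 df; a transcript
is a QTT for a trait at p < 5e-4. Summaries: transcripts significant for
≥ 2 traits; (transcript, trait) pairs shared between tissues with a
sign-agreement flag (discordant signs are reported, not dropped); and
per-trait-group distinct-QTT counts (a transcript significant for two pH
traits counts once in the pH group).

## Co-expression network

Unsigned weighted network: a_ij = |r_ij|^β. The soft power is chosen by
the scale-free topology criterion — bin log10 k into 10 equal-width bins,
regress log10(frequency) on log10(mean k), report R² (0 if the slope is
positive), choose the smallest β with R² ≥ 0.85, falling back to the
argmax. The adjacency maps to the standard unsigned topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij) (diag 1),
pinned by a triple-loop oracle. Modules come from average-linkage
clustering of 1 − TOM with a static height cut and minimum size 30;
clusters below the minimum become label 0, survivors are renumbered by
decreasing size. The default cut height is 0.95: at 0.99 the
between-module dissimilarities (≈0.98–0.999 on realistic inputs) merge
everything into one cluster, so 0.99 is not a usable default; the
parameter remains exposed. A static cut is used instead of dynamic hybrid
tree cutting to keep the procedure deterministic and dependency-free —
it recovers well-separated modules exactly but will not split nested or
tightly adjacent modules the way dynamic cutting can.

Module eigengenes are the first principal component of the z-scored
member submatrix, sign-aligned to correlate positively with members on
average. Module–trait significance uses the reciprocal-product threshold
α = 1/(N_modules × N_traits) as published (a conventional Bonferroni can
be passed instead). Connectivity k is the adjacency row sum (diag 0),
K_in its within-module restriction; hubs are the top decile of K_in; the
module edge export returns the strongest within-module pairs by |r|
(ties lexicographic).

## Triad integration

QTL regions are ±2.5 Mb windows around retained GWAS peaks —
per-chromosome peaks below a suggestive threshold (default 1e-4, chosen
to admit peaks of the magnitude the source analysis treated as regions;
no cutoff is stated) — clamped to chromosome bounds, with overlapping
same-trait regions merged (stronger peak kept). Within a region,
significant QTTs for the region's trait whose gene overlaps it
(any-overlap) are screened; a candidate is accepted if it has a
significant cis-eQTL whose peak SNP is the GWAS peak SNP exactly
(tier *shared-peak*) or lies inside the region (tier *region-overlap*).
Shared-peak requires SNP identity, matching the exemplar logic of the
source analysis; an LD-based relaxation was considered and left out of
the default path. Sign consistency multiplies sign(QTT r) × sign(eQTL
effect) × sign(GWAS effect): under pure expression mediation the product
is positive. Candidates are ranked by (tier, cis-eQTL p, |QTT r|).

## Benchmark problem sizes

The verification suite uses: n = 500 F2s on the pig-length map for
planted-eQTL recovery (50 cis effects at 10% variance plus a 10-target
trans hub over a ~400-transcript background) and for heritability
recovery (50 REML fits at true h² = 0.5); 100,000 null transcript–trait
pairs for QTT calibration and 5,000 null SNPs under a h² = 0.5 polygenic
null for genomic-inflation control (λ ∈ [0.9, 1.1] with kinship, λ ≫ 1.1
without); 20 replicates of five planted modules (sizes 40–80, factor
share 0.4) for module recovery; and 50 mediation-vs-decoy replicates
(n = 400, sparse 150-SNP map so that peak identity is well defined) for
the end-to-end triad benchmark. Fixture genomes are chosen per benchmark:
structure-sensitive benchmarks get the realistic map, calibration
benchmarks the compact default.
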