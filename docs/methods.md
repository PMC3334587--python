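# Methods

## Model and estimation

The hierarchical model treats each gene independently given shared
parameters (λ, Π0). Its assumptions: at most one causal SNP (eQTN) per
gene; the candidate set is the cis-window (100 kb 5' of the TSS through
100 kb 3' of the TES, strand-aware, clipped at the chromosome start);
annotation effects are additive on the log-odds scale and shared across
genes; Π0 is a single scalar, not gene-specific. The gene likelihood is
evaluated relative to the no-eQTN model, `Π0 + (1−Π0) Σ_j π_j BF_j`, so
only Bayes factors — not raw expression likelihoods — enter the fit. The
per-SNP prior π is the softmax of `x_j = Σ_l λ_l δ_jl`, computed with
max-subtraction; it is invariant to adding a constant score to every SNP,
which also means a set of indicator columns that partitions the cis-window
(e.g. a full set of distance bins) carries one redundant direction — one
bin should be dropped as the reference when such a set is used.

Single-SNP Bayes factors use the conjugate linear model `y = μ + β g + ε`
with a flat prior on μ, reference prior p(σ²) ∝ 1/σ², and effect prior
β ~ N(0, w σ²) with w = σ_a². Integrating μ, β and σ² gives

    BF(w) = (1 + w S_gg)^(-1/2) (1 − w S_gy² / ((1 + w S_gg) S_yy))^(-(n-1)/2)

in centered second moments; BFs are averaged over a grid of σ_a (default
{0.1, 0.2, 0.4, 0.8}, equal weights — configurable, and analyses of
simulated data match the grid to the generating mixture). The phenotype is
standardized first, so the BF is invariant to affine rescaling and the
prior SDs live on the standardized scale. A constant dosage yields BF = 1.
Dominance terms are not modelled.

Fitting maximizes the summed log relative likelihood over (λ, logit Π0).
Two backends: EM (default — E-step computes each gene's posterior eQTN
weight and per-SNP allocation; M-step updates Π0 in closed form and solves
a weighted conditional-logit problem for λ with a quasi-Newton inner
optimizer) and direct bounded L-BFGS-B with the analytic gradient. λ is
capped at ±20: a cap hit signals separation (an annotation absorbing all
eQTN mass) and warns. Convergence is declared when the log-likelihood
changes by less than `tol` (default 1e-6). Confidence intervals are
profile-likelihood intervals against the χ²₁ cutoff, re-optimizing all
other parameters at each fixed λ_l; a profile that never drops below the
cutoff in one direction is reported as an unbounded (−∞ or +∞) endpoint,
which on the fold-enrichment scale becomes a lower bound of 0.

Model comparison uses AIC = 2k − 2 loglik (k = number of annotations + 1)
with differences above 2 flagged, and gene-level k-fold cross-validation:
parameters are fitted on training folds and the summed test-gene log
relative likelihood is evaluated with parameters frozen, so models of any
size are directly comparable on the test folds.

## Frequentist scan and FDR

The cis scan is per-SNP OLS of the normalized phenotype on additive
dosage (two-sided t, P floored at 1e-300; constant SNPs get P = 1 and a
flag). The gene-level FDR permutes the individual labels of the expression
matrix — one permutation applied jointly to all genes, preserving both
genotype LD and gene-gene expression correlation — and estimates
FDR(t) as the permutation-mean count of genes with best P ≤ t divided by
the observed count. The permutation null counts every gene, including
truly associated ones, so the estimator is conservative.

## Expression pipeline

Probe-SNP residualization regresses a probe's intensity on the dosage of
a SNP inside the probe and keeps the residual when the slope is
significant at α = 0.05 (when a probe overlaps several SNPs, the most
significant single SNP is used). Confounder PCs are computed on the
genes × individuals matrix after centering within each individual
(genes as observations); each of the first 30 PCs is kept iff its
variance-explained share exceeds its own permutation null (each gene's
values permuted across individuals; empirical P with the +1 correction,
P < 0.05). Covariate removal always removes population and sex (OLS);
the selected PCs, orthogonalized against that block, then compete in an
elastic net (mixing parameter grid 0.1–0.9 × a 50-point regularization
path) tuned by leave-one-out CV; a PC is "selected" for a gene when its
coefficient is nonzero. Residuals are mapped within each population to
standard-normal quantiles Φ⁻¹((rank − 0.5)/n) with mid-ranks for ties —
deterministic, symmetric, finite — so each gene's phenotype within a
population is exactly a permutation of a fixed score set. A gene counts
as expressed when its normalized read depth exceeds 1e-10 in strictly
more than half the individuals.

## Annotation designs

Indicator columns are half-open interval membership (δ = 1 iff
start ≤ pos < end after per-track merging). Background features are a
one-hot, strand-aware signed distance-to-TSS bin — default edges at ±1 kb,
±5 kb, ±20 kb, ±100 kb (8 bins), clamped into the outer bins so the bins
partition any window — plus in_exon / in_intron / downstream-of-TES
indicators. Core-promoter motifs (TATA box TATAAA, GC box CCCCGCCCCG,
BRE SSRCGCC, DPE RGWYV, and Inr as YYANWYY — the Inr consensus is not
uniquely standardized and is flagged as an assumption) are scanned as
IUPAC patterns on the sense strand within ±50 bp of the TSS, whole-match
inside the window. Hexamer overrepresentation compares pooled overlapping
hexamer counts in the core promoter against a control region (default
[−100, −50) bp 5' of the TSS) by one-sided binomial test, returning up to
1,000 words below P = 1e-10. The peak caller counts reads in 150-bp
windows stepped 1 bp, smooths with a Gaussian kernel (SD 50 bp), and sets
its threshold from Monte-Carlo placements of the same read count uniformly
on the genome so that the null per-window exceedance frequency is below
1e-6 (per-window, not family-wise); windows above threshold merge by
contiguity. Because smoothing correlates neighboring windows, null
exceedances arrive in rare clusters: most null datasets produce no call at
all, and the per-window rate is honored on average.

## Synthetic data

The generator emulates the study design the methods target: 210
individuals, ~1,200 cis SNPs per 100-kb-flank region, MAF ≥ 1% with a
1/f spectrum, one causal SNP per eQTL gene placed by the softmax prior at
the configured true λ (uniform when λ = 0), expression
`y = β·dosage + N(0, σ²)` with β from a mixture of normals (default SDs
{0.2, 0.4, 0.8}, equal weights, σ = 1 on the standardized scale), and
optional genotyping error that replaces hard calls with one of the other
two dosage classes (platform mix: 0.5% for half the SNPs, uniform 1–3%
for the rest). Haplotypes are latent Gaussian chains with exponential
(Ornstein-Uhlenbeck) autocorrelation exp(−d/ℓ), thresholded at the
allele-frequency quantile; the kernel's Markov property makes sampling
exact and O(M). The correlation length defaults to ℓ = 15 kb, chosen as a
realistic scale for human cis-region LD; `genotype_corr_from_latent`
gives the closed-form genotype correlation implied by the thresholding,
which the test suite checks empirically. What the generator does not
emulate: recombination hotspots and block structure, population
structure/admixture, allele-frequency–dependent LD, structural variants,
array probe artifacts. Passing tests therefore demonstrate correctness of
the estimators under a clean single-causal-variant generative model, not
robustness to every feature of real panel data.

## Numerical choices and degenerate inputs

Log-scale accumulation with segmented logsumexp throughout the
hierarchical likelihood; Π0 optimized on the logit scale within (±35);
P-values floored at 1e-300; BF prior shrink factor guarded against
frac → 1. Ties in rankings use mid-ranks; `prior_only_ranking` percentile
is rank/M, so an all-tied gene reports (M+1)/(2M). Missing genotypes are
mean-imputed per SNP by default (strict mode raises); multi-allelic VCF
records are skipped and counted; fractional dosages are rounded before
error injection with a warning. Empty SNP sets, zero-membership
annotation columns, empty control sequence sets and single-genotype-class
concordance inputs raise informative errors.

## Problem sizes in the test suite

Experiments are sized for single-CPU runs: causal-identification at 500
genes (2,000 in the acceptance script), enrichment recovery at 100
replicates of 2,000 genes × 40 SNPs, FDR calibration at 500 genes × 150
SNPs, model comparison at 2,000 genes × 120 SNPs with a 20%-coverage
enriched track. Larger regions only change runtime, not the estimators.

## Known limitations and open choices

A single shared Π0 (no gene classes); one causal variant per gene; no
annotation interactions; the per-SNP BF mixture weights are fixed rather
than hierarchically estimated (configurable); the exponential-LD
stand-in bounds how literally the causal-identification rates transfer to
real panels — they are reported as lower-bound-style checks under the
generator's conditions. For a single binary annotation all member SNPs
tie in the prior, so the *median* causal-SNP rank percentile moves in
steps as enrichment grows (and only crosses 0.5 once most causal SNPs are
members); the mean percentile is the strictly monotone summary and is
what the ranking tests assert strictly.
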