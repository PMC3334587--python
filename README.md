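# eqtnprior

Annotation-informed priors for cis-eQTL fine-mapping.

Mapping an expression quantitative trait locus (eQTL) rarely pins down the
causal variant — the eQTN — because linkage disequilibrium makes dozens of
SNPs nearly equally associated with expression. `eqtnprior` implements a
Bayesian hierarchical model that resolves this by borrowing strength across
genes: it estimates how strongly eQTNs are enriched in regulatory
annotations (open chromatin, histone marks, TF binding sites, core-promoter
elements, distance to the TSS) and feeds those enrichments back as a prior
over which SNP in each cis-window is causal. It is written for statistical
geneticists and regulatory genomicists who want a tested, scriptable
pipeline from genotype/expression/annotation inputs to enrichment estimates
and per-SNP causal posteriors — with a synthetic-data generator so that
every stage can be validated against known truth without any external data.

## The model

Each gene *k* has *M<sub>k</sub>* candidate SNPs in its cis-window (100 kb
beyond the TSS through 100 kb beyond the TES). Assuming at most one eQTN
per gene, a softmax (conditional-logit) prior places SNP *j* as the causal
site with probability

> &pi;<sub>jk</sub> = exp(x<sub>jk</sub>) / &Sigma;<sub>j'</sub> exp(x<sub>j'k</sub>),  x<sub>jk</sub> = &Sigma;<sub>l</sub> &lambda;<sub>l</sub> &delta;<sub>jkl</sub>,

where &delta;<sub>jkl</sub> ∈ {0,1} indicates whether SNP *j* lies in
annotation *l* and &lambda;<sub>l</sub> is that annotation's log-odds
enrichment (exp(&lambda;<sub>l</sub>) is its fold enrichment). With
Π<sub>0</sub> the probability that a gene has no eQTN, the marginal
likelihood of the expression data relative to the no-eQTN model is

> L<sub>k</sub> / P<sub>k0</sub> = Π<sub>0</sub> + (1 − Π<sub>0</sub>) &Sigma;<sub>j</sub> &pi;<sub>jk</sub> BF<sub>jk</sub>,

where BF<sub>jk</sub> is a closed-form conjugate single-SNP Bayes factor
(normal effect-size prior averaged over a grid of SDs, reference prior on
the variance). Maximizing &Sigma;<sub>k</sub> log(L<sub>k</sub>/P<sub>k0</sub>)
over (&lambda;, Π<sub>0</sub>) — by EM or quasi-Newton — yields enrichment
estimates with profile-likelihood CIs; combining the fitted prior with the
Bayes factors gives each SNP a posterior probability of being the eQTN.

Around this core the package provides: format I/O (VCF, dosage tables,
BED/BED12, GFF3, TSV) with a single 0-based half-open coordinate
convention; the expression normalization pipeline (probe-SNP
residualization, permutation-calibrated PC selection, elastic-net covariate
regression, per-population quantile normalization); frequentist scans with
gene-level permutation FDR; annotation design construction including
background distance/gene-structure features, core-promoter motif and
hexamer scans, and a Monte-Carlo-thresholded peak caller; model comparison
by AIC and ten-fold cross-validation; prior-only SNP ranking; and the
synthetic-data generator (LD genotypes, planted enrichments, genotyping
error).

## Worked example

`examples/03_fit_enrichment.py` simulates 1,500 genes whose causal SNPs
are enriched (&lambda; = 1.5, i.e. ~4.5-fold) in an annotation covering 5%
of SNPs, with Π<sub>0</sub> = 0.3, fits the hierarchical model, and prints:

```
true lambda 1.5 -> estimate 1.726
fold enrichment: 5.62 (95% CI 3.90-7.87)
Pi0 (no-eQTN probability): 0.347 (true 0.30)
posterior eQTN mass inside the annotation: 20.9%
```

The fold enrichment is exp(&lambda;̂) with the profile CI covering the
planted truth; the posterior-mass line apportions causal-SNP probability
across the annotation — with a ~5-fold enrichment over 5% of SNPs, about a
fifth of all eQTN mass falls inside it. The other examples cover study
simulation and file round-trips (`01`), scans and permutation FDR (`02`),
prior-only ranking (`04`), and promoter motifs, hexamer enrichment and
peak calling (`05`); each prints a short annotated summary.

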