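"""Fit the hierarchical enrichment model and read off its estimates.

Computes single-SNP Bayes factors per gene, fits the softmax-prior
mixture model by maximum likelihood, and reports the annotation's fold
enrichment exp(lambda) with a profile-likelihood CI, the no-eQTN
probability Pi0, and the share of posterior eQTN mass falling inside the
annotation.
"""

import numpy as np

from eqtnprior import (
    SimulationConfig,
    annotation_posterior_mass,
    enrichment_report,
    fit_hierarchical,
    posterior_probabilities,
    profile_ci,
)
from eqtnprior.simulate import simulate_hier_dataset

config = SimulationConfig(
    seed=3,
    n_genes=1500,
    n_individuals=210,
    snps_per_region=40,
    flank=10_000,
    gene_length=2_000,
    annotation_coverage={"open_chromatin": 0.05},
    true_lambdas={"open_chromatin": 1.5},
    true_pi0=0.3,
)
data, truth = simulate_hier_dataset(config)

fit = fit_hierarchical(data)
fit.ci["open_chromatin"] = profile_ci(fit, data, "open_chromatin")
report = enrichment_report(fit)

posts, cols = [], []
for k in range(data.n_genes):
    sl = data.gene_slice(k)
    post, _ = posterior_probabilities(fit.params, data.log_bf[sl] / np.log(10), data.delta[sl])
    posts.append(post)
    cols.append(data.delta[sl][:, 0])
mass = annotation_posterior_mass(posts, cols)

row = report.iloc[0]
print(f"true lambda 1.5 -> estimate {fit.params.lambdas[0]:.3f}")
print(f"fold enrichment: {row['fold']:.2f} (95% CI {row['fold_lo']:.2f}-{row['fold_hi']:.2f})")
print(f"Pi0 (no-eQTN probability): {fit.params.pi0:.3f} (true 0.30)")
print(f"posterior eQTN mass inside the annotation: {mass:.1%}")
# With a ~4.5-fold enrichment covering 5% of SNPs, roughly a fifth of all
# causal-SNP posterior mass should sit inside the annotation.
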