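"""Rank candidate SNPs using the prior alone (no expression signal).

Simulates genes whose causal SNPs are enriched in an annotation, then
asks where the annotation prior ranks each true causal SNP among all cis
SNPs when the association signal is withheld.
"""

import numpy as np

from eqtnprior import HierParams, SimulationConfig, prior_only_ranking
from eqtnprior.simulate import simulate_hier_dataset

config = SimulationConfig(
    seed=4,
    n_genes=600,
    n_individuals=210,
    snps_per_region=60,
    flank=12_000,
    gene_length=3_000,
    annotation_coverage={"open_chromatin": 0.10},
    true_lambdas={"open_chromatin": 2.0},
    true_pi0=0.0,
)
data, truth = simulate_hier_dataset(config)
params = HierParams([2.0], 0.0, ["open_chromatin"])  # the (here, known) prior weights

percentiles = []
for k, row in enumerate(truth.itertuples()):
    sl = data.gene_slice(k)
    ranking = prior_only_ranking(params, data.delta[sl])
    percentiles.append(ranking["percentile"].iloc[row.causal_index])

percentiles = np.array(percentiles)
print(f"genes: {len(percentiles)}; median prior-rank percentile of the true eQTN: "
      f"{np.median(percentiles):.2f}")
print(f"true eQTN in the top 10% of cis SNPs by prior alone: {(percentiles <= 0.10).mean():.0%}")
print("(a random prior would put it in the top 10% for 10% of genes)")
# Annotations alone carry real fine-mapping information: the enriched
# track pulls true causal SNPs far up the ranking before any expression
# data are consulted.
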