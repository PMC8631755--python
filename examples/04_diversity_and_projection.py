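"""Diversity statistics (Shannon's I, effective alleles Ne, expected
heterozygosity He; sequence pi, h, Nh) and the persistence projection:
populations below the lowest presence threshold under the future
climate are dropped and everything is recomputed."""

import numpy as np

from landgen import popgen
from landgen.raster import SuitabilityMap
from landgen.synthetic import (
    SyntheticScenario,
    generate_climate_stack,
    generate_populations_and_genotypes,
)

scenario = SyntheticScenario(seed=9, n_cells=(24, 30), n_vars=6, n_pops=10,
                             n_ind_per_pop=8)
current, future = generate_climate_stack(scenario)
pops, genotypes, haplotypes, _ = generate_populations_and_genotypes(
    scenario, current
)

table = popgen.diversity_table(genotypes, haplotypes)
table = popgen.filter_min_n(table, n_min=5)
print(table.round(3).to_string(index=False))

F, labels = popgen.pairwise_fst(genotypes)
lin = popgen.linearize_fst(F)
print(f"\nmean pairwise Weir-Cockerham theta: "
      f"{F[np.triu_indices_from(F, 1)].mean():.3f} "
      f"(linearized mean {lin[np.triu_indices_from(lin, 1)].mean():.3f})")

# a future suitability surface: logistic of the shifted first layer
fut_suit = SuitabilityMap(
    future.grid, 1 / (1 + np.exp(-(future.layers[future.names[0]] - 1.0))),
    "future",
)
proj = popgen.project_future_diversity(genotypes, haplotypes, pops, fut_suit,
                                       lpt=0.3)
print(f"\npersistence projection (LPT=0.3): {len(proj.survivors)} of "
      f"{len(pops)} populations persist; lost: {proj.lost}")
print(f"pooled surviving-haplotype count Nh = {proj.pooled.get('Nh')}")
# Dropping populations can only shrink the pooled haplotype set: future
# diversity is bounded above by current diversity.
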