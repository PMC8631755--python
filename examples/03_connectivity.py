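"""Least-cost connectivity: invert suitability into friction, then build
the all-pairs and shared-haplotype population networks."""

import numpy as np

from landgen import connectivity
from landgen.raster import SuitabilityMap
from landgen.synthetic import (
    SyntheticScenario,
    generate_climate_stack,
    generate_populations_and_genotypes,
)

scenario = SyntheticScenario(seed=8, n_cells=(24, 30), n_vars=6, n_pops=8,
                             n_ind_per_pop=8)
current, _ = generate_climate_stack(scenario)
pops, _, haplotypes, _ = generate_populations_and_genotypes(scenario, current)

suit = SuitabilityMap(current.grid,
                      1 / (1 + np.exp(-current.layers[current.names[0]])))
friction = connectivity.friction_from_suitability(suit, epsilon=0.001)
print("friction: cost = (1 - suitability) + 0.001, so good habitat is cheap")

R = connectivity.resistance_matrix(pops, friction)
print(f"resistance matrix: {R.shape[0]}x{R.shape[1]}, "
      f"mean pairwise cost {R[np.triu_indices_from(R, 1)].mean():.2f}")

links = connectivity.shared_haplotype_links(haplotypes)
net_all = connectivity.build_network(pops, friction, links, "all-pairs")
net_shared = connectivity.build_network(pops, friction, links,
                                        "shared-haplotype")
print(f"population connectivity: {len(net_all.edges)} least-cost paths "
      f"(all pairs)")
print(f"genetic connectivity: {len(net_shared.edges)} paths between "
      f"populations sharing a haplotype")
longest = max(net_all.edges, key=lambda e: e.cost)
print(f"costliest link: {longest.pop_a}-{longest.pop_b} "
      f"(cost {longest.cost:.2f}, {len(longest.path)} cells)")
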