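"""Generate a synthetic study system: autocorrelated climate layers,
occurrences from a known logistic suitability, and climate-driven
population genetics."""

import numpy as np

from landgen.synthetic import (
    SyntheticScenario,
    generate_climate_stack,
    generate_occurrences,
    generate_populations_and_genotypes,
)

scenario = SyntheticScenario(seed=1, n_cells=(30, 36), n_vars=8, n_pops=12,
                             n_ind_per_pop=8, K_true=3)
current, future = generate_climate_stack(scenario)
print(f"climate stack: {current.n_layers} layers on a "
      f"{current.grid.nrows}x{current.grid.ncols} grid")

beta = np.zeros(current.n_layers + 1)
beta[0], beta[1], beta[2] = -2.0, 3.0, -2.0  # restricted-range species
occ, true_suit = generate_occurrences(current, beta, n=150, seed=2)
print(f"occurrences: {len(occ)} points; "
      f"mean true suitability at presences = "
      f"{np.mean([true_suit.value_at(lo, la) for lo, la in zip(occ.lons, occ.lats)]):.2f}")

pops, genotypes, haplotypes, Q_true = generate_populations_and_genotypes(
    scenario, current
)
print(f"populations: {len(pops)}; individuals: {genotypes.n_individuals}; "
      f"SSR loci: {genotypes.n_loci}; haplotypes: {haplotypes.n_haplotypes}")
print("true ancestry of first 3 individuals (rows sum to 1):")
print(np.round(Q_true[:3], 3))
# Each row is an individual's membership in the K=3 climate-driven
# clusters; downstream stages must recover this structure from the
# genotypes and climate alone.
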