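"""Synthetic landscapes, occurrences and genotypes for pipeline testing.

The generators emulate the study design the analysis assumes: a stack of
spatially autocorrelated climate layers for a current and a future
scenario, occurrence points drawn from a known logistic suitability
function, and populations whose ancestry is driven by climate through a
softmax regression, producing diploid SSR genotypes and haploid
chloroplast-style sequences. Every generator is a pure function of its
seed, so all downstream stages are testable without external data.

Default sizes mirror a realistic single-species landscape-genetics
study: 24 populations, 8 SSR loci, 7 haplotypes, 19 climate layers and
~9 individuals per population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genetics import GenotypeTable, HaplotypeSet, PopulationSet
from .geo import OccurrenceSet
from .raster import GridSpec, RasterStack, SuitabilityMap

__all__ = [
    "SyntheticScenario",
    "gaussian_random_field",
    "generate_climate_stack",
    "generate_occurrences",
    "generate_populations_and_genotypes",
    "generate_ibr_genotypes",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study.

    ``beta_true`` is the (K_true, n_env_covariates + 1) coefficient
    matrix (intercept first) that links standardized climate at an
    individual's location to its cluster ancestry through a softmax;
    ``None`` draws a well-separated default.
    """

    seed: int = 0
    extent: tuple[float, float, float, float] = (100.0, 25.0, 112.0, 35.0)
    n_cells: tuple[int, int] = (40, 48)
    n_vars: int = 19
    autocorr_range: float = 6.0
    future_shift: np.ndarray | float = 1.0
    future_noise: float = 0.1
    n_pops: int = 24
    n_ind_per_pop: int = 9
    K_true: int = 3
    beta_true: np.ndarray | None = None
    ancestry_noise: float = 0.25
    n_env_covariates: int = 3
    n_ssr_loci: int = 8
    n_alleles_per_locus: int = 5
    allele_concentration: float = 0.3
    n_haplotypes: int = 7
    haplotype_concentration: float = 0.5
    seq_length: int = 1000

    def __post_init__(self) -> None:
        rows, cols = self.n_cells
        if rows < 8 or cols < 8:
            raise ValueError("n_cells must both be >= 8")
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        if self.n_pops < 2:
            raise ValueError("n_pops must be >= 2")
        if self.autocorr_range <= 0:
            raise ValueError("autocorr_range must be positive")
        if self.K_true > self.n_haplotypes:
            raise ValueError("K_true exceeds the number of distinct haplotypes")

    @property
    def grid(self) -> GridSpec:
        xmin, ymin, xmax, ymax = self.extent
        rows, cols = self.n_cells
        cell = (xmax - xmin) / cols
        if abs((ymax - ymin) / rows - cell) > 1e-9:
            # keep cells square: honour x-extent and row count
            ymax = ymin + rows * cell
        return GridSpec(xmin, ymin, cell, rows, cols)

    def shift_vector(self) -> np.ndarray:
        s = np.asarray(self.future_shift, dtype=float)
        if s.ndim == 0:
            return np.full(self.n_vars, float(s))
        if s.shape != (self.n_vars,):
            raise ValueError("future_shift length must equal n_vars")
        return s


def gaussian_random_field(shape: tuple[int, int], corr_range: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian random field by FFT spectral synthesis.

    White noise is filtered with a Gaussian transfer function whose
    standard deviation is ``corr_range`` cells; the result is
    standardized to zero mean and unit variance.
    """
    if corr_range <= 0:
        raise ValueError("corr_range must be positive")
    noise = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    transfer = np.exp(-2 * (np.pi * corr_range) ** 2 * (fx**2 + fy**2))
    f = np.fft.ifft2(np.fft.fft2(noise) * transfer).real
    sd = f.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def generate_climate_stack(scenario: SyntheticScenario
                           ) -> tuple[RasterStack, RasterStack]:
    """Current and future climate stacks sharing one grid and mask.

    Each layer ``bio01..bioNN`` is an independent smoothed Gaussian
    random field; the future layer adds the per-variable trend plus
    small-scale (weakly autocorrelated) noise.
    """
    grid = scenario.grid
    rng = np.random.default_rng(scenario.seed)
    shift = scenario.shift_vector()
    current, future = {}, {}
    for v in range(scenario.n_vars):
        name = f"bio{v + 1:02d}"
        base = gaussian_random_field(grid.shape, scenario.autocorr_range, rng)
        current[name] = base
        if scenario.future_noise > 0:
            eps = scenario.future_noise * gaussian_random_field(
                grid.shape, max(scenario.autocorr_range / 4, 1.0), rng
            )
        else:
            eps = 0.0
        future[name] = base + shift[v] + eps
    return RasterStack(grid, current), RasterStack(grid, future)


def true_suitability(stack: RasterStack, true_beta: np.ndarray) -> SuitabilityMap:
    """Logistic suitability implied by a coefficient vector
    (intercept + one slope per layer) on the raw layer values."""
    true_beta = np.asarray(true_beta, dtype=float)
    if true_beta.shape != (stack.n_layers + 1,):
        raise ValueError("true_beta length must be n_layers + 1 (intercept first)")
    rows, cols, X = stack.table()
    eta = true_beta[0] + X @ true_beta[1:]
    suit = np.full(stack.grid.shape, np.nan)
    suit[rows, cols] = 1.0 / (1.0 + np.exp(-eta))
    return SuitabilityMap(stack.grid, suit, scenario="true")


def generate_occurrences(stack: RasterStack, true_beta: np.ndarray, n: int,
                         seed: int) -> tuple[OccurrenceSet, SuitabilityMap]:
    """Occurrence points sampled from a known logistic suitability.

    Each unmasked cell is a Bernoulli trial with success probability
    equal to its suitability; if more than ``n`` cells succeed, ``n``
    are kept at random, and if fewer succeed a warning is raised and all
    successes are returned. Points are cell centres. The true
    suitability surface is returned alongside for recovery tests.
    """
    suit = true_suitability(stack, true_beta)
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(stack.mask)
    p = suit.values[rows, cols]
    hits = rng.random(len(p)) < p
    idx = np.nonzero(hits)[0]
    if len(idx) > n:
        idx = rng.choice(idx, size=n, replace=False)
        idx.sort()
    elif len(idx) < n:
        warnings.warn(
            f"requested {n} occurrences but presence mass supports only {len(idx)}"
        )
    lons, lats = [], []
    for i in idx:
        lon, lat = stack.grid.center_of(int(rows[i]), int(cols[i]))
        lons.append(lon)
        lats.append(lat)
    occ = OccurrenceSet(np.array(lons), np.array(lats), provenance="synthetic")
    return occ, suit


def _default_beta(scenario: SyntheticScenario, rng: np.random.Generator) -> np.ndarray:
    """Well-separated cluster-by-covariate coefficients: each cluster
    responds strongly to a different covariate."""
    K, m = scenario.K_true, scenario.n_env_covariates
    beta = np.zeros((K, m + 1))
    for k in range(K):
        beta[k, 1 + (k % m)] = 3.0 * (1 if (k // m) % 2 == 0 else -1)
    return beta


def generate_populations_and_genotypes(
    scenario: SyntheticScenario, stack: RasterStack
) -> tuple[PopulationSet, GenotypeTable, HaplotypeSet, np.ndarray]:
    """Populations, SSR genotypes, haplotype sequences and true ancestry.

    Population sites are unmasked cells sampled without replacement.
    Individual ancestry is ``Q_true = softmax(beta_true @ x + noise)``
    with ``x`` the standardized climate covariates at the population's
    location. Each gene copy picks a cluster from ``Q_true`` and an
    allele from that cluster's Dirichlet-drawn frequencies; haplotypes
    are drawn the same way from per-cluster haplotype frequencies (one
    copy per individual, maternally inherited). Sequences share a random
    base string with one diagnostic substitution per haplotype, and
    every requested haplotype is guaranteed at least one carrier.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    grid = stack.grid
    rows, cols = np.nonzero(stack.mask)
    if len(rows) < scenario.n_pops:
        raise ValueError("not enough unmasked cells for the requested populations")
    sites = rng.choice(len(rows), size=scenario.n_pops, replace=False)
    pop_ids = [f"P{j + 1:02d}" for j in range(scenario.n_pops)]
    lons, lats = zip(*(grid.center_of(int(rows[s]), int(cols[s])) for s in sites))
    pops = PopulationSet(pop_ids, np.array(lons), np.array(lats))

    # standardized climate covariates at population sites
    m = min(scenario.n_env_covariates, stack.n_layers)
    env = stack.values_at_cells(rows[sites], cols[sites])[:, :m]
    env = (env - env.mean(axis=0)) / np.where(env.std(axis=0) > 0, env.std(axis=0), 1)

    K = scenario.K_true
    beta = scenario.beta_true
    if beta is None:
        beta = _default_beta(scenario, rng)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (K, m + 1):
        raise ValueError(f"beta_true shape {beta.shape} != ({K}, {m + 1})")

    n_ind = scenario.n_pops * scenario.n_ind_per_pop
    individuals, populations, ind_pop = [], [], []
    for j, pid in enumerate(pop_ids):
        for i in range(scenario.n_ind_per_pop):
            individuals.append(f"{pid}_{i + 1:02d}")
            populations.append(pid)
            ind_pop.append(j)
    ind_pop = np.array(ind_pop)

    eta = np.column_stack([np.ones(scenario.n_pops), env]) @ beta.T  # (n_pops, K)
    z = eta[ind_pop] + scenario.ancestry_noise * rng.standard_normal((n_ind, K))
    z -= z.max(axis=1, keepdims=True)
    Q_true = np.exp(z)
    Q_true /= Q_true.sum(axis=1, keepdims=True)

    # per-cluster SSR allele frequencies (Dirichlet; low concentration
    # gives strongly differentiated clusters)
    A = scenario.n_alleles_per_locus
    allele_sizes = 100 + 2 * np.arange(A)
    f = rng.dirichlet(
        np.full(A, scenario.allele_concentration), size=(K, scenario.n_ssr_loci)
    )
    copies = np.empty((n_ind, scenario.n_ssr_loci, 2), dtype=int)
    u = _sample_categorical(rng, np.repeat(Q_true, 2 * scenario.n_ssr_loci, axis=0))
    u = u.reshape(n_ind, scenario.n_ssr_loci, 2)
    for l in range(scenario.n_ssr_loci):
        for c in range(2):
            probs = f[u[:, l, c], l]
            copies[:, l, c] = allele_sizes[_sample_categorical(rng, probs)]
    gt = GenotypeTable(
        individuals,
        populations,
        [f"SSR{l + 1}" for l in range(scenario.n_ssr_loci)],
        copies,
        coords=np.column_stack([pops.lons[ind_pop], pops.lats[ind_pop]]),
    )

    # per-cluster haplotype frequencies and one haplotype per individual
    g = rng.dirichlet(
        np.full(scenario.n_haplotypes, scenario.haplotype_concentration), size=K
    )
    hk = _sample_categorical(rng, Q_true)
    hap_idx = np.array([_sample_categorical(rng, g[k][None, :])[0] for k in hk])
    # guarantee every requested haplotype has at least one carrier
    for h in range(scenario.n_haplotypes):
        if not (hap_idx == h).any():
            hap_idx[rng.integers(n_ind)] = h
    base = rng.choice(_BASES, size=scenario.seq_length)
    seqs = []
    for h in hap_idx:
        s = base.copy()
        if h > 0:  # H1 is the base sequence; Hj substitutes site j-1
            pos = h - 1
            s[pos] = _BASES[(np.nonzero(_BASES == s[pos])[0][0] + 1) % 4]
        seqs.append("".join(s))
    haps = HaplotypeSet(
        list(individuals),
        list(populations),
        seqs,
        [f"H{h + 1}" for h in hap_idx],
    )
    return pops, gt, haps, Q_true


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorized draw of one category per row of a probability matrix."""
    cdf = np.cumsum(probs, axis=1)
    cdf[:, -1] = 1.0
    r = rng.random((probs.shape[0], 1))
    return (r > cdf).sum(axis=1)


def generate_ibr_genotypes(
    pops: PopulationSet,
    resistance: np.ndarray,
    n_ind_per_pop: int = 10,
    n_loci: int = 8,
    n_alleles: int = 5,
    sigma: float = 1.5,
    seed: int = 0,
) -> GenotypeTable:
    """Genotypes whose divergence grows with landscape resistance.

    Population allele frequencies are a shared Dirichlet base perturbed
    on the logit scale by a multivariate normal with covariance
    ``sigma² · exp(−R/ρ)`` (ρ = median off-diagonal resistance), so
    pairs separated by high resistance drift further apart — an
    isolation-by-resistance signal for Mantel-test validation.
    """
    rng = np.random.default_rng(seed)
    n_pops = len(pops)
    R = np.asarray(resistance, dtype=float)
    if R.shape != (n_pops, n_pops):
        raise ValueError("resistance matrix shape mismatch")
    off = R[np.triu_indices(n_pops, k=1)]
    rho = np.median(off) if off.size else 1.0
    rho = max(rho, 1e-9)
    cov = sigma**2 * np.exp(-R / rho)
    cov += 1e-9 * np.eye(n_pops)
    allele_sizes = 100 + 2 * np.arange(n_alleles)
    chol = np.linalg.cholesky(cov)
    individuals, populations, rows = [], [], []
    freqs = np.empty((n_pops, n_loci, n_alleles))
    for l in range(n_loci):
        base = rng.dirichlet(np.full(n_alleles, 1.0))
        logit = np.log(np.clip(base, 1e-9, None))
        dev = chol @ rng.standard_normal((n_pops, n_alleles))
        w = np.exp(logit[None, :] + dev)
        freqs[:, l, :] = w / w.sum(axis=1, keepdims=True)
    for j, pid in enumerate(pops.ids):
        for i in range(n_ind_per_pop):
            individuals.append(f"{pid}_{i + 1:02d}")
            populations.append(pid)
            calls = np.empty((n_loci, 2), dtype=int)
            for l in range(n_loci):
                calls[l] = allele_sizes[rng.choice(n_alleles, size=2, p=freqs[j, l])]
            rows.append(calls)
    return GenotypeTable(
        individuals, populations,
        [f"SSR{l + 1}" for l in range(n_loci)], np.array(rows),
    )
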