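"""Microsatellite and sequence diversity statistics, pairwise Fst, and
the persistence projection of future genetic diversity.

Per-locus frequency statistics follow Nei: expected heterozygosity
He = 1 - sum(p^2), effective allele number Ne = 1/sum(p^2), Shannon's
information index I = -sum(p ln p); population-level values are means
over loci (He without small-sample correction, matching GenAlEx's He,
with the unbiased uHe also emitted). Sequence statistics: nucleotide
diversity (pi, mean pairwise proportion of differing sites with
pairwise deletion of gapped columns), gene diversity
h = n(1 - sum q^2)/(n - 1), and the haplotype count Nh.

Pairwise population divergence is Weir & Cockerham's theta, combined
across alleles and loci as a ratio of sums, and linearized as
Fst/(1-Fst) for isolation-by-resistance regressions.

The persistence projection drops populations whose habitat suitability
under a future scenario falls below the lowest presence threshold and
recomputes every statistic on the survivors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import MISSING, GenotypeTable, HaplotypeSet, PopulationSet
from .raster import SuitabilityMap

__all__ = [
    "allele_frequencies",
    "expected_heterozygosity",
    "effective_alleles",
    "shannon_index",
    "nucleotide_diversity",
    "gene_diversity",
    "haplotype_count",
    "ssr_diversity_table",
    "sequence_diversity_table",
    "diversity_table",
    "pairwise_fst",
    "linearize_fst",
    "filter_min_n",
    "project_future_diversity",
]


# ---------------------------------------------------------------------------
# allele-frequency statistics


def allele_frequencies(gt: GenotypeTable, population: str, locus: str) -> dict[int, float]:
    """Observed allele frequencies in one population at one locus."""
    try:
        l = gt.loci.index(locus)
    except ValueError:
        raise KeyError(f"unknown locus {locus!r}") from None
    mask = gt.population_mask(population)
    calls = gt.alleles[mask, l, :].ravel()
    calls = calls[calls != MISSING]
    if calls.size == 0:
        raise ValueError(f"all genotypes missing for {population}/{locus}")
    values, counts = np.unique(calls, return_counts=True)
    total = counts.sum()
    return {int(v): float(c) / total for v, c in zip(values, counts)}


def _check_freqs(p) -> np.ndarray:
    p = np.asarray(list(p.values()) if isinstance(p, dict) else p, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("frequencies must be non-negative and sum to 1")
    return p


def expected_heterozygosity(p) -> float:
    """Nei's expected heterozygosity He = 1 - sum(p^2)."""
    p = _check_freqs(p)
    return float(1.0 - np.sum(p**2))


def effective_alleles(p) -> float:
    """Number of effective alleles Ne = 1 / sum(p^2)."""
    p = _check_freqs(p)
    return float(1.0 / np.sum(p**2))


def shannon_index(p) -> float:
    """Shannon's information index I = -sum(p ln p)."""
    p = _check_freqs(p)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


# ---------------------------------------------------------------------------
# sequence statistics


def _pairwise_prop_diff(a: str, b: str) -> float:
    """Proportion of differing sites between two aligned sequences,
    skipping columns where either has a gap/missing symbol."""
    aa = np.frombuffer(a.encode(), dtype="S1")
    bb = np.frombuffer(b.encode(), dtype="S1")
    ok = ~(np.isin(aa, (b"-", b"N", b"?")) | np.isin(bb, (b"-", b"N", b"?")))
    n = int(ok.sum())
    if n == 0:
        return np.nan
    return float((aa[ok] != bb[ok]).sum()) / n


def nucleotide_diversity(seqs: list[str]) -> float:
    """pi: mean pairwise proportion of differing compared sites."""
    n = len(seqs)
    if n < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    total, pairs = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            d = _pairwise_prop_diff(seqs[i], seqs[j])
            if np.isfinite(d):
                total += d
                pairs += 1
    if pairs == 0:
        return np.nan
    return total / pairs


def gene_diversity(seqs: list[str]) -> float:
    """Nei's gene (haplotype) diversity h = n(1 - sum q^2)/(n - 1)."""
    n = len(seqs)
    if n < 2:
        raise ValueError("gene diversity needs >= 2 sequences")
    _, counts = np.unique(seqs, return_counts=True)
    q = counts / n
    return float(n * (1.0 - np.sum(q**2)) / (n - 1))


def haplotype_count(seqs: list[str]) -> int:
    """Number of distinct sequences (gaps significant)."""
    return len(set(seqs))


# ---------------------------------------------------------------------------
# per-population tables


def ssr_diversity_table(gt: GenotypeTable) -> pd.DataFrame:
    """Per-population SSR diversity: N, I, Ne, He, uHe (means over loci)."""
    rows = []
    for pop in gt.population_ids:
        mask = gt.population_mask(pop)
        N = int(mask.sum())
        I_vals, Ne_vals, He_vals, uHe_vals = [], [], [], []
        for locus in gt.loci:
            try:
                p = allele_frequencies(gt, pop, locus)
            except ValueError:
                continue
            pv = np.asarray(list(p.values()))
            he = expected_heterozygosity(pv)
            n_copies = int(
                (gt.alleles[mask, gt.loci.index(locus), :] != MISSING).sum()
            )
            I_vals.append(shannon_index(pv))
            Ne_vals.append(effective_alleles(pv))
            He_vals.append(he)
            if n_copies > 1:
                uHe_vals.append(he * n_copies / (n_copies - 1))
        rows.append(
            {
                "pop": pop,
                "N": N,
                "I": float(np.mean(I_vals)) if I_vals else np.nan,
                "Ne": float(np.mean(Ne_vals)) if Ne_vals else np.nan,
                "He": float(np.mean(He_vals)) if He_vals else np.nan,
                "uHe": float(np.mean(uHe_vals)) if uHe_vals else np.nan,
            }
        )
    return pd.DataFrame(rows)


def sequence_diversity_table(haps: HaplotypeSet) -> pd.DataFrame:
    """Per-population sequence diversity: n, h, pi, Nh.

    h and pi are reported as NaN when a population has fewer than two
    sequences; Nh is always computed.
    """
    rows = []
    seqs_by_pop: dict[str, list[str]] = {}
    for p, s in zip(haps.populations, haps.sequences):
        seqs_by_pop.setdefault(p, []).append(s)
    for pop in haps.population_ids:
        seqs = seqs_by_pop[pop]
        n = len(seqs)
        rows.append(
            {
                "pop": pop,
                "n": n,
                "h": gene_diversity(seqs) if n >= 2 else np.nan,
                "pi": nucleotide_diversity(seqs) if n >= 2 else np.nan,
                "Nh": haplotype_count(seqs),
            }
        )
    return pd.DataFrame(rows)


def diversity_table(gt: GenotypeTable, haps: HaplotypeSet) -> pd.DataFrame:
    """Joined per-population SSR + sequence diversity table."""
    return ssr_diversity_table(gt).merge(
        sequence_diversity_table(haps), on="pop", how="outer"
    )


def species_level_stats(gt: GenotypeTable, haps: HaplotypeSet) -> dict[str, float]:
    """Pooled (all individuals as one population) species-level stats."""
    pooled_gt = GenotypeTable(
        list(gt.individuals), ["ALL"] * gt.n_individuals, list(gt.loci), gt.alleles
    )
    ssr = ssr_diversity_table(pooled_gt).iloc[0]
    seqs = list(haps.sequences)
    out = {
        "I": float(ssr["I"]),
        "Ne": float(ssr["Ne"]),
        "He": float(ssr["He"]),
        "n_seq": len(seqs),
        "Nh": haplotype_count(seqs) if seqs else 0,
    }
    out["h"] = gene_diversity(seqs) if len(seqs) >= 2 else np.nan
    out["pi"] = nucleotide_diversity(seqs) if len(seqs) >= 2 else np.nan
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham theta


def _wc_components(gt: GenotypeTable, pop_a: str, pop_b: str
                   ) -> tuple[float, float]:
    """Sums of Weir-Cockerham a and a+b+c over alleles and loci for one
    population pair (r = 2)."""
    sum_a, sum_abc = 0.0, 0.0
    r = 2
    for l, locus in enumerate(gt.loci):
        stats = []
        for pop in (pop_a, pop_b):
            mask = gt.population_mask(pop)
            calls = gt.alleles[mask, l, :]
            ok = (calls != MISSING).all(axis=1)
            calls = calls[ok]
            if len(calls) == 0:
                break
            stats.append(calls)
        if len(stats) < 2:
            continue
        alleles = np.unique(np.concatenate([c.ravel() for c in stats]))
        if len(alleles) < 2:
            continue
        n_i = np.array([len(c) for c in stats], dtype=float)
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        for allele in alleles:
            p_i = np.array([(c == allele).sum() / (2 * len(c)) for c in stats])
            h_i = np.array(
                [((c[:, 0] == allele) ^ (c[:, 1] == allele)).mean() for c in stats]
            )
            pbar = (n_i * p_i).sum() / (r * nbar)
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2
                - 1.0 / (nbar - 1)
                * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            sum_a += a
            sum_abc += a + b + c
    return sum_a, sum_abc


def pairwise_fst(gt: GenotypeTable) -> tuple[np.ndarray, list[str]]:
    """Multilocus Weir-Cockerham theta for every population pair
    (ratio-of-sums over alleles and loci); returns (matrix, labels)."""
    pops = gt.population_ids
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    sizes = gt.population_sizes()
    small = [p for p in pops if sizes[p] < 2]
    if small:
        raise ValueError(f"populations with < 2 individuals: {small}")
    n = len(pops)
    F = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sa, sabc = _wc_components(gt, pops[i], pops[j])
            theta = sa / sabc if sabc != 0 else 0.0
            F[i, j] = F[j, i] = theta
    return F, pops


def linearize_fst(F: np.ndarray) -> np.ndarray:
    """Slatkin's linearization Fst/(1-Fst); negative estimates are
    floored at zero first, and Fst = 1 maps to inf (flagged)."""
    F = np.asarray(F, dtype=float)
    Fc = np.clip(F, 0.0, None)
    with np.errstate(divide="ignore"):
        out = Fc / (1.0 - Fc)
    if np.isinf(out).any():
        warnings.warn("Fst = 1 pair(s): linearized distance infinite")
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# filtering and the persistence projection


def filter_min_n(table: pd.DataFrame, n_min: int = 5, size_col: str = "N"
                 ) -> pd.DataFrame:
    """Drop populations with sample size below ``n_min`` (avoids
    underestimating Ne from tiny samples); exclusions are logged."""
    drop = table[table[size_col] < n_min]["pop"].tolist()
    if drop:
        warnings.warn(f"excluding populations with {size_col} < {n_min}: {drop}")
    return table[table[size_col] >= n_min].reset_index(drop=True)


@dataclass
class PersistenceProjection:
    scenario: str
    lpt: float
    suitability: dict[str, float]
    survivors: list[str]
    lost: list[str]
    table: pd.DataFrame
    pooled: dict[str, float]
    per_population_mean: dict[str, float]


def project_future_diversity(
    gt: GenotypeTable,
    haps: HaplotypeSet,
    pops: PopulationSet,
    future_suit: SuitabilityMap,
    lpt: float,
) -> PersistenceProjection:
    """Diversity after climate-driven local extinction.

    A population persists iff the future suitability of the cell holding
    its coordinate is >= the lowest presence threshold; all statistics
    are recomputed on the survivors. Pooled species-level statistics
    (all surviving individuals as one sample) and the mean of
    per-population values are both reported.
    """
    suit_at = {
        pid: future_suit.value_at(lon, lat)
        for pid, lon, lat in zip(pops.ids, pops.lons, pops.lats)
    }
    survivors = [p for p in pops.ids if np.isfinite(suit_at[p]) and suit_at[p] >= lpt]
    lost = [p for p in pops.ids if p not in survivors]
    if not survivors:
        warnings.warn(f"no populations persist under {future_suit.scenario}")
        return PersistenceProjection(
            future_suit.scenario, lpt, suit_at, [], lost,
            pd.DataFrame(), {}, {},
        )
    keep = set(survivors)
    idx = np.nonzero([p in keep for p in gt.populations])[0]
    gt_s = gt.subset_individuals(idx)
    haps_s = haps.subset_populations(keep)
    table = diversity_table(gt_s, haps_s)
    pooled = species_level_stats(gt_s, haps_s)
    numeric = table.drop(columns=["pop"]).mean(numeric_only=True)
    per_pop_mean = {k: float(v) for k, v in numeric.items()}
    return PersistenceProjection(
        future_suit.scenario, lpt, suit_at, survivors, lost, table, pooled,
        per_pop_mean,
    )
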