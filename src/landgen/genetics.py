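"""Containers for population-genetic data.

Diploid microsatellite (SSR) genotypes are held as an individuals x loci
table of integer allele pairs with population labels and optional
coordinates; aligned haplotype sequences (e.g. chloroplast spacers) are
held per individual with population labels and collapsed haplotype ids.

I/O: GenAlEx-style genotype CSV (two header rows, two columns per
locus) and FASTA alignments with ``<population>_<individual>`` ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["PopulationSet", "GenotypeTable", "HaplotypeSet", "MISSING"]

#: sentinel allele value for a missing genotype call
MISSING = 0


@dataclass
class PopulationSet:
    """Sampled populations with ids and lon/lat coordinates."""

    ids: list[str]
    lons: np.ndarray
    lats: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate population ids")
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        if not (len(self.ids) == len(self.lons) == len(self.lats)):
            raise ValueError("ids and coordinates differ in length")

    def __len__(self) -> int:
        return len(self.ids)

    def coords(self) -> np.ndarray:
        return np.column_stack([self.lons, self.lats])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"id": self.ids, "lon": self.lons, "lat": self.lats}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationSet":
        df = pd.read_csv(path)
        return cls(df["id"].astype(str).tolist(), df["lon"].to_numpy(), df["lat"].to_numpy())


@dataclass
class GenotypeTable:
    """Diploid SSR calls: ``alleles[i, l, :]`` are the two integer allele
    sizes of individual ``i`` at locus ``l`` (0 = missing; both copies
    present or both missing)."""

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    alleles: np.ndarray  # (n_ind, n_loci, 2) int
    coords: np.ndarray | None = None  # (n_ind, 2) lon/lat

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=int)
        n, L = len(self.individuals), len(self.loci)
        if self.alleles.shape != (n, L, 2):
            raise ValueError(f"alleles shape {self.alleles.shape} != ({n},{L},2)")
        if len(self.populations) != n:
            raise ValueError("every individual needs a population label")
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing genotype call (one allele of two)")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def subset_individuals(self, index: np.ndarray) -> "GenotypeTable":
        index = np.asarray(index)
        return GenotypeTable(
            [self.individuals[i] for i in index],
            [self.populations[i] for i in index],
            list(self.loci),
            self.alleles[index],
            None if self.coords is None else self.coords[index],
        )

    def population_mask(self, pop: str) -> np.ndarray:
        return np.array([p == pop for p in self.populations])

    def population_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.populations:
            out[p] = out.get(p, 0) + 1
        return out

    # -- GenAlEx-style CSV ------------------------------------------------
    def to_genalex_csv(self, path: str | Path) -> None:
        """Two numeric header rows (n_loci, n_samples, n_pops), a column
        header row, then one row per individual with two allele columns
        per locus."""
        n_pops = len(self.population_ids)
        cols = ["sample", "population"]
        for loc in self.loci:
            cols += [loc, f"{loc}.2"]
        lines = [
            ",".join(map(str, [self.n_loci, self.n_individuals, n_pops]
                         + [""] * (len(cols) - 3))),
            ",".join(["landgen genotypes"] + [""] * (len(cols) - 1)),
            ",".join(cols),
        ]
        for i, (ind, pop) in enumerate(zip(self.individuals, self.populations)):
            row = [ind, pop]
            for l in range(self.n_loci):
                row += [str(self.alleles[i, l, 0]), str(self.alleles[i, l, 1])]
            lines.append(",".join(row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_genalex_csv(cls, path: str | Path) -> "GenotypeTable":
        lines = Path(path).read_text().splitlines()
        n_loci = int(lines[0].split(",")[0])
        header = lines[2].split(",")
        loci = [header[2 + 2 * l] for l in range(n_loci)]
        individuals, populations, rows = [], [], []
        for line in lines[3:]:
            if not line.strip():
                continue
            parts = line.split(",")
            individuals.append(parts[0])
            populations.append(parts[1])
            vals = [int(float(v)) if v.strip() else MISSING for v in parts[2:2 + 2 * n_loci]]
            rows.append(np.array(vals).reshape(n_loci, 2))
        return cls(individuals, populations, loci, np.array(rows))


@dataclass
class HaplotypeSet:
    """Aligned sequences with population labels and collapsed haplotype ids.

    Haplotype identity is exact string identity of the aligned sequence
    (gap characters significant), so indel variants count as distinct
    haplotypes.
    """

    individuals: list[str]
    populations: list[str]
    sequences: list[str]
    haplotype_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("alignment not rectangular")
        if len(self.populations) != len(self.individuals) or len(self.sequences) != len(
            self.individuals
        ):
            raise ValueError("individuals, populations, sequences differ in length")
        if not self.haplotype_ids:
            self.haplotype_ids = self._collapse()
        else:
            by_seq: dict[str, str] = {}
            for s, h in zip(self.sequences, self.haplotype_ids):
                if by_seq.setdefault(s, h) != h:
                    raise ValueError("identical sequences with differing haplotype ids")

    def _collapse(self) -> list[str]:
        ids: dict[str, str] = {}
        out = []
        for s in self.sequences:
            if s not in ids:
                ids[s] = f"H{len(ids) + 1}"
            out.append(ids[s])
        return out

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def n_haplotypes(self) -> int:
        return len(set(self.haplotype_ids))

    @property
    def population_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_haplotypes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for p, h in zip(self.populations, self.haplotype_ids):
            out.setdefault(p, set()).add(h)
        return out

    def subset_populations(self, keep: set[str]) -> "HaplotypeSet":
        idx = [i for i, p in enumerate(self.populations) if p in keep]
        return HaplotypeSet(
            [self.individuals[i] for i in idx],
            [self.populations[i] for i in idx],
            [self.sequences[i] for i in idx],
            [self.haplotype_ids[i] for i in idx],
        )

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s), id=ind, description=f"haplotype={h}")
            for ind, s, h in zip(self.individuals, self.sequences, self.haplotype_ids)
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "HaplotypeSet":
        """Ids must be ``<population>_<individual>``."""
        individuals, populations, sequences = [], [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            if "_" not in rec.id:
                raise ValueError(f"id {rec.id!r} lacks '<population>_<individual>' form")
            pop = rec.id.rsplit("_", 1)[0]
            individuals.append(rec.id)
            populations.append(pop)
            sequences.append(str(rec.seq).upper())
        if not individuals:
            warnings.warn(f"no sequences in {path}")
        return cls(individuals, populations, sequences)
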