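"""Shared in-memory containers for the association-mapping pipeline.

All genotype data is biallelic and coded 0/1 with -1 for missing; the panel
and the doubled-haploid material are inbred, so a single code per (line,
marker) cell is a complete genotype. Map positions are centimorgans on a
named linkage group of a named consensus map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing genotype call


class PedqtlError(Exception):
    """Base class for package errors."""


class ConfigError(PedqtlError):
    """Invalid configuration or precondition violation."""


class FormatError(PedqtlError):
    """Malformed on-disk input."""


class PedigreeError(PedqtlError):
    """Inconsistent pedigree (cycles, unknown parents)."""


class DesignError(PedqtlError):
    """Primer design infeasible under the stated constraints."""


@dataclass
class GenotypeMatrix:
    """Accessions x markers matrix of biallelic calls.

    ``calls`` holds int8 codes in {0, 1, MISSING}. Code 1 is, by convention,
    the allele carried by the focal line of the analysis (the variety whose
    pedigree is being dissected) whenever orientation is known; estimated
    marker effects then read directly as the effect of the focal allele.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise ConfigError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ConfigError("duplicate accession ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ConfigError("duplicate marker ids")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ConfigError(
                f"invalid genotype code {self.calls[i, j]} at accession "
                f"{self.accession_ids[i]!r}, marker {self.marker_ids[j]!r}"
            )

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def accession_index(self, accession_id: str) -> int:
        return self.accession_ids.index(accession_id)

    def marker_index(self, marker_id: str) -> int:
        return self.marker_ids.index(marker_id)

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self.marker_index(marker_id)]

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker over non-missing calls.

        Markers with no non-missing calls get NaN.
        """
        obs = self.calls != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq1 = np.where(obs, self.calls, 0).sum(axis=0) / np.where(n > 0, n, 1)
        freq1 = np.where(n > 0, freq1, np.nan)
        return np.minimum(freq1, 1.0 - freq1)

    def subset_markers(self, marker_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.marker_index(m) for m in marker_ids]
        return GenotypeMatrix(list(self.accession_ids), list(marker_ids), self.calls[:, idx])

    def subset_accessions(self, accession_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.accession_index(a) for a in accession_ids]
        return GenotypeMatrix(list(accession_ids), list(self.marker_ids), self.calls[idx, :])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.accession_ids, columns=self.marker_ids)


@dataclass
class GeneticMap:
    """Marker positions (cM) on linkage groups of one or more consensus maps."""

    table: pd.DataFrame  # columns: marker_id, linkage_group, position_cm, map_source

    REQUIRED = ("marker_id", "linkage_group", "position_cm", "map_source")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ConfigError(f"genetic map missing columns: {missing}")
        t = self.table.copy()
        t["position_cm"] = pd.to_numeric(t["position_cm"], errors="raise")
        if (t["position_cm"] < 0).any():
            raise ConfigError("negative cM position in genetic map")
        if t.duplicated(subset=["marker_id", "map_source"]).any():
            dup = t[t.duplicated(subset=["marker_id", "map_source"])]["marker_id"].iloc[0]
            raise ConfigError(f"duplicate (marker_id, map_source): {dup!r}")
        self.table = t.sort_values(
            ["map_source", "linkage_group", "position_cm", "marker_id"]
        ).reset_index(drop=True)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table["marker_id"])

    def linkage_groups(self, map_source: str | None = None) -> list[str]:
        t = self.table
        if map_source is not None:
            t = t[t["map_source"] == map_source]
        return list(dict.fromkeys(t["linkage_group"]))

    def group(self, linkage_group: str, map_source: str | None = None) -> pd.DataFrame:
        t = self.table[self.table["linkage_group"] == linkage_group]
        if map_source is not None:
            t = t[t["map_source"] == map_source]
        return t.reset_index(drop=True)

    def position_of(self, marker_id: str) -> tuple[str, float]:
        rows = self.table[self.table["marker_id"] == marker_id]
        if rows.empty:
            raise KeyError(marker_id)
        r = rows.iloc[0]
        return str(r["linkage_group"]), float(r["position_cm"])


@dataclass
class PhenotypeTable:
    """Long-format trait records: one row per (accession, environment, replicate, trait).

    Environment labels follow the study convention of first letter of location
    plus harvest year (e.g. "K09") when data is imported from field trials,
    but any label is accepted.
    """

    table: pd.DataFrame  # columns: accession, environment, replicate, trait, value

    REQUIRED = ("accession", "environment", "replicate", "trait", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ConfigError(f"phenotype table missing columns: {missing}")
        t = self.table.copy()
        t["value"] = pd.to_numeric(t["value"], errors="raise")
        key = ["accession", "environment", "replicate", "trait"]
        if t.duplicated(subset=key).any():
            raise ConfigError("duplicate (accession, environment, replicate, trait) record")
        self.table = t.reset_index(drop=True)

    def traits(self) -> list[str]:
        return sorted(self.table["trait"].unique())

    def environments(self) -> list[str]:
        return sorted(self.table["environment"].unique())

    def env_means(self, trait: str) -> pd.DataFrame:
        """Accession x environment table of replicate-mean values for one trait."""
        t = self.table[self.table["trait"] == trait]
        if t.empty:
            raise ConfigError(f"trait {trait!r} not present")
        cell = t.groupby(["accession", "environment"])["value"].mean()
        return cell.unstack("environment")

    def genotypic_values(self, trait: str) -> pd.Series:
        """Per-accession mean over environments (the study's genotypic value)."""
        return self.env_means(trait).mean(axis=1)


class Pedigree:
    """Acyclic parent graph over accessions; founders have no parents."""

    def __init__(self, entries: list[tuple[str, str | None, str | None]]):
        self._parents: dict[str, tuple[str | None, str | None]] = {}
        for line_id, mother, father in entries:
            if line_id in self._parents:
                raise PedigreeError(f"duplicate pedigree entry for {line_id!r}")
            self._parents[line_id] = (mother, father)
        for line_id, (mother, father) in self._parents.items():
            for p in (mother, father):
                if p is not None and p not in self._parents:
                    raise PedigreeError(f"parent {p!r} of {line_id!r} has no pedigree entry")
        g = nx.DiGraph()
        g.add_nodes_from(self._parents)
        for line_id, (mother, father) in self._parents.items():
            for p in (mother, father):
                if p is not None:
                    g.add_edge(p, line_id)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise PedigreeError(f"pedigree contains a cycle: {cycle}")
        self._graph = g

    @property
    def members(self) -> list[str]:
        return list(self._parents)

    def parents(self, line_id: str) -> tuple[str | None, str | None]:
        return self._parents[line_id]

    @property
    def founders(self) -> list[str]:
        return [l for l, (m, f) in self._parents.items() if m is None and f is None]

    def is_founder(self, line_id: str) -> bool:
        m, f = self._parents[line_id]
        return m is None and f is None

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self._graph))

    def ancestors(self, line_id: str) -> set[str]:
        return nx.ancestors(self._graph, line_id)

    def entries(self) -> list[tuple[str, str | None, str | None]]:
        return [(l, m, f) for l, (m, f) in self._parents.items()]


@dataclass
class ContigTriplet:
    """Homoeologous contigs from the A, B and D subgenomes around a target SNP.

    ``target_snp`` is (genome_label, 0-based offset, ref allele, alt allele);
    the ref allele is the base present in the stored target-genome sequence.
    """

    sequences: dict[str, str]  # genome label -> sequence over ACGT
    target_snp: tuple[str, int, str, str]

    def __post_init__(self) -> None:
        genome, offset, ref, alt = self.target_snp
        if genome not in self.sequences:
            raise ConfigError(f"target genome {genome!r} not among contigs")
        seq = self.sequences[genome]
        if not (0 <= offset < len(seq)):
            raise ConfigError("SNP offset outside its sequence")
        if seq[offset] != ref:
            raise ConfigError(
                f"ref allele {ref!r} does not match sequence base {seq[offset]!r} at offset {offset}"
            )
        if ref == alt:
            raise ConfigError("ref and alt alleles are identical")

    @property
    def target_genome(self) -> str:
        return self.target_snp[0]

    @property
    def off_genomes(self) -> list[str]:
        return [g for g in self.sequences if g != self.target_genome]

    def allele_sequence(self, allele: str) -> str:
        """Target-genome sequence carrying the given allele at the SNP."""
        genome, offset, ref, alt = self.target_snp
        if allele not in (ref, alt):
            raise ConfigError(f"allele {allele!r} is neither ref {ref!r} nor alt {alt!r}")
        seq = self.sequences[genome]
        return seq[:offset] + allele + seq[offset + 1 :]


@dataclass
class DHPopulation:
    """A doubled-haploid population from a biparental cross.

    Calls keep the panel's 0/1 allele coding; ``focal_alleles`` records the
    focal parent's allele per marker so analyses can orient effects to it.
    Each line carries one phenotype value (unreplicated trial).
    """

    name: str
    parent1: str  # focal parent
    parent2: str
    genotypes: GenotypeMatrix
    phenotypes: pd.Series | None = field(default=None)  # index = line ids
    focal_alleles: np.ndarray | None = field(default=None)  # parent1 allele per marker

    def __post_init__(self) -> None:
        if self.phenotypes is not None:
            extra = set(self.phenotypes.index) - set(self.genotypes.accession_ids)
            if extra:
                raise ConfigError(f"phenotyped lines without genotypes: {sorted(extra)[:5]}")

    def polymorphic_markers(self) -> list[str]:
        out = []
        for j, m in enumerate(self.genotypes.marker_ids):
            col = self.genotypes.calls[:, j]
            obs = col[col != MISSING]
            if obs.size and obs.min() != obs.max():
                out.append(m)
        return out
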