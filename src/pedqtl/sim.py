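"""Synthetic breeding-population generator.

Emulates the data structure of a pedigree-derived inbred wheat panel: a
founder set, a breeding pedigree producing fully inbred (doubled-haploid
style) lines with strong familial relatedness, biallelic genome-wide markers
on multi-linkage-group genetic maps, multi-environment phenotypes with a
binary kernel-texture locus of large fixed effect plus additive QTLs, DH
validation populations from biparental crosses, and homoeologous contig
triplets around a target SNP for primer design.

Model choices
-------------
* All lines are inbred; heterozygotes are never generated. A non-founder is
  the doubled product of a single meiosis of the F1 of its parents.
* Crossovers follow the Haldane (no-interference) model: recombination
  fraction r = (1 - exp(-2d/100)) / 2 for adjacent markers d cM apart, with
  independent assortment across linkage groups.
* Phenotype: y(line, env, rep) = mu + sum_q effect_q * x_q + kernel_effect*k
  + g_line + E_env + eps, with g ~ N(0, var_genotype) a polygenic line
  effect, E_env ~ N(0, var_environment) shared by all lines in an
  environment, eps ~ N(0, var_residual) per plot.
* Every stochastic call takes an explicit seed; there is no global state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import (
    ConfigError,
    ContigTriplet,
    DesignError,
    DHPopulation,
    GeneticMap,
    GenotypeMatrix,
    Pedigree,
    PhenotypeTable,
)

import pandas as pd

#: a pedigree specification is simply a validated parent graph
PedigreeSpec = Pedigree

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the structure of the study panel: 65 inbred lines in
    9 environments, broad-sense heritability near 0.385 from the variance
    triple (6.5, 7.3, 3.1) in trait units squared (flour-yield percentage
    points), a kernel locus with a large fixed effect, and additive QTLs
    with per-allele effects of 1.5-2.7 trait units.
    """

    n_founders: int = 12
    n_markers_per_lg: int = 100
    lg_lengths: list[float] = field(default_factory=lambda: [150.0] * 10)
    qtl_spec: list[tuple[str, float, float]] = field(default_factory=list)
    kernel_locus: tuple[str, float] | None = None
    kernel_locus_effect: float = 3.0
    var_genotype: float = 6.5
    var_environment: float = 7.3
    var_residual: float = 3.1
    n_environments: int = 9
    n_reps: int = 1
    mu: float = 64.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("var_genotype", "var_environment", "var_residual"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_founders < 2:
            raise ConfigError("need at least 2 founders")
        lgs = {self._lg_name(i) for i in range(len(self.lg_lengths))}
        for lg, pos, _ in self.qtl_spec:
            if lg not in lgs:
                raise ConfigError(f"QTL linkage group {lg!r} not in map")
            length = self.lg_lengths[int(lg.replace("LG", "")) - 1]
            if not (0 <= pos <= length):
                raise ConfigError(f"QTL position {pos} outside linkage group {lg}")

    @staticmethod
    def _lg_name(i: int) -> str:
        return f"LG{i + 1}"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "qtl_spec" in raw:
            raw["qtl_spec"] = [tuple(q) for q in raw["qtl_spec"]]
        if raw.get("kernel_locus") is not None:
            raw["kernel_locus"] = tuple(raw["kernel_locus"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            **{k: getattr(self, k) for k in (
                "n_founders", "n_markers_per_lg", "var_genotype", "var_environment",
                "var_residual", "n_environments", "n_reps", "mu", "seed",
                "kernel_locus_effect",
            )},
            "lg_lengths": list(self.lg_lengths),
            "qtl_spec": [list(q) for q in self.qtl_spec],
            "kernel_locus": list(self.kernel_locus) if self.kernel_locus else None,
        }
        Path(path).write_text(yaml.safe_dump(data))


def make_genetic_map(config: SimulationConfig, map_source: str = "synthetic") -> GeneticMap:
    """Evenly spaced markers on each linkage group (deterministic)."""
    rows = []
    for i, length in enumerate(config.lg_lengths):
        lg = config._lg_name(i)
        positions = np.linspace(0.0, length, config.n_markers_per_lg)
        for j, pos in enumerate(positions):
            rows.append((f"m{lg}_{j:04d}", lg, float(pos), map_source))
    return GeneticMap(
        pd.DataFrame(rows, columns=["marker_id", "linkage_group", "position_cm", "map_source"])
    )


def nearest_marker(gmap: GeneticMap, linkage_group: str, position_cm: float) -> str:
    """Id of the map marker closest to a (linkage group, cM) locus."""
    grp = gmap.group(linkage_group)
    if grp.empty:
        raise ConfigError(f"linkage group {linkage_group!r} not in map")
    i = (grp["position_cm"] - position_cm).abs().idxmin()
    return str(grp.loc[i, "marker_id"])


# ---------------------------------------------------------------------------
# meiosis


def _lg_blocks(gmap: GeneticMap) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per linkage group: (marker row indices in map order, adjacent Haldane r)."""
    t = gmap.table
    blocks = []
    for (_, _), sub in t.groupby(["map_source", "linkage_group"], sort=False):
        idx = sub.index.to_numpy()
        d = np.diff(sub["position_cm"].to_numpy())
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        blocks.append((idx, r))
    return blocks


def _meiosis_choices(gmap: GeneticMap, rng: np.random.Generator, n: int) -> np.ndarray:
    """n x n_markers array of 0/1 haplotype choices under the Haldane model."""
    m = len(gmap.table)
    choice = np.empty((n, m), dtype=np.int8)
    for idx, r in _lg_blocks(gmap):
        k = len(idx)
        start = rng.integers(0, 2, size=(n, 1))
        if k > 1:
            switches = (rng.random((n, k - 1)) < r).astype(np.int8)
            states = np.concatenate([start, switches], axis=1)
            np.bitwise_xor.accumulate(states, axis=1, out=states)
        else:
            states = start
        choice[:, idx] = states
    return choice


def simulate_gamete(
    parent: np.ndarray, gmap: GeneticMap, seed: int, n: int = 1
) -> np.ndarray:
    """Recombinant gamete(s) from a phased parent.

    ``parent`` is either a (2, n_markers) phased haplotype pair, or a
    1-D fully homozygous genotype (an inbred, trivially phased). Returns an
    (n, n_markers) array of gametes; marker order follows the sorted map.
    """
    parent = np.asarray(parent)
    if parent.ndim == 1:
        if not np.isin(parent, (0, 1)).all():
            raise ConfigError("unphased heterozygous parent: supply a (2, m) haplotype pair")
        parent = np.stack([parent, parent])
    if parent.ndim != 2 or parent.shape[0] != 2 or parent.shape[1] != len(gmap.table):
        raise ConfigError("parent must be a (2, n_markers) haplotype pair matching the map")
    rng = np.random.default_rng(seed)
    choice = _meiosis_choices(gmap, rng, n)
    return np.where(choice == 0, parent[0], parent[1])


def simulate_founders(
    config: SimulationConfig,
    gmap: GeneticMap,
    seed: int,
    founder_freqs: np.ndarray | None = None,
    founder_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Fully homozygous founder genotypes.

    Per-marker frequencies of allele 1 are drawn uniform on [0.1, 0.9]
    unless ``founder_freqs`` is given; each founder's call is an independent
    Bernoulli draw, so observed frequencies carry binomial sampling error.
    """
    if len(gmap.table) == 0:
        raise ConfigError("empty genetic map")
    rng = np.random.default_rng(seed)
    m = len(gmap.table)
    if founder_freqs is None:
        founder_freqs = rng.uniform(0.1, 0.9, size=m)
    else:
        founder_freqs = np.asarray(founder_freqs, dtype=float)
        if founder_freqs.shape != (m,):
            raise ConfigError("founder_freqs length must equal number of map markers")
    calls = (rng.random((config.n_founders, m)) < founder_freqs).astype(np.int8)
    if founder_ids is None:
        founder_ids = [f"f{i + 1:02d}" for i in range(config.n_founders)]
    return GenotypeMatrix(founder_ids, gmap.marker_ids, calls)


def simulate_pedigree_lines(
    spec: Pedigree,
    founders: GenotypeMatrix,
    gmap: GeneticMap,
    seed: int,
    return_origins: bool = False,
) -> GenotypeMatrix | tuple[GenotypeMatrix, np.ndarray]:
    """Propagate founder genotypes through a breeding pedigree.

    Each non-founder is one recombinant gamete from each parent (an F1),
    fixed to homozygosity by one further meiosis (DH-style), so every line
    is inbred. With ``return_origins`` the founder index each allele
    descends from is tracked through the identical crossover draws and
    returned as a parallel (n_lines, n_markers) array — the
    transmission-tagging oracle used to check identity-by-descent.
    """
    rng = np.random.default_rng(seed)
    founder_set = set(spec.founders)
    missing = founder_set - set(founders.accession_ids)
    if missing:
        raise ConfigError(f"founder genotypes missing for {sorted(missing)}")
    if founders.marker_ids != gmap.marker_ids:
        raise ConfigError("founder matrix markers must match the map")
    m = len(gmap.table)
    geno: dict[str, np.ndarray] = {}
    orig: dict[str, np.ndarray] = {}
    for fid in spec.founders:
        i = founders.accession_index(fid)
        geno[fid] = founders.calls[i].astype(np.int8)
        orig[fid] = np.full(m, i, dtype=np.int32)
    for line in spec.topological_order():  # acyclicity guaranteed by Pedigree
        if line in geno:
            continue
        mother, father = spec.parents(line)
        if mother is None or father is None:
            raise ConfigError(f"non-founder {line!r} must have two parents")
        # parents are inbred, so the gamete each contributes equals its
        # genotype; the F1's meiosis is where recombination happens
        f1_hap = (geno[mother], geno[father])
        f1_org = (orig[mother], orig[father])
        choice = _meiosis_choices(gmap, rng, 1)[0]
        geno[line] = np.where(choice == 0, f1_hap[0], f1_hap[1]).astype(np.int8)
        orig[line] = np.where(choice == 0, f1_org[0], f1_org[1])
    order = spec.members
    calls = np.stack([geno[l] for l in order])
    matrix = GenotypeMatrix(list(order), gmap.marker_ids, calls)
    if return_origins:
        return matrix, np.stack([orig[l] for l in order])
    return matrix


def build_breeding_pedigree(
    n_founders: int = 12, n_lines: int = 65, seed: int = 0, focal_id: str = "focal"
) -> Pedigree:
    """A breeding-program-shaped pedigree: founders, then successive crosses.

    Crosses preferentially reuse recent material (as selection in a breeding
    program does), producing the strong familial relatedness of a pedigree
    panel. The focal line is the last entry; its parents and grandparents
    are therefore identifiable for origin tracing.
    """
    if n_lines <= n_founders + 1:
        raise ConfigError("n_lines must exceed n_founders + 1")
    rng = np.random.default_rng(seed)
    entries: list[tuple[str, str | None, str | None]] = []
    ids = [f"f{i + 1:02d}" for i in range(n_founders)]
    entries.extend((fid, None, None) for fid in ids)
    n_derived = n_lines - n_founders - 1
    for i in range(n_derived):
        # geometric-ish bias toward recent lines
        w = np.arange(1, len(ids) + 1, dtype=float) ** 2
        w /= w.sum()
        mother, father = rng.choice(ids, size=2, replace=False, p=w)
        line = f"l{i + 1:02d}"
        entries.append((line, str(mother), str(father)))
        ids.append(line)
    entries.append((focal_id, ids[-1], ids[-2]))
    return Pedigree(entries)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    gmap: GeneticMap,
    seed: int,
    trait: str = "FlYd",
) -> PhenotypeTable:
    """Multi-environment phenotypes under the additive model (see module docs)."""
    rng = np.random.default_rng(seed)
    n = genotypes.n_accessions
    genetic = np.full(n, config.mu, dtype=float)
    for lg, pos, effect in config.qtl_spec:
        mid = nearest_marker(gmap, lg, pos)
        x = genotypes.column(mid).astype(float)
        if (x < 0).any():
            raise ConfigError(f"missing calls at QTL marker {mid}; impute first")
        genetic += effect * x
    if config.kernel_locus is not None:
        mid = nearest_marker(gmap, *config.kernel_locus)
        genetic += config.kernel_locus_effect * genotypes.column(mid).astype(float)
    if config.var_genotype > 0:
        genetic += rng.normal(0.0, np.sqrt(config.var_genotype), size=n)
    env_effects = rng.normal(0.0, np.sqrt(config.var_environment), size=config.n_environments)
    rows = []
    for e in range(config.n_environments):
        env = f"E{e + 1:02d}"
        for r in range(config.n_reps):
            eps = (
                rng.normal(0.0, np.sqrt(config.var_residual), size=n)
                if config.var_residual > 0
                else np.zeros(n)
            )
            vals = genetic + env_effects[e] + eps
            rows.extend(
                (acc, env, r + 1, trait, v) for acc, v in zip(genotypes.accession_ids, vals)
            )
    return PhenotypeTable(
        pd.DataFrame(rows, columns=["accession", "environment", "replicate", "trait", "value"])
    )


def kernel_types(genotypes: GenotypeMatrix, config: SimulationConfig, gmap: GeneticMap) -> pd.Series:
    """Binary kernel-type indicator (0 soft, 1 hard) read off the kernel locus."""
    if config.kernel_locus is None:
        raise ConfigError("config has no kernel locus")
    mid = nearest_marker(gmap, *config.kernel_locus)
    return pd.Series(genotypes.column(mid), index=genotypes.accession_ids, name="kernel_type")


def simulate_dh_population(
    parent1: np.ndarray,
    parent2: np.ndarray,
    n_lines: int,
    gmap: GeneticMap,
    seed: int,
    name: str = "DH",
    parent_ids: tuple[str, str] = ("P1", "P2"),
) -> DHPopulation:
    """Doubled-haploid lines from a biparental cross of two inbreds.

    Each line is one F1 gamete doubled, so exactly one meiosis of
    recombination separates it from the parents and the expected allele
    frequency is 0.5 at every parent-polymorphic marker. Calls keep the
    parental 0/1 coding; ``focal_alleles`` records parent1's allele per
    marker so downstream tests can orient effects.
    """
    parent1 = np.asarray(parent1, dtype=np.int8)
    parent2 = np.asarray(parent2, dtype=np.int8)
    if n_lines < 1:
        raise ConfigError("n_lines must be >= 1")
    for p in (parent1, parent2):
        if not np.isin(p, (0, 1)).all():
            raise ConfigError("DH parents must be inbred (codes 0/1, no missing)")
    if not (parent1 != parent2).any():
        warnings.warn(f"cross {name}: parents share alleles at every marker (monomorphic)")
    rng = np.random.default_rng(seed)
    choice = _meiosis_choices(gmap, rng, n_lines)
    calls = np.where(choice == 0, parent1, parent2).astype(np.int8)
    ids = [f"{name}_{i + 1:03d}" for i in range(n_lines)]
    matrix = GenotypeMatrix(ids, gmap.marker_ids, calls)
    return DHPopulation(
        name=name,
        parent1=parent_ids[0],
        parent2=parent_ids[1],
        genotypes=matrix,
        phenotypes=None,
        focal_alleles=parent1.copy(),
    )


# ---------------------------------------------------------------------------
# contig triplets


def simulate_contig_triplet(
    length: int,
    pairwise_divergence: float,
    snp_offset: int,
    alleles: tuple[str, str] = ("G", "A"),
    seed: int = 0,
    target_genome: str = "B",
    flank: int = 200,
    max_retries: int = 50,
) -> ContigTriplet:
    """Three homoeologous contigs from a common ancestor.

    Each subgenome branch substitutes bases independently at rate
    ``pairwise_divergence / 2`` so two contigs differ at about
    ``pairwise_divergence * length`` sites. The target SNP site is held
    invariant across genomes (the polymorphism exists only within the
    target genome, between varieties). For positive divergence the triplet
    is resampled until at least one genome-discriminating site (target
    differs from both others) lies within ``flank`` bases on each side of
    the SNP; at divergence 0 no such site can exist and the sequences are
    returned as-is (downstream genome-specific design then fails, which is
    the intended behaviour).
    """
    if not (0 <= pairwise_divergence < 0.2):
        raise ConfigError("pairwise_divergence must be in [0, 0.2)")
    if not (0 < snp_offset < length - 1):
        raise ConfigError("snp_offset must be interior to the sequence")
    ref, alt = alleles
    if ref == alt:
        raise ConfigError("alleles must differ")
    rng = np.random.default_rng(seed)
    rate = pairwise_divergence / 2.0
    genomes = ["A", "B", "D"]
    if target_genome not in genomes:
        raise ConfigError("target_genome must be one of A, B, D")

    achieved = 0.0
    for _ in range(max_retries):
        ancestor = rng.integers(0, 4, size=length)
        ancestor[snp_offset] = int(np.where(_BASES == ref)[0][0])
        seqs = {}
        for g in genomes:
            s = ancestor.copy()
            mut = rng.random(length) < rate
            mut[snp_offset] = False
            shift = rng.integers(1, 4, size=length)
            s[mut] = (s[mut] + shift[mut]) % 4
            seqs[g] = s
        tgt = seqs[target_genome]
        others = [seqs[g] for g in genomes if g != target_genome]
        disc = (tgt != others[0]) & (tgt != others[1])
        disc[snp_offset] = False
        left = disc[max(0, snp_offset - flank) : snp_offset].any()
        right = disc[snp_offset + 1 : snp_offset + 1 + flank].any()
        achieved = float(np.mean(seqs["A"] != seqs["B"]))
        if pairwise_divergence == 0 or (left and right):
            strings = {g: "".join(_BASES[s]) for g, s in seqs.items()}
            return ContigTriplet(strings, (target_genome, snp_offset, ref, alt))
    raise DesignError(
        f"no discriminating site within {flank} bp of the SNP after {max_retries} "
        f"draws (achieved pairwise divergence {achieved:.4f})"
    )


# ---------------------------------------------------------------------------
# study-condition bundle


@dataclass
class StudyPanel:
    """A full synthetic analogue of the study's association panel."""

    config: SimulationConfig
    gmap: GeneticMap
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    kernel_type: pd.Series
    qtl_markers: list[str]
    focal_id: str


def default_study_config(seed: int = 0) -> SimulationConfig:
    """Study conditions for the synthetic association panel.

    9 environments with the variance structure of the motivating trial
    (environment variance 7.3, plot residual 3.1 trait units squared), a
    dozen additive QTLs with per-allele effects of 1.5-2.7 trait units at
    minor-ish founder frequencies, a kernel locus worth 3 trait units, and
    a small polygenic background (0.8) so that the total genotypic
    variance lands near 6.5 and broad-sense heritability near 0.38.
    """
    rng = np.random.default_rng(seed)
    lg_lengths = [150.0] * 10
    n_qtl = 12
    qtl_spec = []
    lgs = rng.integers(0, len(lg_lengths), size=n_qtl)
    for i, lg_i in enumerate(lgs):
        pos = float(rng.uniform(5.0, lg_lengths[lg_i] - 5.0))
        effect = float(rng.uniform(1.5, 2.7))
        qtl_spec.append((f"LG{lg_i + 1}", pos, effect))
    return SimulationConfig(
        n_founders=12,
        n_markers_per_lg=100,
        lg_lengths=lg_lengths,
        qtl_spec=qtl_spec,
        kernel_locus=("LG5", 75.0),
        kernel_locus_effect=3.0,
        var_genotype=0.8,
        var_environment=7.3,
        var_residual=3.1,
        n_environments=9,
        n_reps=1,
        mu=64.0,
        seed=seed,
    )


def simulate_study_panel(
    seed: int,
    config: SimulationConfig | None = None,
    n_lines: int = 65,
    missing_rate: float = 0.02,
    qtl_founder_freq: float = 0.15,
    block_markers: int = 8,
    block_span_cm: float = 0.8,
    block_noise: float = 0.05,
) -> StudyPanel:
    """Generate the complete synthetic association panel in one call.

    Founder frequencies at the planted QTL markers are set to
    ``qtl_founder_freq`` (QTL alleles segregate at minor-ish frequency, as
    the mapped loci do) and at the kernel locus to 0.26 (roughly a quarter
    of lines hard-type).

    Each QTL sits at the centre of a dense local marker cluster
    (``block_markers`` markers over ``block_span_cm`` cM) whose founder
    haplotypes tag the QTL allele — carriers of the trait-raising allele
    share one ancestral block haplotype, non-carriers its complement, with
    a per-founder flip rate of ``block_noise`` standing in for ancestral
    recombination and genotyping error. This reproduces the LD blocks that
    surround mapped QTLs in a breeding panel; founder calls elsewhere are
    drawn independently (linkage equilibrium among founders).

    A fraction ``missing_rate`` of panel calls is masked at random — never
    at the QTL or kernel markers — so imputation is exercised on realistic
    input.
    """
    if config is None:
        config = default_study_config(seed)
    rng = np.random.default_rng(seed)

    base = make_genetic_map(config).table
    extra_rows = []
    cluster_ids: list[list[str]] = []
    qtl_markers: list[str] = []
    for qi, (lg, pos, _) in enumerate(config.qtl_spec):
        length = config.lg_lengths[int(lg.replace("LG", "")) - 1]
        centre = f"mq{qi}_c"
        qtl_markers.append(centre)
        extra_rows.append((centre, lg, float(pos), "synthetic"))
        ids = []
        offsets = np.linspace(-block_span_cm / 2, block_span_cm / 2, block_markers)
        for k, off in enumerate(offsets):
            p = float(np.clip(pos + off, 0.0, length))
            mid = f"mq{qi}_{k}"
            ids.append(mid)
            extra_rows.append((mid, lg, p, "synthetic"))
        cluster_ids.append(ids)
    gmap = GeneticMap(
        pd.concat(
            [base, pd.DataFrame(extra_rows, columns=base.columns)], ignore_index=True
        )
    )
    marker_pos = {m: i for i, m in enumerate(gmap.marker_ids)}

    freqs = rng.uniform(0.1, 0.9, size=len(gmap.table))
    for m in qtl_markers:
        freqs[marker_pos[m]] = qtl_founder_freq
    special = set(qtl_markers)
    if config.kernel_locus is not None:
        km = nearest_marker(gmap, *config.kernel_locus)
        freqs[marker_pos[km]] = 0.26
        special.add(km)

    pedigree = build_breeding_pedigree(config.n_founders, n_lines, seed=seed)
    founders = simulate_founders(config, gmap, seed=seed + 1, founder_freqs=freqs)
    # impose the ancestral block haplotypes around each QTL
    fcalls = founders.calls.copy()
    for centre, ids in zip(qtl_markers, cluster_ids):
        hap1 = rng.integers(0, 2, size=len(ids)).astype(np.int8)
        qtl_allele = fcalls[:, marker_pos[centre]]
        for k, mid in enumerate(ids):
            col = np.where(qtl_allele == 1, hap1[k], 1 - hap1[k]).astype(np.int8)
            flips = rng.random(col.shape) < block_noise
            col[flips] = 1 - col[flips]
            fcalls[:, marker_pos[mid]] = col
    founders = GenotypeMatrix(list(founders.accession_ids), list(founders.marker_ids), fcalls)

    genotypes = simulate_pedigree_lines(pedigree, founders, gmap, seed=seed + 2)
    phenotypes = simulate_phenotypes(genotypes, config, gmap, seed=seed + 3)
    ktype = kernel_types(genotypes, config, gmap)
    if missing_rate > 0:
        mask = rng.random(genotypes.calls.shape) < missing_rate
        keep_cols = [marker_pos[m] for m in special]
        mask[:, keep_cols] = False
        calls = genotypes.calls.copy()
        calls[mask] = -1
        genotypes = GenotypeMatrix(
            list(genotypes.accession_ids), list(genotypes.marker_ids), calls
        )
    return StudyPanel(
        config=config,
        gmap=gmap,
        pedigree=pedigree,
        genotypes=genotypes,
        phenotypes=phenotypes,
        kernel_type=ktype,
        qtl_markers=qtl_markers,
        focal_id="focal",
    )
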