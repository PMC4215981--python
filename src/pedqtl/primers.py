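"""Genome- and allele-specific PCR assay design for a polyploid, with
in-silico verification.

An array SNP assayed on one subgenome of hexaploid wheat is converted into
a gel-readable PCR marker in three steps:

1. the SNP's probe sequence is matched against homoeologous contigs to
   recover one contig per subgenome (A, B, D), the perfect-match contig
   being the target genome;
2. a genome-specific primer (GSP) pair is designed so that each primer's
   3'-terminal base sits on a site where the target genome differs from
   both homoeologs, with the SNP at roughly one third of the amplicon;
3. two allele-specific primers (ASPs) are designed whose 3' base is the
   SNP itself, with an artificial destabilising mismatch (a fixed
   transversion) at the third base from the 3' end; the ASP amplifies the
   short side of the one-third split together with the nearer GSP.

Each genotyping reaction contains both GSPs and one ASP: a template
matching the ASP allele yields two bands (GSP product + shorter ASP
product), a non-matching template one band, and an off-target subgenome
none. The in-silico PCR uses an engineering binding rule, not
thermodynamics: a primer binds iff its 3'-terminal base matches exactly,
it has at most 1 mismatch within its 3'-terminal 5 bases and at most 3
overall; amplicons are enumerated for all convergent primer pairs within
2 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.SeqUtils import MeltingTemp

from .core import ConfigError, ContigTriplet, DesignError

#: deterministic artificial-mismatch rule: substitute by the transversion partner
TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def primer_tm(seq: str) -> float:
    """Nearest-neighbour melting temperature under PCR-buffer salt conditions.

    50 mM monovalent cation, 1.5 mM Mg2+ (the assay buffer), 200 nM primer,
    Owczarzy (2008) magnesium correction.
    """
    return MeltingTemp.Tm_NN(seq, Na=50, Mg=1.5, dnac1=200, dnac2=200, saltcorr=7)


@dataclass
class DesignConstraints:
    primer_len: tuple[int, int] = (18, 26)
    #: ASPs anchor their 3' end on the SNP, so length is their only Tm lever;
    #: they are allowed to run longer than GSPs in AT-rich contexts
    asp_primer_len: tuple[int, int] = (15, 32)
    tm_range: tuple[float, float] = (55.0, 65.0)
    amplicon_range: tuple[int, int] = (150, 600)
    snp_fraction_band: tuple[float, float] = (0.233, 0.433)  # 1/3 +- 0.1
    annealing_range: tuple[float, float] = (55.0, 62.0)  # reported PCR program
    max_product: int = 2000


@dataclass
class ASPrimer:
    """Allele-specific primer with its engineered-mismatch annotation."""

    sequence: str
    allele: str  # the SNP allele this primer detects (target-strand base)
    mismatch_pos_from_3: int  # 1-based from the 3' end
    original_base: str
    substituted_base: str


@dataclass
class GSPDesign:
    """Genome-specific primer pair and its amplicon on the target contig."""

    forward: str
    reverse: str
    amplicon_start: int  # 0-based half-open on the target contig
    amplicon_end: int
    forward_site: int  # 3'-end offset of the discriminating site each primer sits on
    reverse_site: int
    snp_fraction: float  # SNP position as a fraction of the amplicon from the forward primer
    tm_forward: float
    tm_reverse: float

    @property
    def product_size(self) -> int:
        return self.amplicon_end - self.amplicon_start


@dataclass
class PrimerSet:
    marker_id: str
    gsp_forward: str
    gsp_reverse: str
    asp_allele1: ASPrimer
    asp_allele2: ASPrimer
    asp_orientation: str  # "forward" | "reverse"
    expected_sizes: tuple[int, int]  # (GSP product, ASP product)
    annealing_range: tuple[float, float]
    gsp: GSPDesign | None = None


@dataclass
class BandPattern:
    reaction_id: str
    n_bands: int
    band_sizes: list[int]


# ---------------------------------------------------------------------------
# homoeolog search


def find_homoeologs(
    probe: str,
    contig_db: list[tuple[str, str]],
    snp_offset_in_probe: int,
    alt_allele: str,
    min_score: float | None = None,
) -> ContigTriplet:
    """Recover one contig per subgenome by local alignment of the probe.

    ``contig_db`` records are (id, sequence) with ids ending ``_A``/``_B``/
    ``_D`` naming the genome of origin. Scoring is match +1, mismatch -2,
    gap open -5, extend -1 (a BLASTN-like local search); the default
    ``min_score`` of 0.6x probe length admits ~97%-identical homoeologs
    and rejects unrelated sequences. The contig containing the probe as an
    exact substring is the target genome; the SNP's contig offset is the
    match start plus ``snp_offset_in_probe``.
    """
    probe = probe.upper()
    if min_score is None:
        min_score = 0.6 * len(probe)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1

    best: dict[str, tuple[float, str, str]] = {}  # genome -> (score, id, seq)
    for rec_id, seq in contig_db:
        tail = rec_id.rsplit("_", 1)[-1].upper()
        if tail not in ("A", "B", "D"):
            continue
        score = aligner.score(seq, probe)
        if tail not in best or score > best[tail][0]:
            best[tail] = (score, rec_id, seq)
    missing = [g for g in ("A", "B", "D") if g not in best or best[g][0] < min_score]
    if missing:
        raise DesignError(f"homoeolog set incomplete: no hit above score for genome(s) {missing}")

    target_genome = None
    for g, (_, _, seq) in best.items():
        if probe in seq:
            target_genome = g
            break
    if target_genome is None:
        raise DesignError("no contig with a perfect probe match; cannot assign target genome")
    target_seq = best[target_genome][2]
    offset = target_seq.index(probe) + snp_offset_in_probe
    ref = target_seq[offset]
    return ContigTriplet(
        {g: best[g][2] for g in ("A", "B", "D")},
        (target_genome, offset, ref, alt_allele),
    )


# ---------------------------------------------------------------------------
# genome-specific primers


def _discriminating_sites(triplet: ContigTriplet) -> np.ndarray:
    lens = {len(s) for s in triplet.sequences.values()}
    if len(lens) != 1:
        raise DesignError("contigs must be equal length (pre-aligned, no indels)")
    tgt = np.frombuffer(triplet.sequences[triplet.target_genome].encode(), dtype=np.uint8)
    others = [
        np.frombuffer(triplet.sequences[g].encode(), dtype=np.uint8)
        for g in triplet.off_genomes
    ]
    disc = (tgt != others[0]) & (tgt != others[1])
    disc[triplet.target_snp[1]] = False
    return np.where(disc)[0]


def design_gsp(
    triplet: ContigTriplet, constraints: DesignConstraints | None = None
) -> GSPDesign:
    """Design a genome-specific primer pair around the target SNP.

    Each primer's 3'-terminal base is placed exactly on a genome-
    discriminating site (target differs from both homoeologs), so under
    the 3'-exact-match binding rule neither primer can prime on the other
    subgenomes. Candidates are tried nearest-site-first and the first pair
    meeting length, Tm, amplicon-size and SNP-placement constraints wins;
    the SNP fraction band is tried with the SNP near the forward primer
    first, then mirrored.
    """
    c = constraints or DesignConstraints()
    seq = triplet.sequences[triplet.target_genome]
    s = triplet.target_snp[1]
    sites = _discriminating_sites(triplet)
    up = sites[sites < s][::-1]  # nearest first
    down = sites[sites > s]
    if up.size == 0 or down.size == 0:
        raise DesignError("no genome-specific site flanking the SNP")
    lmin, lmax = c.primer_len
    n_geom, n_tm = 0, 0
    for mirror in (False, True):  # forward-near preferred; retry mirrored
        lo, hi = c.snp_fraction_band if not mirror else (
            1 - c.snp_fraction_band[1], 1 - c.snp_fraction_band[0]
        )
        for d_up in up:
            for d_down in down:
                for lf in range(lmin, lmax + 1):
                    f5 = int(d_up) - lf + 1
                    if f5 < 0:
                        continue
                    fwd = seq[f5 : int(d_up) + 1]
                    for lr in range(lmin, lmax + 1):
                        r3 = int(d_down)
                        r5_end = r3 + lr  # half-open end of reverse footprint
                        if r5_end > len(seq):
                            continue
                        length = r5_end - f5
                        if not (c.amplicon_range[0] <= length <= c.amplicon_range[1]):
                            n_geom += 1
                            continue
                        frac = (s - f5) / length
                        if not (lo <= frac <= hi):
                            n_geom += 1
                            continue
                        tm_f = primer_tm(fwd)
                        if not (c.tm_range[0] <= tm_f <= c.tm_range[1]):
                            n_tm += 1
                            break  # longer lr will not fix the forward Tm
                        rev = revcomp(seq[r3:r5_end])
                        tm_r = primer_tm(rev)
                        if not (c.tm_range[0] <= tm_r <= c.tm_range[1]):
                            n_tm += 1
                            continue
                        return GSPDesign(
                            forward=fwd,
                            reverse=rev,
                            amplicon_start=f5,
                            amplicon_end=r5_end,
                            forward_site=int(d_up),
                            reverse_site=int(d_down),
                            snp_fraction=frac,
                            tm_forward=tm_f,
                            tm_reverse=tm_r,
                        )
    raise DesignError(
        "no feasible genome-specific pair: "
        f"{n_geom} candidates failed amplicon/SNP-placement geometry, "
        f"{n_tm} failed the Tm window {c.tm_range}"
    )


# ---------------------------------------------------------------------------
# allele-specific primers


def _engineer_mismatch(primer: str) -> tuple[str, str, str]:
    i = len(primer) - 3  # third nucleotide from the 3' end
    orig = primer[i]
    sub = TRANSVERSION[orig]
    return primer[:i] + sub + primer[i + 1 :], orig, sub


def design_asp(
    triplet: ContigTriplet,
    gsp: GSPDesign,
    constraints: DesignConstraints | None = None,
) -> tuple[ASPrimer, ASPrimer, str]:
    """Two allele-specific primers ending exactly on the SNP.

    Orientation is chosen so the ASP product covers the short side of the
    one-third split (reverse-oriented when the SNP is nearer the forward
    GSP). The base three positions from the 3' end is replaced by its
    transversion partner — one engineered mismatch against the primer's
    own allele template, two (including the 3' terminus) against the other
    allele. Returns (asp_allele1, asp_allele2, orientation); allele1 is
    the triplet's ref allele.
    """
    c = constraints or DesignConstraints()
    _, s, ref, alt = triplet.target_snp
    if ref == alt:
        raise ConfigError("identical alleles")
    orientation = "reverse" if gsp.snp_fraction < 0.5 else "forward"
    lmin, lmax = c.asp_primer_len

    def _build(length: int, allele: str) -> str:
        if orientation == "reverse":
            # anneals to the plus strand right of the SNP; 3' end on the SNP
            end = s + length
            if end > gsp.amplicon_end:
                raise DesignError("ASP footprint extends past the amplicon")
            template = triplet.allele_sequence(allele)[s:end]
            return revcomp(template)
        start = s - length + 1
        if start < gsp.amplicon_start:
            raise DesignError("ASP footprint extends past the amplicon")
        return triplet.allele_sequence(allele)[start : s + 1]

    chosen_len = None
    last_err: DesignError | None = None
    for length in range(lmin, lmax + 1):
        try:
            candidate = _build(length, ref)
        except DesignError as exc:
            last_err = exc
            continue
        if c.tm_range[0] <= primer_tm(candidate) <= c.tm_range[1]:
            chosen_len = length
            break
    if chosen_len is None:
        if last_err is not None:
            raise last_err
        raise DesignError(
            f"no ASP length in {c.asp_primer_len} meets the Tm window {c.tm_range}"
        )

    out = []
    for allele in (ref, alt):
        raw = _build(chosen_len, allele)
        mutated, orig, sub = _engineer_mismatch(raw)
        out.append(
            ASPrimer(
                sequence=mutated,
                allele=allele,
                mismatch_pos_from_3=3,
                original_base=orig,
                substituted_base=sub,
            )
        )
    return out[0], out[1], orientation


def design_primer_set(
    triplet: ContigTriplet,
    marker_id: str = "marker",
    constraints: DesignConstraints | None = None,
) -> PrimerSet:
    """Full assay design: GSP pair + two ASPs + expected band sizes."""
    c = constraints or DesignConstraints()
    gsp = design_gsp(triplet, c)
    asp1, asp2, orientation = design_asp(triplet, gsp, c)
    s = triplet.target_snp[1]
    if orientation == "reverse":
        asp_size = (s + len(asp1.sequence)) - gsp.amplicon_start
    else:
        asp_size = gsp.amplicon_end - (s - len(asp1.sequence) + 1)
    return PrimerSet(
        marker_id=marker_id,
        gsp_forward=gsp.forward,
        gsp_reverse=gsp.reverse,
        asp_allele1=asp1,
        asp_allele2=asp2,
        asp_orientation=orientation,
        expected_sizes=(gsp.product_size, asp_size),
        annealing_range=c.annealing_range,
        gsp=gsp,
    )


# ---------------------------------------------------------------------------
# in-silico PCR


def _binding_sites(primer: str, template: np.ndarray) -> np.ndarray:
    """Plus-strand windows (start offsets) where the primer binds.

    Binding rule: 3'-terminal base exact, <=1 mismatch in the 3'-terminal
    5 bases, <=3 mismatches overall; no gaps.
    """
    L = len(primer)
    n = template.size
    if n < L:
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(template, L)
    prim = np.frombuffer(primer.encode(), dtype=np.uint8)
    mism = windows != prim
    total = mism.sum(axis=1)
    last5 = mism[:, -5:].sum(axis=1)
    ok = (~mism[:, -1]) & (last5 <= 1) & (total <= 3)
    return np.where(ok)[0]


def insilico_pcr(
    primers: list[str],
    template: str,
    reaction_id: str = "reaction",
    max_product: int = 2000,
) -> BandPattern:
    """Predicted band pattern of one reaction on one template.

    All primers are scanned against both strands; every convergent
    forward/reverse site pair within ``max_product`` yields an amplicon.
    Distinct product sizes count as bands (0 bands is a valid outcome).
    """
    template = template.upper()
    tarr = np.frombuffer(template.encode(), dtype=np.uint8)
    rarr = np.frombuffer(revcomp(template).encode(), dtype=np.uint8)
    n = len(template)
    fwd_sites: list[tuple[int, int]] = []  # (5' start, 3' end) on plus strand
    rev_sites: list[tuple[int, int]] = []  # (5' end, 3' start) on plus strand
    for p in primers:
        L = len(p)
        for start in _binding_sites(p, tarr):
            fwd_sites.append((int(start), int(start) + L - 1))
        for start in _binding_sites(p, rarr):
            five = n - 1 - int(start)  # plus-strand position of the primer 5' end
            rev_sites.append((five, five - L + 1))
    sizes = set()
    for f5, f3 in fwd_sites:
        for r5, r3 in rev_sites:
            if f3 <= r3:  # convergent, non-crossing 3' ends
                size = r5 - f5 + 1
                if 0 < size <= max_product:
                    sizes.add(size)
    band_sizes = sorted(sizes)
    return BandPattern(reaction_id=reaction_id, n_bands=len(band_sizes), band_sizes=band_sizes)


# ---------------------------------------------------------------------------
# validation


@dataclass
class SpecificityReport:
    passed: bool
    failures: list[str]
    patterns: dict[str, BandPattern]
    notes: list[str] = field(default_factory=list)


def validate_primer_set(
    primer_set: PrimerSet,
    triplet: ContigTriplet,
    max_product: int = 2000,
) -> SpecificityReport:
    """Check genome and allele specificity of a designed assay in silico.

    PASS iff each allele's reaction gives 2 bands on its own allele
    template, 1 band on the other allele template, and 0 bands on both
    off-target subgenomes. The report enumerates every deviation.
    """
    _, _, ref, alt = triplet.target_snp
    gsps = [primer_set.gsp_forward, primer_set.gsp_reverse]
    reactions = {ref: primer_set.asp_allele1, alt: primer_set.asp_allele2}
    failures: list[str] = []
    notes: list[str] = []
    patterns: dict[str, BandPattern] = {}

    for rx_allele, asp in reactions.items():
        primers = gsps + [asp.sequence]
        for tpl_allele in (ref, alt):
            rx_id = f"ASP-{rx_allele}_on_allele-{tpl_allele}"
            bp = insilico_pcr(primers, triplet.allele_sequence(tpl_allele), rx_id, max_product)
            patterns[rx_id] = bp
            expected = 2 if tpl_allele == rx_allele else 1
            if bp.n_bands != expected:
                failures.append(f"{rx_id}: expected {expected} band(s), predicted {bp.n_bands}")
        for genome in triplet.off_genomes:
            rx_id = f"ASP-{rx_allele}_on_genome-{genome}"
            bp = insilico_pcr(primers, triplet.sequences[genome], rx_id, max_product)
            patterns[rx_id] = bp
            if bp.n_bands != 0:
                failures.append(f"{rx_id}: off-target amplification ({bp.n_bands} band(s))")

    for asp in (primer_set.asp_allele1, primer_set.asp_allele2):
        if asp.original_base == asp.substituted_base:
            notes.append(
                f"ASP for allele {asp.allele}: no engineered mismatch; "
                "reduced discrimination margin"
            )
    return SpecificityReport(passed=not failures, failures=failures, patterns=patterns, notes=notes)
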