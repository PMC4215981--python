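"""QTL classification, LD blocks, and pedigree origin tracing.

Significant markers are grouped into QTLs per (consensus map, linkage
group) by merging consecutive markers whose cM gap does not exceed a
threshold; markers located on different consensus maps are never merged
(overlap between maps is reported downstream, not resolved). Around each
QTL an LD block is the maximal run of map-adjacent markers in high r^2.
A QTL's route into the focal line is traced by flagging pedigree members
whose genotype inside the block matches the focal line's, and walking
carrier-only paths up the pedigree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .core import MISSING, ConfigError, GeneticMap, GenotypeMatrix, Pedigree


@dataclass
class QTL:
    """A map-position cluster of marker-trait associations."""

    id: str  # "<linkage group>.<index>"
    map_source: str
    linkage_group: str
    cm_start: float
    cm_end: float
    member_markers: list[str]
    mean_maf: float
    mean_q: float
    mean_r2_pct: float
    mean_effect: float

    @property
    def n_markers(self) -> int:
        return len(self.member_markers)


def classify_mtas(
    mtas: pd.DataFrame, gap_cm: float = 15.0
) -> tuple[list[QTL], list[str]]:
    """Group located MTAs into QTLs; returns (qtls, unlocated marker ids).

    ``mtas`` is the significant-marker table from ``assoc.mta_table``
    (columns marker_id, maf, q_value, r_squared_pct, effect, map_source,
    linkage_group, position_cm). Within each (map source, linkage group),
    markers sorted by cM are merged while the gap to the previous marker is
    at most ``gap_cm`` — the transitive closure of the gap relation — and
    QTLs are labelled ``<group>.<index>`` in position order. Unlocated
    markers are reported separately and excluded. The grouping is
    idempotent and invariant to input row order.
    """
    unlocated = sorted(mtas.loc[mtas["linkage_group"].isna(), "marker_id"])
    located = mtas.dropna(subset=["linkage_group", "position_cm"])
    qtls: list[QTL] = []
    for (source, lg), sub in located.groupby(["map_source", "linkage_group"], sort=True):
        sub = sub.sort_values(["position_cm", "marker_id"]).reset_index(drop=True)
        clusters: list[list[int]] = [[0]]
        for i in range(1, len(sub)):
            if sub.loc[i, "position_cm"] - sub.loc[i - 1, "position_cm"] <= gap_cm:
                clusters[-1].append(i)
            else:
                clusters.append([i])
        for idx, rows in enumerate(clusters, start=1):
            c = sub.loc[rows]
            qtls.append(
                QTL(
                    id=f"{lg}.{idx}",
                    map_source=str(source),
                    linkage_group=str(lg),
                    cm_start=float(c["position_cm"].min()),
                    cm_end=float(c["position_cm"].max()),
                    member_markers=list(c["marker_id"]),
                    mean_maf=float(c["maf"].mean()),
                    mean_q=float(c["q_value"].mean()),
                    mean_r2_pct=float(c["r_squared_pct"].mean()),
                    mean_effect=float(c["effect"].mean()),
                )
            )
    return qtls, unlocated


def qtl_table(qtls: list[QTL]) -> pd.DataFrame:
    """Per-QTL summary (member count and means of MAF, q, R^2 %, effect)."""
    return pd.DataFrame(
        [
            {
                "qtl": q.id,
                "n_markers": q.n_markers,
                "mean_maf": q.mean_maf,
                "mean_q": q.mean_q,
                "mean_r2_pct": q.mean_r2_pct,
                "mean_effect": q.mean_effect,
                "map_source": q.map_source,
                "linkage_group": q.linkage_group,
                "cm_start": q.cm_start,
                "cm_end": q.cm_end,
            }
            for q in qtls
        ]
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_r2(g: GenotypeMatrix, marker_a: str, marker_b: str) -> float:
    """Squared Pearson correlation of allele codes (r^2 for inbred biallelic data).

    Computed over accessions non-missing at both markers; NaN when either
    marker is monomorphic on the shared set.
    """
    a = g.column(marker_a)
    b = g.column(marker_b)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 3:
        raise ConfigError(
            f"fewer than 3 non-missing pairs for ({marker_a}, {marker_b})"
        )
    x, y = a[ok].astype(float), b[ok].astype(float)
    if x.std() == 0 or y.std() == 0:
        return math.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class LDBlock:
    linkage_group: str
    start_cm: float  # NaN when absent
    end_cm: float
    marker_ids: list[str]
    present: bool

    @property
    def size_cm(self) -> float:
        return self.end_cm - self.start_cm


def detect_ld_block(
    g: GenotypeMatrix,
    gmap: GeneticMap,
    qtl: QTL,
    r2_min: float = 0.7,
    min_markers: int = 3,
) -> LDBlock:
    """Maximal run of map-adjacent high-LD markers containing the QTL.

    Considers the genotyped markers of the QTL's linkage group (on its
    map) in cM order; a run extends while every adjacent-pair r^2 is at
    least ``r2_min``. The longest run containing at least one QTL member
    is the block, declared present iff it spans at least ``min_markers``
    markers. The result is invariant to 0/1 allele-code flips (r^2 is).
    """
    grp = gmap.group(qtl.linkage_group, qtl.map_source)
    genotyped = set(g.marker_ids)
    grp = grp[grp["marker_id"].isin(genotyped)].reset_index(drop=True)
    members = set(qtl.member_markers)
    ids = list(grp["marker_id"])
    runs: list[list[int]] = [[0]] if ids else []
    for i in range(1, len(ids)):
        try:
            r2 = ld_r2(g, ids[i - 1], ids[i])
        except ConfigError:
            r2 = math.nan
        if not math.isnan(r2) and r2 >= r2_min:
            runs[-1].append(i)
        else:
            runs.append([i])
    candidate = None
    for run in runs:
        if any(ids[i] in members for i in run):
            if candidate is None or len(run) > len(candidate):
                candidate = run
    if candidate is None or len(candidate) < min_markers:
        return LDBlock(qtl.linkage_group, math.nan, math.nan, qtl.member_markers, False)
    pos = grp["position_cm"]
    return LDBlock(
        qtl.linkage_group,
        float(pos.iloc[candidate[0]]),
        float(pos.iloc[candidate[-1]]),
        [ids[i] for i in candidate],
        True,
    )


def block_table(blocks: dict[str, LDBlock]) -> pd.DataFrame:
    """QTL -> block summary in the presence/range layout of the study."""
    rows = []
    for qtl_id, b in blocks.items():
        rows.append(
            {
                "qtl": qtl_id,
                "ld_block": "+" if b.present else "-",
                "linkage_group": b.linkage_group,
                "n_markers": len(b.marker_ids),
                "start_cm": b.start_cm,
                "end_cm": b.end_cm,
                "size_cm": b.size_cm if b.present else math.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# origin tracing


def block_similarity(
    g: GenotypeMatrix, block: LDBlock, focal: str
) -> pd.Series:
    """Per-accession fraction of block markers identical to the focal line.

    Computed over markers non-missing in both the accession and the focal
    line; accessions with no overlap get NaN with a warning.
    """
    markers = [m for m in block.marker_ids if m in set(g.marker_ids)]
    if not markers:
        raise ConfigError("no block markers genotyped")
    sub = g.subset_markers(markers)
    fi = sub.accession_index(focal)
    focal_calls = sub.calls[fi]
    if (focal_calls == MISSING).all():
        raise ConfigError(f"focal line {focal!r} has no calls in the block")
    obs = (sub.calls != MISSING) & (focal_calls != MISSING)[None, :]
    match = (sub.calls == focal_calls[None, :]) & obs
    n = obs.sum(axis=1)
    if (n == 0).any():
        warnings.warn("accessions with no shared block markers reported missing")
    with np.errstate(invalid="ignore"):
        frac = np.where(n > 0, match.sum(axis=1) / np.where(n > 0, n, 1), np.nan)
    return pd.Series(frac, index=sub.accession_ids, name="similarity")


@dataclass
class OriginAssignment:
    qtl_id: str
    carrier_similarities: pd.Series
    origin_class: str  # maternal | paternal | both | undetermined
    source_ancestors: list[str]
    discrepancy: bool
    missing_members: list[str] = field(default_factory=list)


def trace_origin(
    pedigree: Pedigree,
    similarities: pd.Series,
    focal: str,
    carrier_threshold: float = 0.9,
    qtl_id: str = "",
) -> OriginAssignment:
    """Trace a QTL block's route into the focal line through the pedigree.

    A pedigree member is a carrier when its block similarity to the focal
    line reaches ``carrier_threshold``. The origin class reads off the
    focal line's parents (only mother carries -> maternal; only father ->
    paternal; both -> both, the side cannot be determined; neither ->
    undetermined). Source ancestors are carriers reached from the focal
    line along carrier-only parent paths that themselves have no carrying
    parent; a non-founder source signals a discrepancy with the pedigree
    record (the block appears without a recorded transmitting parent).
    Members without similarity data are tolerated, treated as non-carriers
    and listed in ``missing_members``.
    """
    if focal not in pedigree.members:
        raise ConfigError(f"focal line {focal!r} not in pedigree")
    members = set(pedigree.members)
    missing = sorted(members - set(similarities.dropna().index))
    carrier = {
        m: bool(similarities.get(m, math.nan) >= carrier_threshold) for m in members
    }
    carrier[focal] = True  # the focal line matches itself by definition

    mother, father = pedigree.parents(focal)
    m_car = carrier.get(mother, False) if mother else False
    f_car = carrier.get(father, False) if father else False
    if m_car and f_car:
        origin_class = "both"
    elif m_car:
        origin_class = "maternal"
    elif f_car:
        origin_class = "paternal"
    else:
        origin_class = "undetermined"

    # walk carrier-only paths upward
    visited: set[str] = set()
    stack = [focal]
    while stack:
        line = stack.pop()
        if line in visited:
            continue
        visited.add(line)
        for parent in pedigree.parents(line):
            if parent is not None and carrier.get(parent, False):
                stack.append(parent)

    sources = []
    discrepancy = False
    for line in sorted(visited):
        parents = [p for p in pedigree.parents(line) if p is not None]
        carrying_parents = [p for p in parents if carrier.get(p, False)]
        if not carrying_parents:
            sources.append(line)
            if parents:  # non-founder carrier with no carrying parent
                discrepancy = True
    return OriginAssignment(
        qtl_id=qtl_id,
        carrier_similarities=similarities,
        origin_class=origin_class,
        source_ancestors=sources,
        discrepancy=discrepancy,
        missing_members=missing,
    )
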