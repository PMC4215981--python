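"""Delimited-text, FASTA and newick input/output.

Conventions
-----------
* Delimiter (comma vs tab) is auto-detected from the header line.
* Missing genotype calls are written as ``NA`` and accepted as ``NA`` or ``-``.
* Sequence offsets are 0-based half-open in memory; human-readable reports
  print 1-based inclusive coordinates.
* Readers validate and reject malformed input instead of coercing it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    MISSING,
    ConfigError,
    ContigTriplet,
    FormatError,
    GeneticMap,
    GenotypeMatrix,
    Pedigree,
    PhenotypeTable,
)

_MISSING_TOKENS = {"NA", "-", ""}


def _detect_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a genotype matrix: header row of marker ids, first column accession ids."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    delim = _detect_delimiter(lines[0])
    header = lines[0].split(delim)
    marker_ids = [h.strip() for h in header[1:]]
    accession_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(delim)
        if len(fields) != len(marker_ids) + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {len(marker_ids) + 1} fields, got {len(fields)}"
            )
        accession_ids.append(fields[0].strip())
        row = []
        for j, tok in enumerate(fields[1:]):
            tok = tok.strip()
            if tok in _MISSING_TOKENS:
                row.append(MISSING)
            elif tok in ("0", "1"):
                row.append(int(tok))
            else:
                raise FormatError(
                    f"{path}:{lineno}: unknown genotype code {tok!r} "
                    f"(accession {fields[0].strip()!r}, marker {marker_ids[j]!r})"
                )
        rows.append(row)
    return GenotypeMatrix(accession_ids, marker_ids, np.array(rows, dtype=np.int8))


def write_genotypes(matrix: GenotypeMatrix, path: str | Path, delimiter: str = "\t") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(delimiter.join(["accession"] + matrix.marker_ids) + "\n")
        for i, acc in enumerate(matrix.accession_ids):
            codes = ["NA" if c == MISSING else str(int(c)) for c in matrix.calls[i]]
            fh.write(delimiter.join([acc] + codes) + "\n")


def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header:
        raise FormatError(f"{path}: empty file")
    delim = _detect_delimiter(header)
    try:
        df = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def read_map(path: str | Path) -> GeneticMap:
    """Read a genetic map table (marker_id, linkage_group, position_cm, map_source).

    Rows out of order are sorted by (map source, linkage group, cM) on load.
    """
    df = _read_table(path, GeneticMap.REQUIRED)
    try:
        df["position_cm"] = df["position_cm"].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cM position ({exc})") from exc
    try:
        return GeneticMap(df)
    except ConfigError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_map(gmap: GeneticMap, path: str | Path, delimiter: str = "\t") -> None:
    gmap.table.to_csv(path, sep=delimiter, index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read long-format phenotype records (accession, environment, replicate, trait, value)."""
    df = _read_table(path, PhenotypeTable.REQUIRED)
    df = df[df["value"].astype(str).str.strip() != ""]  # missing plots permitted
    try:
        df["value"] = df["value"].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric trait value ({exc})") from exc
    df["replicate"] = df["replicate"].astype(int)
    try:
        return PhenotypeTable(df.reset_index(drop=True))
    except ConfigError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_phenotypes(pheno: PhenotypeTable, path: str | Path, delimiter: str = "\t") -> None:
    pheno.table.to_csv(path, sep=delimiter, index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a parent table (line_id, mother, father); blank/NA parent = founder side."""
    df = _read_table(path, ("line_id", "mother", "father"))

    def _norm(tok: str) -> str | None:
        tok = tok.strip()
        return None if tok in _MISSING_TOKENS else tok

    entries = [
        (str(r["line_id"]).strip(), _norm(str(r["mother"])), _norm(str(r["father"])))
        for _, r in df.iterrows()
    ]
    return Pedigree(entries)  # acyclicity enforced by the constructor


def write_pedigree(ped: Pedigree, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(["line_id", "mother", "father"]) + "\n")
        for line_id, mother, father in ped.entries():
            fh.write(delimiter.join([line_id, mother or "NA", father or "NA"]) + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercase sequence) pairs."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def _genome_label(record_id: str) -> str | None:
    tail = record_id.rsplit("_", 1)[-1].upper()
    return tail if tail in ("A", "B", "D") else None


def triplet_from_fasta(
    path: str | Path, target_snp: tuple[str, int, str, str]
) -> ContigTriplet:
    """Build a homoeologous contig triplet from a 3-record FASTA.

    Record ids must end in ``_A``, ``_B`` or ``_D`` naming the subgenome of
    each contig; the target SNP (genome, 0-based offset, ref, alt) is supplied
    separately because FASTA carries no variant annotation.
    """
    records = read_fasta(path)
    sequences: dict[str, str] = {}
    for rec_id, seq in records:
        label = _genome_label(rec_id)
        if label is None:
            raise FormatError(f"{path}: cannot infer genome label from record id {rec_id!r}")
        if label in sequences:
            raise FormatError(f"{path}: duplicate genome label {label!r}")
        sequences[label] = seq
    if set(sequences) != {"A", "B", "D"}:
        raise FormatError(f"{path}: need exactly genomes A, B, D; got {sorted(sequences)}")
    return ContigTriplet(sequences, target_snp)


def write_triplet_fasta(triplet: ContigTriplet, path: str | Path, prefix: str = "contig") -> None:
    write_fasta([(f"{prefix}_{g}", s) for g, s in sorted(triplet.sequences.items())], path)


# ---------------------------------------------------------------------------
# newick


def newick_string(node) -> str:
    """Serialise an ultrametric tree (see ``assoc.upgma``) as newick.

    Branch lengths are parent height minus child height; a two-leaf tree of
    height h renders as ``(A:h,B:h);``.
    """
    if node is None:
        raise ConfigError("empty tree")

    def _render(n, parent_height: float | None) -> str:
        if n.children:
            inner = ",".join(_render(c, n.height) for c in n.children)
            label = f"({inner})"
        else:
            label = n.name
        if parent_height is None:
            return label
        return f"{label}:{parent_height - n.height:g}"

    return _render(node, None) + ";"


def write_newick(node, path: str | Path) -> None:
    Path(path).write_text(newick_string(node) + "\n")


# ---------------------------------------------------------------------------
# primer table


PRIMER_TABLE_COLUMNS = [
    "marker",
    "gsp_forward",
    "gsp_reverse",
    "asp_allele1",
    "asp_allele2",
    "asp_orientation",
    "gsp_product_bp",
    "asp_product_bp",
    "annealing_min_c",
    "annealing_max_c",
]


def write_primer_table(primer_sets: list, path: str | Path, delimiter: str = "\t") -> None:
    """Write designed primer sets (see ``primers.PrimerSet``) as delimited text."""
    rows = []
    for ps in primer_sets:
        rows.append(
            {
                "marker": ps.marker_id,
                "gsp_forward": ps.gsp_forward,
                "gsp_reverse": ps.gsp_reverse,
                "asp_allele1": ps.asp_allele1.sequence,
                "asp_allele2": ps.asp_allele2.sequence,
                "asp_orientation": ps.asp_orientation,
                "gsp_product_bp": ps.expected_sizes[0],
                "asp_product_bp": ps.expected_sizes[1],
                "annealing_min_c": ps.annealing_range[0],
                "annealing_max_c": ps.annealing_range[1],
            }
        )
    pd.DataFrame(rows, columns=PRIMER_TABLE_COLUMNS).to_csv(path, sep=delimiter, index=False)
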