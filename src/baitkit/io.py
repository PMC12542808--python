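"""Readers and writers for the formats the toolkit touches.

FASTA goes through Biopython's SeqIO; GFF3 exon tables and TSVs go through
pandas.  Internally every coordinate is 0-based half-open; GFF3's 1-based
inclusive convention is converted exactly once, at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import GAP, ungap
from .errors import (
    AlignmentShapeError,
    CoordinateError,
    FormatError,
    NamingError,
)

_FASTA_WRAP = 80  # writer line width


@dataclass
class MultipleAlignment:
    """An in-memory multiple sequence alignment.

    ``records`` is an ordered list of ``(taxon_label, sequence)`` pairs; all
    sequences share the same length.  Sequences are stored upper-case over
    the alphabet ``{A, C, G, T, N, -, ?}`` plus degenerate IUPAC codes.
    """

    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentShapeError("alignment must contain >= 1 record")
        self.records = [(lab, seq.upper()) for lab, seq in self.records]
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def taxa(self) -> list[str]:
        return [lab for lab, _ in self.records]

    def sequence_of(self, taxon: str) -> str:
        for lab, seq in self.records:
            if lab == taxon:
                return seq
        raise KeyError(taxon)

    def columns(self) -> Iterator[str]:
        """Yield alignment columns as strings, one per position."""
        seqs = [seq for _, seq in self.records]
        for j in range(self.length):
            yield "".join(s[j] for s in seqs)

    def slice_columns(self, start: int, stop: int) -> "MultipleAlignment":
        """Column slice [start, stop); records that become all-gap are kept."""
        return MultipleAlignment(
            [(lab, seq[start:stop]) for lab, seq in self.records]
        )

    def ungapped_lengths(self) -> dict[str, int]:
        return {lab: len(ungap(seq)) for lab, seq in self.records}


@dataclass
class ExonCoordinateTable:
    """Exon intervals on each gene's ungapped reference sequence.

    ``entries`` holds ``(gene_id, exon_index, start, end)`` with 0-based
    half-open coordinates; within a gene, intervals are sorted and
    non-overlapping and exon indices count from 1 in coordinate order.
    """

    entries: list[tuple[str, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_gene: dict[str, list[tuple[int, int]]] = {}
        for gene, _idx, start, end in self.entries:
            if start >= end:
                raise CoordinateError(
                    f"{gene}: empty or reversed interval [{start}, {end})"
                )
            by_gene.setdefault(gene, []).append((start, end))
        for gene, ivals in by_gene.items():
            ivals.sort()
            for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise CoordinateError(
                        f"{gene}: overlapping exons [{s1},{e1}) and [{s2},..)"
                    )

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for gene, *_ in self.entries:
            seen.setdefault(gene)
        return list(seen)

    def exons_of(self, gene_id: str) -> list[tuple[int, int, int]]:
        """Sorted ``(exon_index, start, end)`` for one gene."""
        rows = [
            (idx, s, e) for g, idx, s, e in self.entries if g == gene_id
        ]
        rows.sort(key=lambda r: r[1])
        return rows


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read one aligned FASTA file; mixed case is normalized to upper."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    try:
        return MultipleAlignment(records)
    except AlignmentShapeError as exc:
        raise AlignmentShapeError(f"{path}: {exc}") from exc


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=lab, description="") for lab, seq in aln.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=_FASTA_WRAP)
        writer.write_file(recs)


def write_target_fasta(target_set, path: str | Path) -> None:
    """Write a capture target file with ``Taxon-LocusID`` headers.

    The hyphen is the reserved separator between taxon and locus, so taxon
    labels must not contain one.  Sequences are written ungapped, ordered by
    locus id then taxon.
    """
    recs = []
    for locus_id in sorted(target_set.loci):
        for taxon, seq in sorted(target_set.loci[locus_id]):
            if "-" in taxon:
                raise NamingError(
                    f"taxon label {taxon!r} contains the reserved '-' separator"
                )
            recs.append(
                SeqRecord(Seq(ungap(seq)), id=f"{taxon}-{locus_id}", description="")
            )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=_FASTA_WRAP)
        writer.write_file(recs)


_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def _gff_attribute(attrs: str, keys: Iterable[str]) -> str | None:
    fields = dict(
        kv.split("=", 1) for kv in attrs.strip().strip(";").split(";") if "=" in kv
    )
    for key in keys:
        if key in fields:
            return fields[key]
    return None


def read_exon_coordinates(path: str | Path) -> ExonCoordinateTable:
    """Read exon rows from a GFF3 file into an :class:`ExonCoordinateTable`.

    Only rows of feature type ``exon`` are consumed; each is assigned to the
    gene named by its ``gene`` (falling back to ``Parent``, then ``ID``)
    attribute.  GFF3's 1-based inclusive coordinates become 0-based
    half-open, and exons are renumbered 1.. in ascending coordinate order.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", names=_GFF_COLUMNS, header=None,
        dtype=str, keep_default_na=False,
    )
    if df.empty:
        raise FormatError(f"{path}: no GFF3 feature rows")
    exons = df[df["type"] == "exon"]
    by_gene: dict[str, list[tuple[int, int]]] = {}
    for _, row in exons.iterrows():
        gene = _gff_attribute(row["attributes"], ("gene", "Parent", "ID"))
        if gene is None:
            raise FormatError(
                f"{path}: exon row without gene/Parent/ID attribute"
            )
        start = int(row["start"]) - 1  # GFF 1-based inclusive -> half-open
        end = int(row["end"])
        by_gene.setdefault(gene, []).append((start, end))
    entries = []
    for gene in by_gene:
        for idx, (start, end) in enumerate(sorted(by_gene[gene]), start=1):
            entries.append((gene, idx, start, end))
    return ExonCoordinateTable(entries)


def write_exon_coordinates(
    table: ExonCoordinateTable, path: str | Path, source: str = "baitkit"
) -> None:
    """Write the table back to GFF3 (the inverse of :func:`read_exon_coordinates`)."""
    rows = []
    for gene, idx, start, end in table.entries:
        rows.append(
            [gene, source, "exon", start + 1, end, ".", "+", ".",
             f"gene={gene};exon_number={idx}"]
        )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_newick(path: str | Path):
    """Read a single newick tree (DendroPy, unrooted semantics)."""
    import dendropy

    return dendropy.Tree.get(
        path=str(path), schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
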