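"""Gene- and exon-level filtering cascade.

Candidate single-copy genes (one alignment per gene, possibly found under
several reference genomes) are reduced to a ranked exon panel:

1. gene filter — shortest ungapped sequence >= ``min_gene_len`` and at least
   ``min_taxa`` distinct taxa;
2. merge across reference genomes by cross-reference gene name;
3. split each gene alignment into exon alignments using reference
   coordinates, treating every exon as its own evolutionary unit (multi-exon
   genes are never re-stitched, which avoids chimeric sequences assembled
   from paralogous copies);
4. exon filter — alignment length >= ``min_exon_len`` and mean pairwise
   identity within ``[identity_lo, identity_hi]`` (all bounds inclusive);
5. final ranking — exons recovered under more reference genomes rank first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from ._util import GAP, UNAMBIGUOUS, ungap
from .config import DesignConfig
from .errors import (
    ArityError,
    CoordinateError,
    UndefinedIdentityError,
)
from .io import ExonCoordinateTable, MultipleAlignment


@dataclass
class GeneCandidate:
    """A candidate single-copy gene: alignment plus reference provenance."""

    gene_id: str
    reference_source: frozenset[str]
    alignment: MultipleAlignment

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        self.reference_source = frozenset(self.reference_source)
        if not self.reference_source:
            raise ValueError("reference_source must be non-empty")


@dataclass
class ExonLocus:
    """One exon alignment treated as an independent locus."""

    gene_id: str
    exon_index: int
    alignment: MultipleAlignment
    references: frozenset[str] = field(default_factory=frozenset)
    ungapped_min_len: int = 0
    mean_pairwise_identity: float = 0.0

    @property
    def locus_id(self) -> str:
        return f"{self.gene_id}_exon{self.exon_index}"


def filter_candidate_genes(
    candidates: list[GeneCandidate], config: DesignConfig
) -> list[GeneCandidate]:
    """Keep genes long enough and covered by enough taxa; order preserved.

    Both thresholds are inclusive ("minimum length", "at least N species").
    """
    kept = []
    for cand in candidates:
        ungapped = cand.alignment.ungapped_lengths()
        if min(ungapped.values()) < config.min_gene_len:
            continue
        if len(set(cand.alignment.taxa)) < config.min_taxa:
            continue
        kept.append(cand)
    return kept


def merge_across_references(
    per_reference_sets: dict[str, list[GeneCandidate]]
) -> list[GeneCandidate]:
    """Union candidate genes found under several reference genomes.

    Genes are keyed by their cross-reference gene id; a gene found under k
    references carries all k labels.  When the per-reference alignments
    differ, the representative is the one with more taxa (ties: longer
    alignment, then first reference label alphabetically).
    """
    merged: dict[str, GeneCandidate] = {}
    best_key: dict[str, tuple] = {}
    for ref in sorted(per_reference_sets):
        for cand in per_reference_sets[ref]:
            key = (
                -len(set(cand.alignment.taxa)),
                -cand.alignment.length,
                ref,
            )
            if cand.gene_id not in merged:
                merged[cand.gene_id] = replace(
                    cand, reference_source=frozenset({ref})
                )
                best_key[cand.gene_id] = key
            else:
                cur = merged[cand.gene_id]
                sources = cur.reference_source | {ref}
                if key < best_key[cand.gene_id]:
                    merged[cand.gene_id] = replace(
                        cand, reference_source=sources
                    )
                    best_key[cand.gene_id] = key
                else:
                    merged[cand.gene_id] = replace(
                        cur, reference_source=sources
                    )
    return [merged[g] for g in sorted(merged)]


def _ungapped_to_aligned(ref_aligned: str) -> list[int]:
    """Map ungapped position -> alignment column for one aligned sequence."""
    return [j for j, ch in enumerate(ref_aligned) if ch != GAP and ch != "?"]


def split_into_exons(
    gene: GeneCandidate,
    coords: ExonCoordinateTable,
    reference_taxon: str,
) -> list[ExonLocus]:
    """Slice a gene alignment into per-exon alignments.

    Coordinates refer to the reference taxon's ungapped sequence; each exon
    alignment is the column slice spanning that interval mapped through the
    reference's gap pattern (so internal gap columns stay in).  Sequences
    that become all-gap inside an exon are dropped from that exon.
    """
    try:
        ref_seq = gene.alignment.sequence_of(reference_taxon)
    except KeyError:
        raise CoordinateError(
            f"reference taxon {reference_taxon!r} absent from gene "
            f"{gene.gene_id}"
        ) from None
    col_of = _ungapped_to_aligned(ref_seq)
    exons = []
    for exon_index, start, end in coords.exons_of(gene.gene_id):
        if end > len(col_of):
            raise CoordinateError(
                f"{gene.gene_id} exon {exon_index}: [{start},{end}) beyond "
                f"ungapped reference length {len(col_of)}"
            )
        lo, hi = col_of[start], col_of[end - 1] + 1
        sub = gene.alignment.slice_columns(lo, hi)
        records = [
            (lab, seq) for lab, seq in sub.records
            if ungap(seq)  # drop sequences that are all gap in this exon
        ]
        if not records:
            continue
        aln = MultipleAlignment(records)
        exon = ExonLocus(
            gene_id=gene.gene_id,
            exon_index=exon_index,
            alignment=aln,
            references=gene.reference_source,
            ungapped_min_len=min(aln.ungapped_lengths().values()),
        )
        if aln.n_records >= 2:
            try:
                exon.mean_pairwise_identity = mean_pairwise_identity(aln)
            except UndefinedIdentityError:
                exon.mean_pairwise_identity = float("nan")
        exons.append(exon)
    return exons


def mean_pairwise_identity(alignment: MultipleAlignment) -> float:
    """Mean percent identity over all unordered sequence pairs.

    For each pair, only columns where both sequences carry an unambiguous
    residue (A/C/G/T) enter the denominator; pairs with no comparable column
    are excluded from the mean.  This matches the usual alignment-viewer
    convention and keeps the statistic stable under missing data.
    """
    if alignment.n_records < 2:
        raise ArityError("mean_pairwise_identity requires >= 2 sequences")
    seqs = [seq for _, seq in alignment.records]
    identities = []
    for a, b in itertools.combinations(seqs, 2):
        comparable = matches = 0
        for x, y in zip(a, b):
            if x in UNAMBIGUOUS and y in UNAMBIGUOUS:
                comparable += 1
                if x == y:
                    matches += 1
        if comparable:
            identities.append(100.0 * matches / comparable)
    if not identities:
        raise UndefinedIdentityError(
            "no sequence pair shares a comparable column"
        )
    return sum(identities) / len(identities)


def filter_exons(
    exons: list[ExonLocus], config: DesignConfig, use_ungapped_len: bool = False
) -> list[ExonLocus]:
    """Keep exons meeting the length and identity windows (inclusive).

    By default the length criterion applies to the exon alignment length;
    ``use_ungapped_len`` switches it to the shortest ungapped sequence.
    """
    kept = []
    for exon in exons:
        length = (
            exon.ungapped_min_len if use_ungapped_len
            else exon.alignment.length
        )
        if length < config.min_exon_len:
            continue
        mpi = exon.mean_pairwise_identity
        if not (config.identity_lo <= mpi <= config.identity_hi):
            continue
        kept.append(exon)
    return kept


def select_final_exons(
    per_reference_exons: dict[str, list[ExonLocus]],
    strict_sequence_identity: bool = False,
) -> list[ExonLocus]:
    """Rank surviving exons, prioritizing those shared by more references.

    Exons are keyed by ``(gene_id, exon_index)``.  By default cross-reference
    sharing is decided by key alone (the upstream merge is by gene name);
    ``strict_sequence_identity`` additionally requires byte-identical
    alignments before two references are counted as sharing an exon.
    """
    by_key: dict[tuple[str, int], ExonLocus] = {}
    refs_of: dict[tuple[str, int], set[str]] = {}
    for ref in sorted(per_reference_exons):
        for exon in per_reference_exons[ref]:
            key = (exon.gene_id, exon.exon_index)
            if key not in by_key:
                by_key[key] = exon
                refs_of[key] = set(exon.references) or {ref}
            else:
                if strict_sequence_identity and (
                    by_key[key].alignment.records != exon.alignment.records
                ):
                    continue
                refs_of[key] |= set(exon.references) or {ref}
    ranked = sorted(
        by_key,
        key=lambda key: (-len(refs_of[key]), key[0], key[1]),
    )
    return [
        replace(by_key[key], references=frozenset(refs_of[key]))
        for key in ranked
    ]


def trim_ragged_edges(
    alignment: MultipleAlignment, min_terminal_occupancy: float = 0.5
) -> MultipleAlignment:
    """Trim alignment ends while terminal-column occupancy is below a cutoff.

    An automated stand-in for manual inspection of alignment starts/ends for
    misassembled overhangs.  Occupancy counts unambiguous residues only.
    """
    n = alignment.n_records
    occ = []
    for col in alignment.columns():
        occ.append(sum(1 for ch in col if ch in UNAMBIGUOUS) / n)
    lo, hi = 0, alignment.length
    while lo < hi and occ[lo] < min_terminal_occupancy:
        lo += 1
    while hi > lo and occ[hi - 1] < min_terminal_occupancy:
        hi -= 1
    if lo == 0 and hi == alignment.length:
        return alignment
    if lo == hi:
        return alignment  # nothing would survive; leave untouched
    return alignment.slice_columns(lo, hi)
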