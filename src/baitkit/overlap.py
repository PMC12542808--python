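"""Locus overlap between bait panels.

Two panels can share loci either by cross-reference gene name (e.g. both map
to the same model-organism gene id) or by carrying literally identical
stretches of sequence.  The sequence mode is an exact-substring search, not
an alignment: a query counts as shared when it has an exact common substring
of at least ``min_exact_match`` bases with any panel sequence, on either
strand.
"""

from __future__ import annotations

import re

_VERSION_SUFFIX = re.compile(r"\.\d+$")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _normalize_gene_id(gene_id: str) -> str:
    return _VERSION_SUFFIX.sub("", gene_id.strip()).upper()


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def overlap_by_gene_id(
    panel_gene_ids: set[str], other_gene_ids: set[str]
) -> tuple[int, list[str]]:
    """Count genes shared by id, case-insensitively, ignoring ".N" versions."""
    panel = {_normalize_gene_id(g) for g in panel_gene_ids}
    other = {_normalize_gene_id(g) for g in other_gene_ids}
    shared = sorted(panel & other)
    return len(shared), shared


def overlap_by_sequence_search(
    panel_sequences: dict[str, str],
    query_sequences: dict[str, str],
    min_exact_match: int = 100,
    both_strands: bool = True,
) -> tuple[int, list[tuple[str, str]]]:
    """Count queries sharing an exact substring >= ``min_exact_match`` bp.

    Implemented as a k-mer membership scan with ``k = min_exact_match``: a
    shared substring of length >= k exists iff the two sequences share a
    k-mer.  Each query counts at most once (against the alphabetically first
    matching panel entry).
    """
    k = min_exact_match
    kmer_to_panel: dict[str, str] = {}
    for panel_id in sorted(panel_sequences):
        seq = panel_sequences[panel_id].upper()
        for i in range(len(seq) - k + 1):
            kmer_to_panel.setdefault(seq[i:i + k], panel_id)
    pairs = []
    for query_id in sorted(query_sequences):
        seq = query_sequences[query_id].upper()
        strands = [seq]
        if both_strands:
            strands.append(reverse_complement(seq))
        hit = None
        for strand_seq in strands:
            for i in range(len(strand_seq) - k + 1):
                panel_id = kmer_to_panel.get(strand_seq[i:i + k])
                if panel_id is not None:
                    hit = panel_id
                    break
            if hit:
                break
        if hit:
            pairs.append((query_id, hit))
    return len(pairs), pairs
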