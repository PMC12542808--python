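import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baitkit import (
    DesignConfig,
    ExonCoordinateTable,
    ExonLocus,
    GeneCandidate,
    MultipleAlignment,
    filter_candidate_genes,
    filter_exons,
    mean_pairwise_identity,
    merge_across_references,
    select_final_exons,
    split_into_exons,
    trim_ragged_edges,
)
from baitkit.errors import ArityError, CoordinateError, UndefinedIdentityError

from .conftest import random_alignment


def gene(gene_id, records, sources=("R1",)):
    return GeneCandidate(
        gene_id=gene_id, reference_source=frozenset(sources),
        alignment=MultipleAlignment(records),
    )


class TestFilterCandidateGenes:
    @pytest.mark.parametrize(
        "n_taxa,seq_len,kept",
        [(5, 499, False),   # below length threshold
         (3, 500, True),    # inclusive boundaries on both criteria
         (2, 600, False)],  # too few taxa
    )
    def test_boundaries(self, n_taxa, seq_len, kept):
        records = [(f"t{i}", "A" * seq_len) for i in range(n_taxa)]
        out = filter_candidate_genes([gene("g", records)], DesignConfig())
        assert bool(out) is kept

    def test_shortest_ungapped_sequence_decides(self):
        records = [("a", "A" * 500), ("b", "-" * 10 + "A" * 490),
                   ("c", "A" * 500)]
        out = filter_candidate_genes([gene("g", records)], DesignConfig())
        assert out == []  # b has 490 ungapped bases

    def test_matches_per_gene_hand_check(self, rng):
        # 10 genes with random lengths/taxon counts; oracle re-derives each
        config = DesignConfig(min_gene_len=50, min_taxa=3)
        genes, expected = [], []
        for i in range(10):
            n = int(rng.integers(2, 6))
            length = int(rng.integers(40, 70))
            g = gene(f"g{i}", [(f"t{j}", "A" * length) for j in range(n)])
            genes.append(g)
            expected.append(length >= 50 and n >= 3)
        out = filter_candidate_genes(genes, config)
        assert [g.gene_id for g in out] == [
            g.gene_id for g, keep in zip(genes, expected) if keep
        ]


class TestMergeAcrossReferences:
    def test_union_with_shared_gene_carrying_both_sources(self):
        recs = [("t1", "ACGT"), ("t2", "ACGT")]
        merged = merge_across_references({
            "R1": [gene("g1", recs), gene("g2", recs)],
            "R2": [gene("g2", recs), gene("g3", recs)],
        })
        assert [g.gene_id for g in merged] == ["g1", "g2", "g3"]
        by_id = {g.gene_id: g.reference_source for g in merged}
        assert by_id["g2"] == {"R1", "R2"}
        assert by_id["g1"] == {"R1"}

    def test_disjoint_inputs_sum(self):
        recs = [("t1", "ACGT")]
        merged = merge_across_references({
            "R1": [gene(f"a{i}", recs) for i in range(3)],
            "R2": [gene(f"b{i}", recs) for i in range(4)],
        })
        assert len(merged) == 7
        assert all(len(g.reference_source) == 1 for g in merged)

    def test_union_size_matches_inclusion_exclusion(self, rng):
        ids = {ref: set(rng.choice(30, size=12, replace=False).tolist())
               for ref in ("R1", "R2", "R3")}
        recs = [("t1", "ACGT")]
        merged = merge_across_references({
            ref: [gene(f"g{i}", recs) for i in sorted(ids[ref])]
            for ref in ids
        })
        a, b, c = ids["R1"], ids["R2"], ids["R3"]
        expected = (len(a) + len(b) + len(c)
                    - len(a & b) - len(a & c) - len(b & c) + len(a & b & c))
        assert len(merged) == expected

    def test_representative_has_most_taxa(self):
        small = [("t1", "ACGT"), ("t2", "ACGT")]
        big = [("t1", "ACGTAA"), ("t2", "ACGTAA"), ("t3", "ACGTAA")]
        merged = merge_across_references({
            "R1": [gene("g", small)], "R2": [gene("g", big)],
        })
        assert merged[0].alignment.n_records == 3
        assert merged[0].reference_source == {"R1", "R2"}


class TestSplitIntoExons:
    def test_gapless_mapping(self):
        g = gene("g", [("ref", "ACGT"), ("x", "TGCA")])
        coords = ExonCoordinateTable([("g", 1, 0, 2)])
        exons = split_into_exons(g, coords, "ref")
        assert exons[0].alignment.records == [("ref", "AC"), ("x", "TG")]

    def test_gap_column_included_inside_exon(self):
        # ref "A-CGT": ungapped positions 0..3 map to columns 0,2,3,4
        g = gene("g", [("ref", "A-CGT"), ("x", "AACGT")])
        coords = ExonCoordinateTable([("g", 1, 0, 2)])
        exons = split_into_exons(g, coords, "ref")
        assert exons[0].alignment.records == [("ref", "A-C"), ("x", "AAC")]

    def test_out_of_range_coordinates_raise(self):
        g = gene("g", [("ref", "ACGT"), ("x", "ACGT")])
        coords = ExonCoordinateTable([("g", 1, 0, 5)])
        with pytest.raises(CoordinateError):
            split_into_exons(g, coords, "ref")

    def test_all_gap_sequences_dropped_per_exon(self):
        g = gene("g", [("ref", "ACGTAC"), ("x", "---TAC")])
        coords = ExonCoordinateTable([("g", 1, 0, 3), ("g", 2, 3, 6)])
        exons = split_into_exons(g, coords, "ref")
        assert exons[0].alignment.taxa == ["ref"]
        assert exons[1].alignment.taxa == ["ref", "x"]

    def test_slices_concatenate_to_gene_columns(self, rng):
        aln = random_alignment(rng, 4, 60, labels=["ref", "a", "b", "c"])
        coords = ExonCoordinateTable(
            [("g", 1, 0, 20), ("g", 2, 20, 45), ("g", 3, 45, 60)]
        )
        exons = split_into_exons(gene("g", aln.records), coords, "ref")
        glued = {lab: "" for lab in aln.taxa}
        for exon in exons:
            for lab, seq in exon.alignment.records:
                glued[lab] += seq
        for lab, seq in aln.records:
            assert glued[lab] == seq


class TestMeanPairwiseIdentity:
    def test_identical_pair_is_100(self):
        aln = MultipleAlignment([("a", "ACGT"), ("b", "ACGT")])
        assert mean_pairwise_identity(aln) == 100.0

    def test_three_of_four_matching_is_75(self):
        aln = MultipleAlignment([("a", "ACGT"), ("b", "ACGA")])
        assert mean_pairwise_identity(aln) == 75.0

    def test_gap_and_ambiguity_columns_excluded_from_denominator(self):
        aln = MultipleAlignment([("a", "ACG-N"), ("b", "ACTTN")])
        # comparable columns: 0,1,2 -> 2 matches of 3
        assert mean_pairwise_identity(aln) == pytest.approx(200 / 3)

    def test_single_sequence_raises(self):
        with pytest.raises(ArityError):
            mean_pairwise_identity(MultipleAlignment([("a", "ACGT")]))

    def test_all_pairs_incomparable_raises(self):
        aln = MultipleAlignment([("a", "AC--"), ("b", "--GT")])
        with pytest.raises(UndefinedIdentityError):
            mean_pairwise_identity(aln)

    def test_invariant_to_order_and_shared_gap_column(self, rng):
        aln = random_alignment(rng, 5, 40, missing=0.1)
        base = mean_pairwise_identity(aln)
        shuffled = MultipleAlignment(aln.records[::-1])
        assert mean_pairwise_identity(shuffled) == pytest.approx(base)
        padded = MultipleAlignment(
            [(lab, seq + "-") for lab, seq in aln.records]
        )
        assert mean_pairwise_identity(padded) == pytest.approx(base)


class TestFilterExons:
    def _exon(self, length, identity, key=("g", 1)):
        aln = MultipleAlignment([("a", "A" * length), ("b", "A" * length)])
        return ExonLocus(gene_id=key[0], exon_index=key[1], alignment=aln,
                         mean_pairwise_identity=identity)

    @pytest.mark.parametrize(
        "length,identity,kept",
        [(500, 75.0, True),   # both boundaries inclusive
         (500, 98.0, True),
         (500, 100.0, False),  # exceeds conservation cap
         (499, 90.0, False),
         (500, 74.9, False)],
    )
    def test_boundaries(self, length, identity, kept):
        out = filter_exons([self._exon(length, identity)], DesignConfig())
        assert bool(out) is kept

    def test_idempotent_and_monotone(self, rng):
        exons = [
            self._exon(int(rng.integers(400, 700)),
                       float(rng.uniform(60, 100)), key=("g", i))
            for i in range(30)
        ]
        config = DesignConfig()
        once = filter_exons(exons, config)
        assert filter_exons(once, config) == once
        tighter = DesignConfig(min_exon_len=600, identity_lo=80,
                               identity_hi=95)
        assert set(
            (e.gene_id, e.exon_index) for e in filter_exons(exons, tighter)
        ) <= set((e.gene_id, e.exon_index) for e in once)


class TestSelectFinalExons:
    def _exon(self, gene_id, idx, refs):
        aln = MultipleAlignment([("a", "ACGT"), ("b", "ACGT")])
        return ExonLocus(gene_id=gene_id, exon_index=idx, alignment=aln,
                         references=frozenset(refs))

    def test_more_references_rank_first(self):
        out = select_final_exons({
            "R1": [self._exon("g2", 1, {"R1", "R2", "R3"}),
                   self._exon("g1", 1, {"R1"})],
        })
        assert (out[0].gene_id, len(out[0].references)) == ("g2", 3)

    def test_empty_input(self):
        assert select_final_exons({}) == []

    def test_order_matches_independent_sort(self, rng):
        refs_pool = ["R1", "R2", "R3"]
        exons = {}
        for i in range(20):
            k = int(rng.integers(1, 4))
            refs = set(rng.choice(refs_pool, size=k, replace=False))
            exons[(f"g{i:02d}", 1)] = refs
        per_ref = {r: [] for r in refs_pool}
        for (gid, idx), refs in exons.items():
            for r in refs:
                per_ref[r].append(self._exon(gid, idx, refs))
        out = select_final_exons(per_ref)
        expected = sorted(
            exons, key=lambda key: (-len(exons[key]), key[0], key[1])
        )
        assert [(e.gene_id, e.exon_index) for e in out] == expected
        assert len(out) == len(exons)  # no duplicate keys


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 2**31 - 1))
def test_mpi_matches_bruteforce_on_random_alignments(seed):
    """Mean pairwise identity equals an explicit per-pair recount."""
    rng = np.random.default_rng(seed)
    aln = random_alignment(rng, int(rng.integers(2, 7)), 30, missing=0.2)
    seqs = [s for _, s in aln.records]
    vals = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            num = den = 0
            for x, y in zip(seqs[i], seqs[j]):
                if x in "ACGT" and y in "ACGT":
                    den += 1
                    num += x == y
            if den:
                vals.append(100 * num / den)
    if not vals:
        with pytest.raises(UndefinedIdentityError):
            mean_pairwise_identity(aln)
    else:
        assert mean_pairwise_identity(aln) == pytest.approx(
            sum(vals) / len(vals)
        )


def test_trim_ragged_edges_removes_sparse_termini():
    aln = MultipleAlignment([
        ("a", "--ACGTAC--"),
        ("b", "--ACGTACGT"),
        ("c", "NNACGTACN-"),
    ])
    trimmed = trim_ragged_edges(aln, 0.5)
    assert trimmed.length == 6  # columns 2..7 survive
    assert trimmed.records[0][1] == "ACGTAC"
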