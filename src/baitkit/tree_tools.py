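"""Gene-tree tip masking and per-branch quartet concordance.

``mask_monophyletic_tips`` prunes duplicate same-taxon leaves (labelled
``taxon@copy``) from gene trees, keeping the copy with the most unambiguous
characters, so multi-copy gene trees become single-copy before concordance
analysis.

``quartet_frequencies`` scores, for every internal branch of an unrooted
species tree, what fraction of gene-tree-induced four-taxon topologies agree
with the species tree (the "main" topology) versus its two alternatives —
the quantities usually drawn as pie charts on species-tree figures.
Everything is unrooted internally: branches are identified by leaf
bipartitions, so the rooting of input files is irrelevant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import DataError

#: Separator between a taxon name and a gene-copy suffix in leaf labels.
COPY_SEP = "@"


def leaf_taxon(label: str) -> str:
    """Taxon part of a leaf label (``A@2`` -> ``A``)."""
    return label.split(COPY_SEP, 1)[0]


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=tree.as_string(schema="newick"), schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )


def mask_monophyletic_tips(
    tree: dendropy.Tree, char_counts: dict[str, int]
) -> dendropy.Tree:
    """Prune duplicate same-taxon leaves, keeping the most data-rich copy.

    Any maximal set of same-taxon leaves that is monophyletic, or forms a
    paraphyletic grade interrupted only by same-taxon leaves, collapses to
    the single leaf with the highest unambiguous-character count (ties:
    longer label, then lexicographically smaller label).  Leaves of taxa
    appearing once are never removed.  The input tree is not modified.

    Implementation: in the unrooted tree, repeatedly merge any two
    same-taxon leaves attached to the same node, suppressing the degree-2
    nodes that pruning creates.  Iterating this local rule to a fixed point
    collapses exactly the monophyletic clades and same-taxon-only grades.
    """
    work = _clone(tree)
    for lf in work.leaf_node_iter():
        if lf.taxon.label not in char_counts:
            raise DataError(f"leaf {lf.taxon.label!r} missing from char_counts")

    def quality(label: str) -> tuple:
        return (-char_counts[label], -len(label), label)

    work.is_rooted = False
    changed = True
    while changed:
        changed = False
        work.collapse_basal_bifurcation()  # treat the root as unrooted
        for node in list(work.preorder_node_iter()):
            groups: dict[str, list] = {}
            for child in node.child_nodes():
                if child.is_leaf():
                    groups.setdefault(
                        leaf_taxon(child.taxon.label), []
                    ).append(child)
            for taxon, leaves in groups.items():
                if len(leaves) < 2:
                    continue
                leaves.sort(key=lambda lf: quality(lf.taxon.label))
                for worse in leaves[1:]:
                    node.remove_child(worse)
                changed = True
            if changed:
                break
        if changed:
            work.suppress_unifurcations()
    return work


# ---------------------------------------------------------------------------
# quartet concordance


@dataclass(frozen=True)
class QuartetSupportRecord:
    """Quartet support around one internal species-tree branch.

    ``branch_id`` is the branch's leaf bipartition, printed as
    ``"A,B|C,D"`` with each side sorted.  ``f_main`` is the fraction of
    resolvable sampled quartets whose gene-tree topology matches the species
    tree; ``f_alt1`` pairs cluster 1 with cluster 3 and ``f_alt2`` pairs
    cluster 1 with cluster 4 (a fixed labelling convention).
    """

    branch_id: str
    n_quartets_sampled: int
    f_main: float
    f_alt1: float
    f_alt2: float


def _adjacency(tree: dendropy.Tree) -> dict:
    adj: dict = {}
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        adj.setdefault(edge.tail_node, set()).add(edge.head_node)
        adj.setdefault(edge.head_node, set()).add(edge.tail_node)
    return adj


def _topological_distances(tree: dendropy.Tree) -> tuple[dict[str, int], np.ndarray]:
    """Leaf-to-leaf path lengths in edges, via BFS over the node graph."""
    adj = _adjacency(tree)
    leaves = {
        lf: lf.taxon.label for lf in tree.leaf_node_iter()
    }
    labels = sorted(leaves.values())
    index = {lab: i for i, lab in enumerate(labels)}
    dist = np.full((len(labels), len(labels)), -1, dtype=int)
    for leaf_node, lab in leaves.items():
        i = index[lab]
        seen = {leaf_node: 0}
        frontier = [leaf_node]
        while frontier:
            nxt = []
            for node in frontier:
                for nb in adj.get(node, ()):
                    if nb not in seen:
                        seen[nb] = seen[node] + 1
                        nxt.append(nb)
            frontier = nxt
        for other_node, other_lab in leaves.items():
            dist[i, index[other_lab]] = seen[other_node]
    return index, dist


def induced_quartet(
    index: dict[str, int], dist: np.ndarray, a: str, b: str, c: str, d: str
) -> int | None:
    """Classify the quartet induced by a gene tree on four of its leaves.

    Returns 0 for ``ab|cd``, 1 for ``ac|bd``, 2 for ``ad|bc``, or None when
    the four leaves fall on a star (unresolved).  Uses the four-point
    condition on topological path lengths: the true split is the pairing
    with the strictly smallest sum of within-pair distances.
    """
    ia, ib, ic, id_ = index[a], index[b], index[c], index[d]
    sums = (
        dist[ia, ib] + dist[ic, id_],
        dist[ia, ic] + dist[ib, id_],
        dist[ia, id_] + dist[ib, ic],
    )
    best = min(sums)
    winners = [i for i, s in enumerate(sums) if s == best]
    return winners[0] if len(winners) == 1 else None


def _branch_clusters(tree: dendropy.Tree) -> list[tuple[list[set], str]]:
    """For each internal branch, the four leaf clusters around it.

    The tree is treated as unrooted.  For a branch joining nodes ``u``
    (tail) and ``v`` (head): the head-side clusters are the leaf sets of
    ``v``'s child subtrees, the tail-side clusters are the remaining leaves
    partitioned by ``u``'s other neighbors.  At multifurcations, subtrees
    beyond the first on a side are merged into the second cluster of that
    side.  Within each side, clusters are ordered by their smallest taxon
    label so the alt1/alt2 labelling is reproducible.
    """
    work = _clone(tree)
    work.is_rooted = False
    work.collapse_basal_bifurcation()
    all_leaves = set(_leaf_labels(work))

    def leafset(node) -> set:
        return {lf.taxon.label for lf in node.leaf_iter()}

    out = []
    for node in work.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        if node.parent_node.parent_node is None and (
            len(node.parent_node.child_nodes()) < 3
        ):
            # pseudo-root with <3 children: this edge is not internal
            continue
        head_subs = [leafset(ch) for ch in node.child_nodes()]
        below = leafset(node)
        parent = node.parent_node
        tail_subs = [
            leafset(sib) for sib in parent.child_nodes() if sib is not node
        ]
        above = all_leaves - below - set().union(*tail_subs) if tail_subs else (
            all_leaves - below
        )
        if above:
            tail_subs.append(above)
        if len(head_subs) < 2 or len(tail_subs) < 2:
            continue  # fewer than 4 clusters around this branch
        head_subs.sort(key=min)
        tail_subs.sort(key=min)
        clusters = [
            tail_subs[0],
            set().union(*tail_subs[1:]),
            head_subs[0],
            set().union(*head_subs[1:]),
        ]
        side_a = ",".join(sorted(below))
        side_b = ",".join(sorted(all_leaves - below))
        branch_id = "|".join(sorted([side_a, side_b]))
        out.append((clusters, branch_id))
    return out


def quartet_frequencies(
    species_tree: dendropy.Tree,
    gene_trees: list[dendropy.Tree],
    max_quartets_per_branch: int | None = None,
    seed: int | None = None,
) -> list[QuartetSupportRecord]:
    """Per-branch quartet concordance of gene trees with a species tree.

    For every internal species-tree branch, quartets take one taxon from
    each of the four surrounding clusters; each gene tree containing all
    four taxa votes for the induced topology.  With
    ``max_quartets_per_branch=None`` all quartets are enumerated, otherwise
    that many are drawn uniformly (seeded).  Frequencies are normalized over
    resolvable votes; a branch with zero resolvable quartets is still
    reported (``n_quartets_sampled == 0``, frequencies NaN).

    Gene trees must be single-copy (mask duplicate tips first); their taxa
    may be any subset of the species tree's taxa.
    """
    rng = np.random.default_rng(seed)
    gene_matrices = []
    for gt in gene_trees:
        index, dist = _topological_distances(gt)
        gene_matrices.append((index, dist))

    records = []
    for clusters, branch_id in _branch_clusters(species_tree):
        cluster_lists = [sorted(cl) for cl in clusters]
        combos = itertools.product(*cluster_lists)
        n_total = int(np.prod([len(cl) for cl in cluster_lists]))
        if max_quartets_per_branch is not None and (
            n_total > max_quartets_per_branch
        ):
            combos = (
                tuple(
                    cl[rng.integers(len(cl))] for cl in cluster_lists
                )
                for _ in range(max_quartets_per_branch)
            )
        votes = np.zeros(3, dtype=np.int64)
        for a, b, c, d in combos:
            for index, dist in gene_matrices:
                if not all(t in index for t in (a, b, c, d)):
                    continue
                # main pairs cluster1+cluster2: topology ab|cd
                topo = induced_quartet(index, dist, a, b, c, d)
                if topo is not None:
                    votes[topo] += 1
        n = int(votes.sum())
        if n:
            f_main, f_alt1, f_alt2 = (votes / n).tolist()
        else:
            f_main = f_alt1 = f_alt2 = float("nan")
        records.append(
            QuartetSupportRecord(
                branch_id=branch_id,
                n_quartets_sampled=n,
                f_main=f_main, f_alt1=f_alt1, f_alt2=f_alt2,
            )
        )
    return records
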