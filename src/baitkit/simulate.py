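"""Synthetic inputs for every stage of the toolkit.

Three generators cover the three input classes: per-gene ortholog
alignments with known exon boundaries (to exercise the design cascade),
per-sample per-locus recovery tables with a specimen-age covariate (to
exercise the capture-evaluation statistics), and gene-tree sets with
controlled discordance (to exercise tip masking and quartet concordance).

Every generator is a pure function of (config, seed): sequence evolution is
a per-site substitution process along a random bifurcating topology — no
indel realism — which is sufficient to make filter outcomes predictable
while keeping the generators dependency-free.  Each generator returns a
truth table alongside the data so tests can cross-validate the toolkit's
own measurement operations against the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._util import UNAMBIGUOUS
from .bait_design import TargetSet
from .capture_eval import LocusRecovery, SampleRecoveryRecord
from .io import ExonCoordinateTable, MultipleAlignment
from .locus_selection import GeneCandidate, mean_pairwise_identity
from .tree_tools import COPY_SEP

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic world.

    Defaults mirror the regime of a real clade-specific design: 17 taxa of
    which 8 form the focal ingroup genus, genes of one to four exons a few
    hundred to ~1500 bp long (printed panels average near 1 kb), per-branch
    substitution probability 0.01 per site (pairwise identities land mostly
    in the high-80s/90s, the window the identity filter operates in), ~5%
    missing data, and a ~9% paralog-warning rate (an average of ~76 warnings
    across an 819-locus panel).
    """

    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (1, 4)
    exon_len: tuple[int, int] = (200, 1500)
    n_taxa: int = 17
    ingroup_size: int = 8
    branch_sub_prob: float = 0.01
    missing_fraction: float = 0.05
    taxon_dropout: float = 0.1
    paralog_rate: float = 0.09
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("branch_sub_prob", "missing_fraction",
                     "taxon_dropout", "paralog_rate"):
            val = getattr(self, name)
            if not (0 <= val <= 1):
                raise ValueError(f"{name}={val} outside [0, 1]")
        for name in ("exons_per_gene", "exon_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name}=({lo}, {hi}) is not a valid range")

    def taxon_labels(self) -> list[str]:
        ingroup = [f"Ing{i:02d}" for i in range(1, self.ingroup_size + 1)]
        n_out = self.n_taxa - self.ingroup_size
        outgroup = [f"Out{i:02d}" for i in range(1, n_out + 1)]
        return ingroup + outgroup

    def ingroup_taxa(self) -> set[str]:
        return {f"Ing{i:02d}" for i in range(1, self.ingroup_size + 1)}


# ---------------------------------------------------------------------------
# random topologies and sequence evolution


def _random_topology(labels: list[str], rng: np.random.Generator):
    """Random bifurcating tree as nested tuples of labels."""
    nodes: list = list(labels)
    order = rng.permutation(len(nodes))
    nodes = [nodes[i] for i in order]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = (nodes[i], nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return nodes[0]


def _evolve(node, seq: np.ndarray, p: float, rng: np.random.Generator,
            out: dict[str, np.ndarray]) -> None:
    """Per-site substitution with probability p along each edge."""
    mutate = rng.random(seq.size) < p
    child_seq = seq.copy()
    if mutate.any():
        # substitute to a uniformly chosen *different* base
        shifts = rng.integers(1, 4, size=int(mutate.sum()))
        idx = np.searchsorted(_BASES, child_seq[mutate])
        child_seq[mutate] = _BASES[(idx + shifts) % 4]
    if isinstance(node, str):
        out[node] = child_seq
    else:
        for child in node:
            _evolve(child, child_seq, p, rng, out)


def simulate_ortholog_alignments(
    sim_config: SimulationConfig,
) -> tuple[dict[str, GeneCandidate], ExonCoordinateTable, pd.DataFrame]:
    """Generate per-gene ortholog alignments with known exon structure.

    Returns ``(genes, exon_coordinates, truth)`` where ``truth`` has one row
    per (gene, exon) with its length, taxon coverage and realized mean
    pairwise identity, so downstream filter outcomes are predictable.
    Alignments are gapless except for injected missing data (random N sites
    plus occasional '-' terminal runs), so alignment length equals sequence
    length and exon coordinates need no gap mapping for the reference taxon
    (the first ingroup taxon, which is always retained ungapped).
    """
    cfg = sim_config
    rng = np.random.default_rng(cfg.seed)
    labels = cfg.taxon_labels()
    reference = labels[0]
    genes: dict[str, GeneCandidate] = {}
    coord_entries = []
    truth_rows = []
    for g in range(1, cfg.n_genes + 1):
        gene_id = f"G{g:04d}"
        n_exons = int(rng.integers(cfg.exons_per_gene[0],
                                   cfg.exons_per_gene[1] + 1))
        exon_lens = rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1,
                                 size=n_exons)
        total = int(exon_lens.sum())
        root = _BASES[rng.integers(0, 4, size=total)]
        topo = _random_topology(labels, rng)
        seqs: dict[str, np.ndarray] = {}
        _evolve(topo, root, cfg.branch_sub_prob, rng, seqs)
        # taxon dropout (reference always kept so coordinates stay valid)
        present = [
            lab for lab in labels
            if lab == reference or rng.random() >= cfg.taxon_dropout
        ]
        if len(present) < 2:
            present = labels[:2]
        records = []
        for lab in present:
            arr = seqs[lab].copy()
            if lab != reference and cfg.missing_fraction > 0:
                miss = rng.random(total) < cfg.missing_fraction
                arr[miss] = "N"
                if rng.random() < 0.3:  # occasional ragged terminal run
                    run = int(rng.integers(1, max(2, total // 10)))
                    arr[:run] = "-"
            records.append((lab, "".join(arr)))
        aln = MultipleAlignment(records)
        genes[gene_id] = GeneCandidate(
            gene_id=gene_id, reference_source=frozenset({"SIM"}),
            alignment=aln,
        )
        start = 0
        for e, elen in enumerate(exon_lens, start=1):
            end = start + int(elen)
            coord_entries.append((gene_id, e, start, end))
            sub = aln.slice_columns(start, end)
            try:
                mpi = mean_pairwise_identity(sub)
            except Exception:
                mpi = float("nan")
            truth_rows.append({
                "gene_id": gene_id, "exon_index": e, "length": int(elen),
                "n_taxa": len(present), "mean_pairwise_identity": mpi,
            })
            start = end
    truth = pd.DataFrame(truth_rows)
    return genes, ExonCoordinateTable(coord_entries), truth


# ---------------------------------------------------------------------------
# recovery tables


def simulate_recovery_table(
    panel: TargetSet,
    n_samples: int,
    sim_config: SimulationConfig,
    age_range: tuple[float, float] = (5.0, 95.0),
    base_recovery: float = 0.9,
    recovery_sd: float = 0.15,
    age_slope: float = 0.0,
    dropout: float = 0.05,
    reads_range: tuple[int, int] = (2_800_000, 13_800_000),
    on_target_range: tuple[float, float] = (0.134, 0.385),
) -> tuple[list[SampleRecoveryRecord], np.ndarray]:
    """Draw per-sample per-locus recovery records with an age covariate.

    Each sample gets an age (uniform on ``age_range``, the span of herbarium
    specimen ages a capture study typically spans) and a mean recovered
    fraction ``base_recovery + age_slope * age`` (slope default 0: no age
    effect, matching the negligible trends real data show); per-locus
    recovered fractions are normal around it (sd ``recovery_sd``), clipped
    to [0, 1], with ``dropout`` probability of recovering nothing.  Paralog
    depth warnings fire per locus at ``sim_config.paralog_rate`` (length
    warnings at 0.8x that rate, nested within depth warnings where
    possible).  Read totals and on-target fractions are uniform over the
    magnitudes printed in real capture studies.
    """
    cfg = sim_config
    rng = np.random.default_rng(cfg.seed + 1)
    lengths = panel.locus_lengths()
    loci = sorted(lengths)
    ages = rng.uniform(age_range[0], age_range[1], size=n_samples)
    records = []
    for s in range(n_samples):
        sample_id = f"S{s + 1:03d}"
        total_reads = int(rng.integers(reads_range[0], reads_range[1] + 1))
        mapped = int(total_reads * rng.uniform(*on_target_range))
        mean_frac = base_recovery + age_slope * ages[s]
        locus_recs = {}
        for locus in loci:
            target_len = lengths[locus]
            if rng.random() < dropout:
                recovered = 0
            else:
                frac = np.clip(
                    rng.normal(mean_frac, recovery_sd), 0.0, 1.0
                )
                recovered = int(round(frac * target_len))
            para_depth = bool(rng.random() < cfg.paralog_rate)
            para_len = para_depth and bool(rng.random() < 0.8)
            locus_recs[locus] = LocusRecovery(
                recovered_len=recovered, target_len=target_len,
                has_reads=True, has_seq=recovered > 0,
                paralog_len=para_len, paralog_depth=para_depth,
            )
        records.append(
            SampleRecoveryRecord(
                sample_id=sample_id, total_reads=total_reads,
                mapped_reads=mapped, loci=locus_recs,
            )
        )
    return records, ages


# ---------------------------------------------------------------------------
# gene trees


def _random_nni(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    """Apply one nearest-neighbor interchange on a random internal edge.

    Candidate edges are the internal edges of the *unrooted* topology: every
    internal node/parent pair below the root, plus — when the root is a
    degree-2 node whose children are both internal — the edge joining those
    two children (a parent-child swap across the root would be an unrooted
    no-op, so that edge needs an explicit sibling-pair swap).
    """
    candidates: list[tuple] = []
    root = tree.seed_node
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if (parent is not None and parent is not root
                and not node.is_leaf()
                and len(parent.child_nodes()) >= 2
                and len(node.child_nodes()) >= 2):
            candidates.append(("pc", node))
        if parent is root and len(root.child_nodes()) >= 3 and (
                not node.is_leaf() and len(node.child_nodes()) >= 2):
            # multifurcating root acts as an internal node itself
            candidates.append(("pc", node))
    root_children = root.child_nodes()
    if len(root_children) == 2 and all(
            not ch.is_leaf() and len(ch.child_nodes()) >= 2
            for ch in root_children):
        candidates.append(("root", None))
    if not candidates:
        return
    kind, node = candidates[int(rng.integers(len(candidates)))]
    if kind == "pc":
        parent = node.parent_node
        siblings = [ch for ch in parent.child_nodes() if ch is not node]
        sib = siblings[int(rng.integers(len(siblings)))]
        children = node.child_nodes()
        child = children[int(rng.integers(len(children)))]
        parent.remove_child(sib)
        node.remove_child(child)
        node.add_child(sib)
        parent.add_child(child)
    else:
        left, right = root.child_nodes()
        a_children = left.child_nodes()
        b_children = right.child_nodes()
        a = a_children[int(rng.integers(len(a_children)))]
        b = b_children[int(rng.integers(len(b_children)))]
        left.remove_child(a)
        right.remove_child(b)
        left.add_child(b)
        right.add_child(a)


def simulate_gene_trees(
    species_tree: dendropy.Tree,
    n_trees: int,
    discordance_prob: float,
    sim_config: SimulationConfig,
    duplicate_tip_prob: float = 0.0,
) -> list[dendropy.Tree]:
    """Gene trees = species tree, each independently NNI-perturbed.

    With probability ``discordance_prob`` a gene tree receives one random
    NNI on a random internal edge; otherwise it matches the species tree.
    ``duplicate_tip_prob`` optionally grafts a second copy of one random
    leaf (labelled ``taxon@2``) as its own sister, for tip-mask testing.
    All randomness comes from ``sim_config.seed``.
    """
    rng = np.random.default_rng(sim_config.seed + 2)
    newick = species_tree.as_string(schema="newick")
    trees = []
    for _ in range(n_trees):
        gt = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
        if rng.random() < discordance_prob:
            _random_nni(gt, rng)
        if rng.random() < duplicate_tip_prob:
            leaves = [lf for lf in gt.leaf_node_iter()]
            leaf = leaves[int(rng.integers(len(leaves)))]
            parent = leaf.parent_node
            new_internal = dendropy.Node()
            parent.remove_child(leaf)
            parent.add_child(new_internal)
            new_internal.add_child(leaf)
            copy = dendropy.Node()
            copy.taxon = gt.taxon_namespace.new_taxon(
                f"{leaf.taxon.label}{COPY_SEP}2"
            )
            new_internal.add_child(copy)
        trees.append(gt)
    return trees
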