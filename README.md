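# baitkit

Design and evaluation toolkit for clade-specific target-enrichment bait
sets in plant phylogenomics.

Target enrichment (hybrid capture) concentrates sequencing effort on a few
hundred putative single-copy nuclear loci, which makes it the method of
choice for degraded herbarium DNA and for resolving shallow radiations
where universal kits such as Angiosperms353 carry too little variation.
`baitkit` implements the complete design-and-validation loop for a custom
kit:

1. **Locus selection** — candidate single-copy genes (one multi-species
   alignment per gene, discovered against one or more reference genomes)
   are filtered on minimum length (default 500 bp of ungapped sequence) and
   taxon coverage (default ≥ 3 species), merged across references by
   cross-reference gene name, and split into exons. Each exon is kept as an
   independent locus — never re-stitched — to avoid chimeric assemblies
   from paralogous copies. Exons are then filtered on alignment length
   (≥ 500 bp) and mean pairwise identity, defined over all sequence pairs as

   *identity(i, j) = matching columns / columns where both i and j carry an
   unambiguous residue*,

   with the panel window 75% ≤ mean identity ≤ 98% (divergent enough to be
   informative, conserved enough to capture). Exons recovered under more
   reference genomes rank first in the final panel.
2. **Bait tiling** — per exon, one ingroup and one outgroup representative
   are chosen (fewest missing characters) and 80-nt baits are tiled at 2×
   density: a new bait every `round(80/2) = 40` bases, plus a terminal bait
   anchored at the 3′ end, then GC/N/duplicate QC.
3. **Overlap analysis** — loci shared with other kits, by normalized gene
   id or by exact shared substring (≥ 100 bp, either strand).
4. **Capture evaluation** — per-sample recovery statistics in the usual
   assembly-summary schema (reads, on-target %, loci with sequences above
   50%/75% of the target length, paralog warnings, total bases), their
   Average/Sum/min/max summaries, sample × locus heatmap matrices, and OLS
   R² for covariate trends (e.g. specimen age).
5. **Alignment statistics** — column-occupancy trimming (default 10%) and
   missing-data / variable-site / parsimony-informative-site counts.
6. **Tree tools** — masking of duplicate same-taxon tips in gene trees
   (keeping the copy with the most unambiguous characters) and per-branch
   quartet concordance: for every internal species-tree branch, the
   fraction of gene-tree quartets matching the species tree versus its two
   alternatives — the pie charts of a species-tree figure.
7. **Synthetic data** — seeded generators for ortholog alignments with
   known exon structure, recovery tables with an age covariate, and gene
   trees with controlled NNI discordance, so the whole pipeline runs and
   tests itself without any download.

## Worked example

Simulate a small design input, run the cascade, tile baits, and score
quartet concordance (all numbers below are the actual output of these
commands):

```bash
baitkit simulate genes --n-genes 8 --seed 5 --out sim
baitkit design --genes sim/genes --gff sim/exons.gff3 \
    --reference-taxon Ing01 --out design_out
# 16 exons retained of 20 candidates

printf 'Ing01\nIng02\nIng03\n' > ingroup.txt
baitkit tile --exons design_out --ingroup ingroup.txt --out tiled
# { "n_baits": 455, "n_rejected": 413, "total_bp": 17690, "n_loci": 16,
#   "mean_locus_len": 1105.63, "min_locus_len": 510.0, "max_locus_len": 1367.0 }
```

16 of 20 simulated exons pass the length/identity filters; the panel spans
17,690 bp of capture space across 16 loci, and 455 80-mers survive QC (the
rejected ones contain simulated Ns — the default QC tolerates none).

```bash
echo '((A,B),(C,(D,(E,F))));' > sp.nwk
baitkit simulate trees --species-tree sp.nwk --n-trees 20 \
    --discordance 0.4 --seed 5 --out gts
baitkit quartets --species-tree sp.nwk --gene-trees gts --out q.tsv
```

| branch | n | f_main | f_alt1 | f_alt2 |
|---|---|---|---|---|
| A,B\|C,D,E,F | 60 | 0.95 | 0.05 | 0.00 |
| A,B,C\|D,E,F | 80 | 0.80 | 0.10 | 0.10 |
| A,B,C,D\|E,F | 60 | 0.85 | 0.05 | 0.10 |

With 40% of gene trees one NNI away from the species tree, each internal
branch keeps a clear majority for the species-tree topology while the two
alternatives absorb the discordant minority.

The same operations are available as library functions
(`baitkit.filter_exons`, `baitkit.tile_baits`, `baitkit.summarize_stats`,
`baitkit.quartet_frequencies`, ...).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch at the given seed — gene
simulation, the filtering cascade, representative selection, bait tiling
and QC, capture-space statistics, recovery-table simulation and summary,
tip masking, and quartet concordance — printing stage diagnostics to
stderr and writing the results JSON to `--out`.
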