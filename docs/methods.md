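# Methods

This note documents the models, conventions, and numerical choices behind
`baitkit`, in the spirit of the methods documentation of established
scientific packages: what each operation computes, which defaults matter
and why, what the synthetic generators do and do not emulate, and where a
design choice was genuinely open.

## Character conventions

All sequence operations share one residue classification:

- **unambiguous residues**: `A C G T` — the only characters that count as
  states for identity, occupancy, variability, and parsimony informativeness;
- **gap**: `-`;
- **missing**: `N` and `?`, treated identically everywhere;
- **degenerate IUPAC codes** (`R Y S W K M B D H V`): never act as states;
  in baits they are kept verbatim but count toward the bait's
  missing-base fraction at half weight by default (a degenerate base
  hybridizes partially; a strict mode counts them fully).

"Ungapped length" strips `-` and `?` but keeps `N`: an N occupies a real
position in the molecule, whereas gaps and `?` are alignment padding.

Coordinates are 0-based half-open everywhere inside the package; GFF3's
1-based inclusive convention is converted exactly once at the file
boundary, which keeps all interval arithmetic (exon slicing, bait tiling)
free of off-by-one cases. The conversion is an involution (GFF → internal
→ GFF is the identity), and this is tested.

## Locus selection

**Gene filter.** A candidate gene survives when its *shortest* ungapped
sequence is ≥ `min_gene_len` (default 500 bp) and it covers ≥ `min_taxa`
(default 3) distinct taxa. Both thresholds are inclusive ("minimum",
"at least").

**Merging across references.** Candidate sets discovered against several
reference genomes are united by cross-reference gene id; a gene found under
k references carries all k labels. When per-reference alignments differ,
the representative is the alignment with more taxa (ties: longer alignment,
then first reference alphabetically) — more taxa means more information for
the downstream identity filter.

**Exon splitting.** Exon coordinates refer to a chosen reference taxon's
ungapped sequence and are mapped through its gap pattern, so internal gap
columns stay inside the exon slice. Sequences that are entirely gap within
an exon are dropped from that exon only. Exons are never re-stitched into
genes: each is an independent evolutionary unit end to end, a deliberate
guard against chimeric multi-exon assemblies when paralogous copies
co-assemble.

**Mean pairwise identity** is the mean over all unordered sequence pairs of
(matching columns)/(columns where both members carry an unambiguous
residue), × 100. Columns with a gap, missing, or degenerate code in either
member leave that pair's denominator; pairs with no comparable column leave
the mean. This is the common alignment-viewer semantics and is stable under
missing data: appending shared gap columns or permuting sequences cannot
change it (tested as invariants). The alternative readings (minimum or
maximum pair identity) were rejected because a single poor sequence would
then veto an otherwise well-conserved exon.

**Exon filter.** Length ≥ `min_exon_len` (default 500, applied to the
*alignment* length; a flag switches to shortest ungapped length) and
`identity_lo ≤ mpi ≤ identity_hi` (default 75–98, both inclusive). The
filter is idempotent and monotone in its thresholds (tested).

**Final ranking.** Exons are keyed by (gene id, exon index) and ranked by
the number of references in which they passed all filters (descending),
then key. Cross-reference sharing is decided by key, not by sequence
equality, because the upstream merge is by gene name; a strict mode
requiring byte-identical alignments exists for sensitivity analysis. The
ranked list plus a top-n cut reproduces the *procedure* of prioritizing
shared exons; it does not claim to reproduce any particular published
panel, whose final manual curation is not algorithmically specified.

**Edge trimming.** An optional automated stand-in for manual inspection of
alignment ends: terminal columns are trimmed while their unambiguous-residue
occupancy is below 50%. Off by default.

## Bait design

**Representatives.** Per exon, one ingroup and one non-ingroup sequence,
each chosen as the sequence with the fewest missing characters (ties:
longest ungapped, then alphabetical taxon). The rule is fully deterministic
so a fixed input yields a byte-identical bait file. A one-sided exon yields
a single representative plus a warning rather than an error: such loci are
still usable targets.

**Tiling.** `step = round(bait_len / tiling_density)` (80/2.0 → 40; a step
of 0 is a configuration error). Baits start at 0, step, 2·step, … up to
`L − bait_len`; when the last regular window does not land flush on the 3′
end, one extra bait anchored at `L − bait_len` is appended so no exon tail
is uncovered — maximizing coverage of the declared capture space at the
cost of one bait per non-flush locus. Sequences shorter than one bait yield
no baits (warning). Consequences, both tested exhaustively for L ∈ [1, 400]:
every base is covered by ≥ 1 bait, and every base at distance ≥ step from
both ends by ≥ 2 at 2× density.

**QC.** Defaults: GC within [0.25, 0.75], no missing bases
(`max_n = 0`), exact-duplicate sequences collapsed. Commercial
manufacturers apply additional undisclosed filters; no attempt is made to
emulate them, which is why a printed kit size is not a reproducible
quantity for this package.

**Capture space.** Per-locus reference length is the mean ungapped length
over the locus's (1–2) representative sequences — the same convention the
evaluation side uses for "mean target length", so designer and evaluator
agree by construction. The reported mean locus length uses half-away-from-
zero rounding to 2 decimals.

## Overlap analysis

Gene-id overlap is case-insensitive after stripping trailing version
suffixes (`.1`). Sequence overlap is exact-substring search, not alignment:
a query shares a locus when it has an exact common substring
≥ `min_exact_match` (default 100 bp) with a panel sequence on either strand,
implemented as a k-mer membership scan (a shared substring of length ≥ k
exists iff a shared k-mer does). Reverse-complement matching is on by
default because target-file strand is not guaranteed. Each query counts at
most once.

## Capture evaluation

A sample's row counts loci whose recovered length is **strictly greater**
than 50%/75% of the locus target length (the convention of ">50%"/">75%"
column headings; a flag flips to ≥). The per-sample on-target percentage is
mapped/total × 100 at 1 decimal. Column summaries report the arithmetic
mean at 1 decimal (half away from zero), exact sums, and min/max with the
attaining sample ids. One deliberate exception: the *summary* on-target
percentage is the ratio of the column sums (equivalently of the averaged
counts), matching how published assembly-statistics tables derive the
percentage printed next to the average mapped-read count; the mean of
per-row percentages is a different number and is not what such tables print.

Paralog flags are consumed as input, never recomputed: length- and
depth-based paralog detection belongs to the assembler and is out of scope.
Heatmap matrices cap displayed recovery fractions at 1.0 and use 0.0 for
absent loci; the companion paralog matrix scores 0–2 per cell (one point
per flag type). `linear_r2` is ordinary least squares, reported to 3
decimals, with constant-y defined as 0.0 and constant-x an error.

## Alignment statistics

Occupancy trimming removes columns where fewer than `min_col_occupancy`
(default 0.1) of sequences carry an unambiguous residue; it is idempotent
and can only reduce the missing-data percentage (tested). Missing data
counts all non-state cells — gaps, N/?, and degenerate codes — because the
distinction is not recoverable downstream and both inflate uncertainty the
same way. A column is variable with ≥ 2 distinct states, and
parsimony-informative with ≥ 2 states each in ≥ 2 sequences; `n_pi ≤
n_variable ≤ length` always. Percentages use 1 decimal, half away from zero.

## Tree tools

**Tip masking.** Leaves are labelled `taxon` or `taxon@copy`. Any maximal
same-taxon set forming a monophyletic clade, or a paraphyletic grade
interrupted only by same-taxon leaves, collapses to the copy with the most
unambiguous characters (ties: longer label, then lexicographically
smaller). The implementation repeatedly merges same-taxon leaves attached
to the same node of the *unrooted* tree, suppressing the degree-2 nodes
pruning creates; iterating this local rule to a fixed point collapses
exactly the clades and same-taxon grades while leaving interrupted copies
(e.g. two copies straddling another taxon) untouched. Singleton taxa are
never removed.

**Quartet concordance.** The species tree is handled unrooted; every
internal branch is identified by its leaf bipartition. Around a branch the
four taxon clusters are the two subtrees on each side (at multifurcations,
extra subtrees merge into the second cluster of their side; within a side,
clusters order by smallest taxon label so the alternative-topology
labelling is reproducible). For each quartet — one taxon per cluster — and
each gene tree containing all four taxa, the induced unrooted topology is
classified by the four-point rule on topological path lengths: the pairing
with the strictly smallest within-pair distance sum wins; ties (stars) are
unresolved and do not vote. "Main" pairs clusters 1+2 (the species-tree
pairing); "alt1" pairs cluster 1 with 3; "alt2" pairs 1 with 4 — an
arbitrary but fixed convention, since the usual figure legends do not
define which discordant topology is "first". Frequencies normalize over
resolvable votes; branches with zero resolvable quartets are reported with
n = 0 rather than dropped. Exhaustive mode enumerates all quartets;
sampling mode draws uniformly with a seeded generator and agrees with
exhaustive mode within binomial error (tested at n = 1000 on 8-taxon
fixtures). Local posterior probabilities are *not* computed: they belong
to coalescent species-tree software and have no closed form here.

## Synthetic data

The generators state a world and stay there; they are pure functions of
(config, seed).

- **Ortholog alignments**: a random bifurcating topology per gene; per-site
  substitution with probability 0.01 per branch (pairwise identities land
  mostly in the high 80s–90s, straddling the 75–98% filter window); 17 taxa
  with 8 ingroup (the scale of transcriptome panels used for clade-specific
  designs); 1–4 exons per gene of 200–1500 bp (published exon panels
  average near 1 kb); 5% missing data plus occasional ragged `-` termini;
  10% per-taxon dropout. No indels — alignment length equals sequence
  length, so exon boundaries are exact. The truth table records realized
  identity so tests can cross-validate the package's own measurements
  against the generator.
- **Recovery tables**: per-sample mean recovered fraction = base (0.9) +
  slope × age (slope 0 by default), per-locus draws normal (sd 0.15)
  clipped to [0, 1], 5% dropout; depth-based paralog warnings at rate 0.09
  (≈ 76 warnings on an 819-locus panel, the magnitude real tables print),
  length-based warnings nested at 0.8× that rate; read totals uniform on
  2.8–13.8 million and on-target fractions on 13.4–38.5%, the printed
  ranges of a real 23-sample experiment. Note the [0, 1] clipping censors
  draws when the base recovery sits near 1.0, attenuating a fitted age
  slope; slope-recovery checks therefore run at base 0.7, where the linear
  model actually holds.
- **Gene trees**: each gene tree equals the species tree or (with the
  stated discordance probability) differs by one random NNI. NNI candidate
  edges are the internal edges of the *unrooted* topology — including the
  edge through the root of the rooted representation, which requires an
  explicit sibling-pair swap because a naive parent–child swap across the
  root is an unrooted no-op. Optional duplicate-tip injection supports
  mask testing.

What a green test on synthetic data does **not** establish: realism of
indel structure, rate heterogeneity, coalescent branch lengths, or
assembler behavior. The generators exist to make the *logic* of every
operation checkable against known ground truth, not to imitate real data
distributions beyond their printed magnitudes.

## Known limitations

- The exact membership of any published panel is not reproducible from the
  ranked selection procedure alone (manual curation and vendor QC are not
  specified algorithmically); panel-level headline numbers are therefore
  exercised by property tests, not by value reproduction.
- Sequence-overlap search is exact-substring only; diverged homologs
  require an external aligner and are out of scope.
- Quartet sampling is uniform per cluster, not weighted by cluster size
  products, so sampled frequencies estimate the same per-branch quantity as
  exhaustive enumeration but with different per-quartet weights than some
  coalescent tools use internally.
- The per-sample statistics schema fixes the 50%/75% recovery thresholds
  as named columns; other thresholds are computed but surface only through
  the config.
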