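"""Representative selection, bait tiling, bait QC and capture-space stats.

From each surviving exon alignment, at most two representative sequences are
kept — one from the focal ingroup genus and one from any other genus — and
fixed-length baits are tiled along each ungapped representative at the
configured tiling density (2x by default: a new 80-mer every 40 bases, plus
a terminal bait anchored at the 3' end so no exon tail is left uncovered).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ._util import GAP, MISSING, IUPAC_DEGENERATE, round_half_away, ungap
from .config import DesignConfig
from .errors import EmptyInputError
from .locus_selection import ExonLocus


@dataclass(frozen=True)
class Bait:
    """One probe: a fixed-length window on an ungapped representative."""

    locus_id: str
    source_taxon: str
    start: int  # 0-based offset on the ungapped source sequence
    sequence: str
    gc_fraction: float
    n_fraction: float


@dataclass
class TargetSet:
    """Final target loci: ``locus_id -> [(taxon, ungapped sequence), ...]``."""

    loci: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def locus_lengths(self) -> dict[str, float]:
        """Per-locus reference length: mean ungapped length of its sequences."""
        return {
            locus: sum(len(ungap(s)) for _, s in seqs) / len(seqs)
            for locus, seqs in self.loci.items()
        }

    @property
    def capture_space_bp(self) -> int:
        return int(round_half_away(sum(self.locus_lengths().values())))


def _missing_count(seq: str) -> int:
    return sum(1 for ch in seq if ch == GAP or ch in MISSING)


def _pick_best(candidates: list[tuple[str, str]]) -> tuple[str, str]:
    # fewest missing characters; ties: longest ungapped, then taxon name
    return min(
        candidates,
        key=lambda rec: (_missing_count(rec[1]), -len(ungap(rec[1])), rec[0]),
    )


def select_representatives(
    exon: ExonLocus, ingroup_taxa: set[str], config: DesignConfig | None = None
) -> list[tuple[str, str]]:
    """Pick one ingroup and one non-ingroup representative for an exon.

    The representative on each side is the sequence with the fewest missing
    characters (gap/N/?), breaking ties by longest ungapped length and then
    alphabetical taxon label, so a fixed input always yields the same pair.
    When only one side is present a single representative is returned with a
    warning.  Returned sequences are ungapped.
    """
    if exon.alignment.n_records == 0:
        raise EmptyInputError(f"exon {exon.locus_id} has no sequences")
    ingroup = [
        (lab, seq) for lab, seq in exon.alignment.records if lab in ingroup_taxa
    ]
    outgroup = [
        (lab, seq) for lab, seq in exon.alignment.records
        if lab not in ingroup_taxa
    ]
    chosen = []
    for side, name in ((ingroup, "ingroup"), (outgroup, "non-ingroup")):
        if side:
            lab, seq = _pick_best(side)
            chosen.append((lab, ungap(seq)))
        else:
            warnings.warn(
                f"exon {exon.locus_id}: no {name} sequence; using a single "
                "representative",
                stacklevel=2,
            )
    return chosen


def build_target_set(
    exons: list[ExonLocus], ingroup_taxa: set[str],
    config: DesignConfig | None = None,
) -> TargetSet:
    loci = {}
    for exon in exons:
        loci[exon.locus_id] = select_representatives(exon, ingroup_taxa, config)
    return TargetSet(loci)


def _bait_fractions(
    seq: str, degenerate_weight: float = 0.5
) -> tuple[float, float]:
    gc = sum(1 for ch in seq if ch in "GC") / len(seq)
    n_like = sum(
        1.0 if ch in MISSING or ch == GAP else
        degenerate_weight if ch in IUPAC_DEGENERATE else 0.0
        for ch in seq
    )
    return gc, n_like / len(seq)


def tile_baits(
    locus_id: str,
    taxon: str,
    sequence: str,
    config: DesignConfig,
    strict_degenerate: bool = False,
) -> list[Bait]:
    """Tile fixed-length baits along one ungapped sequence.

    Starts are ``0, step, 2*step, ...`` up to the last start that still fits,
    with ``step = round(bait_len / tiling_density)``; if the final window
    does not land flush on the 3' end, one extra bait anchored at
    ``L - bait_len`` is appended.  Sequences shorter than one bait yield no
    baits (with a warning).  Degenerate IUPAC codes other than N are kept
    verbatim but count toward ``n_fraction`` at half weight by default
    (``strict_degenerate`` counts them fully).
    """
    sequence = sequence.upper()
    L = len(sequence)
    step = config.tiling_step  # raises ConfigError when it rounds to 0
    if L < config.bait_len:
        warnings.warn(
            f"{locus_id}/{taxon}: length {L} < bait length "
            f"{config.bait_len}; no baits tiled",
            stacklevel=2,
        )
        return []
    last = L - config.bait_len
    starts = list(range(0, last + 1, step))
    if last % step != 0:
        starts.append(last)  # terminal bait anchored at the 3' end
    starts = sorted(set(starts))
    weight = 1.0 if strict_degenerate else 0.5
    baits = []
    for start in starts:
        window = sequence[start:start + config.bait_len]
        gc, n_frac = _bait_fractions(window, degenerate_weight=weight)
        baits.append(
            Bait(
                locus_id=locus_id, source_taxon=taxon, start=start,
                sequence=window, gc_fraction=gc, n_fraction=n_frac,
            )
        )
    return baits


def tile_target_set(
    target_set: TargetSet, config: DesignConfig, **kwargs
) -> list[Bait]:
    baits = []
    for locus_id in sorted(target_set.loci):
        for taxon, seq in sorted(target_set.loci[locus_id]):
            baits.extend(tile_baits(locus_id, taxon, seq, config, **kwargs))
    return baits


def qc_baits(
    baits: list[Bait],
    gc_min: float = 0.25,
    gc_max: float = 0.75,
    max_n: float = 0.0,
) -> tuple[list[Bait], list[tuple[Bait, str]]]:
    """Filter baits on GC window, missing-base fraction, and exact duplicates.

    Returns ``(kept, rejected)`` where each rejected entry carries a reason.
    Exact-duplicate bait sequences collapse to the first occurrence.
    """
    kept: list[Bait] = []
    rejected: list[tuple[Bait, str]] = []
    seen: set[str] = set()
    for bait in baits:
        if not (gc_min <= bait.gc_fraction <= gc_max):
            rejected.append((bait, f"gc={bait.gc_fraction:.3f} outside "
                             f"[{gc_min}, {gc_max}]"))
        elif bait.n_fraction > max_n:
            rejected.append((bait, f"n_fraction={bait.n_fraction:.3f} > {max_n}"))
        elif bait.sequence in seen:
            rejected.append((bait, "duplicate sequence"))
        else:
            seen.add(bait.sequence)
            kept.append(bait)
    return kept, rejected


def capture_space_stats(target_set: TargetSet) -> dict:
    """Cumulative capture space and per-locus length summary.

    Per-locus length is the mean ungapped length over that locus's
    representative sequences; the reported mean locus length is rounded half
    away from zero to 2 decimals.
    """
    if not target_set.loci:
        raise EmptyInputError("target set has no loci")
    lengths = target_set.locus_lengths()
    values = list(lengths.values())
    return {
        "total_bp": target_set.capture_space_bp,
        "n_loci": len(values),
        "mean_locus_len": round_half_away(sum(values) / len(values), 2),
        "min_locus_len": min(values),
        "max_locus_len": max(values),
    }
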