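"""Small shared helpers: rounding and residue classification."""

from __future__ import annotations

import math

#: Characters treated as a true (unambiguous) nucleotide state.
UNAMBIGUOUS = frozenset("ACGT")

#: Alignment gap character.
GAP = "-"

#: Missing-data characters ("?" and "N" are equivalent throughout).
MISSING = frozenset("N?")

#: Everything that does NOT count as an unambiguous residue: the gap, the
#: missing codes, and any degenerate IUPAC code (R, Y, S, W, ...).
IUPAC_DEGENERATE = frozenset("RYSWKMBDHV")


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3).

    Python's built-in ``round`` uses banker's rounding; reported summary
    statistics here follow the half-away-from-zero convention instead.
    """
    factor = 10.0 ** ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    result = rounded / factor
    return result if ndigits > 0 else float(int(result))


def is_unambiguous(ch: str) -> bool:
    return ch in UNAMBIGUOUS


def ungap(seq: str) -> str:
    """Strip alignment padding (gaps and '?') from a sequence.

    'N' is kept: it occupies a real position in the molecule even though its
    state is unknown, whereas '-' and '?' are artifacts of the alignment.
    """
    return seq.replace(GAP, "").replace("?", "")


def count_unambiguous(seq: str) -> int:
    return sum(1 for ch in seq if ch in UNAMBIGUOUS)
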