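"""Column-occupancy trimming and alignment informativeness statistics.

Variable and parsimony-informative sites are counted on unambiguous
residues (A/C/G/T) only: gaps, N/?, and degenerate IUPAC codes never act as
character states, matching the convention of standard alignment summary
tools.  Missing data counts gaps and ambiguity codes alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._util import UNAMBIGUOUS, round_half_away
from .errors import EmptyInputError
from .io import MultipleAlignment


@dataclass(frozen=True)
class AlignmentStats:
    length: int
    pct_missing: float
    n_variable: int
    n_parsimony_informative: int
    pct_parsimony_informative: float


def _char_matrix(alignment: MultipleAlignment) -> np.ndarray:
    return np.array(
        [list(seq) for _, seq in alignment.records], dtype="U1"
    )


def trim_by_occupancy(
    alignment: MultipleAlignment, min_col_occupancy: float
) -> MultipleAlignment:
    """Drop columns whose unambiguous-residue occupancy is below the cutoff.

    Occupancy is the fraction of sequences carrying A/C/G/T in the column;
    the sequence set is unchanged.  If every column falls below the cutoff a
    warning is emitted and a zero-length alignment is returned.
    """
    mat = _char_matrix(alignment)
    occ = np.isin(mat, sorted(UNAMBIGUOUS)).mean(axis=0)
    keep = occ >= min_col_occupancy
    if not keep.any():
        warnings.warn(
            "occupancy trimming removed every column", stacklevel=2
        )
    kept = ["".join(row) for row in mat[:, keep]]
    return MultipleAlignment(
        [(lab, seq) for (lab, _), seq in zip(alignment.records, kept)]
    )


def alignment_informativeness(alignment: MultipleAlignment) -> AlignmentStats:
    """Missing-data percentage, variable and parsimony-informative sites.

    A column is variable when >= 2 distinct unambiguous states occur, and
    parsimony-informative when >= 2 states each occur in >= 2 sequences.
    Percentages are reported to 1 decimal, half away from zero.
    """
    if alignment.length == 0 or alignment.n_records == 0:
        raise EmptyInputError("empty alignment")
    mat = _char_matrix(alignment)
    is_state = np.isin(mat, sorted(UNAMBIGUOUS))
    n_rows, n_cols = mat.shape
    pct_missing = round_half_away(
        100.0 * (1.0 - is_state.sum() / (n_rows * n_cols)), 1
    )
    n_variable = n_pi = 0
    for j in range(n_cols):
        col = mat[is_state[:, j], j]
        if col.size == 0:
            continue
        _states, counts = np.unique(col, return_counts=True)
        if counts.size >= 2:
            n_variable += 1
            if (counts >= 2).sum() >= 2:
                n_pi += 1
    return AlignmentStats(
        length=n_cols,
        pct_missing=pct_missing,
        n_variable=n_variable,
        n_parsimony_informative=n_pi,
        pct_parsimony_informative=round_half_away(100.0 * n_pi / n_cols, 1),
    )
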