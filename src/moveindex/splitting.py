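"""Run splitting: trivialize thresholds, then cap row lengths.

Two refinement passes over the BWT run partition.  Thresholds-splitting cuts
every row at each distinct strictly-interior threshold offset it contains, so
that afterwards every row-relative threshold is either 0 or the row length
and a single up/down bit per symbol suffices.  Length-splitting then caps row
length at ``l_max = 2**length_bits - 1`` so the length and offset columns fit
their bit budgets.  Both passes preserve the partition (and therefore every
query answer); they only add rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_text import SIGMA, RowPartition
from .thresholds import ThresholdSet, map_thresholds_to_rows


@dataclass(frozen=True)
class SplitConfig:
    """Bit budget for the length/offset columns and the splitting switches.

    The shipped layouts use ``length_bits`` 11 (default rows), 10 (blocked)
    and 9 (sampled-id); other widths are accepted for experimentation.
    """

    length_bits: int = 11
    do_threshold_split: bool = True

    def __post_init__(self) -> None:
        if self.length_bits < 1:
            raise ValueError("length_bits must be >= 1")

    @property
    def l_max(self) -> int:
        return (1 << self.length_bits) - 1


@dataclass
class SplitReport:
    """Row counts through the two splitting stages, Table-1 style."""

    r_original: int
    rows_after_threshold_split: int
    rows_after_length_split: int

    @property
    def pct_threshold(self) -> float:
        added = self.rows_after_threshold_split - self.r_original
        return 100.0 * added / self.r_original

    @property
    def pct_length(self) -> float:
        added = self.rows_after_length_split - self.rows_after_threshold_split
        return 100.0 * added / self.rows_after_threshold_split

    def as_dict(self) -> dict:
        return {
            "r_original": self.r_original,
            "rows_after_threshold_split": self.rows_after_threshold_split,
            "rows_after_length_split": self.rows_after_length_split,
            "pct_threshold_splitting": self.pct_threshold,
            "pct_length_splitting": self.pct_length,
        }


def split_at_thresholds(rows: RowPartition, ts: ThresholdSet) -> RowPartition:
    """Cut rows at strictly-interior threshold offsets (coincident cuts merged).

    Each row gains at most sigma-1 cuts; afterwards every row-relative
    threshold is trivial (0 or the row length).
    """
    theta = map_thresholds_to_rows(ts, rows)
    own = np.zeros_like(theta, dtype=bool)
    dna = rows.sym >= 1
    own[np.flatnonzero(dna), rows.sym[dna] - 1] = True
    interior = (theta > 0) & (theta < rows.length[:, None]) & ~own
    to_cut = np.flatnonzero(interior.any(axis=1))
    if to_cut.size == 0:
        return rows
    sym_out: list[np.ndarray] = []
    len_out: list[np.ndarray] = []
    prev = 0
    cut_set = set(to_cut.tolist())
    for q in range(rows.row_count):
        if q not in cut_set:
            sym_out.append(rows.sym[q : q + 1])
            len_out.append(rows.length[q : q + 1])
            continue
        cuts = np.unique(theta[q][interior[q]])
        pieces = np.diff(np.concatenate([[0], cuts, [rows.length[q]]]))
        sym_out.append(np.full(pieces.size, rows.sym[q], dtype=rows.sym.dtype))
        len_out.append(pieces)
    length = np.concatenate(len_out)
    head = np.concatenate([[0], np.cumsum(length)[:-1]])
    out = RowPartition(sym=np.concatenate(sym_out), head=head, length=length)
    out.validate()
    return out


def split_by_length(rows: RowPartition, l_max: int) -> RowPartition:
    """Cap row length at ``l_max``.

    A row of length l becomes ceil(l / l_max) sub-rows, all but the last of
    length l_max; an exact multiple produces no zero-length remainder row.
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    if rows.length.max() <= l_max:
        return rows
    k = -(-rows.length // l_max)  # ceil division
    sym = np.repeat(rows.sym, k)
    length = np.full(int(k.sum()), l_max, dtype=rows.length.dtype)
    last = np.cumsum(k) - 1
    length[last] = rows.length - (k - 1) * l_max
    head = np.concatenate([[0], np.cumsum(length)[:-1]])
    out = RowPartition(sym=sym, head=head, length=length)
    out.validate()
    return out


def splitting_stats(
    before: RowPartition, mid: RowPartition, after: RowPartition
) -> SplitReport:
    """Row counts and percentage increases for the two splitting stages."""
    return SplitReport(
        r_original=before.row_count,
        rows_after_threshold_split=mid.row_count,
        rows_after_length_split=after.row_count,
    )
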