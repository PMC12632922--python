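"""Compressed representations of the destination-row id column.

The id column stores, per move row, the index of the row containing the
LF-image of the row head.  Because LF sorts stably, ids are non-decreasing
across the rows of any one symbol, which enables two compressed forms:

* **blocked** — the table is divided into fixed-size blocks of ``b`` rows; a
  B table stores, per block and per symbol, the id of the first row of that
  symbol at or after the block start, and each row keeps only the
  (non-negative) delta from its block's checkpoint;
* **sampled** — checkpoints every ``s`` rows (the S table), and no per-row
  field at all: the id is reconstructed at query time by scanning back to the
  last checkpoint, accumulating the BWT length of same-symbol rows passed,
  and fast-forwarding from the checkpoint's destination by that distance.

The terminator row is excluded everywhere: its stored 2-bit code aliases a
DNA symbol but its true character is the sentinel, and its destination is
always row 0 (the sentinel's LF-image is BWT offset 0), resolved specially.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .move_table import MoveTable

N_DNA = 4
CHECKPOINT_ABSENT = 0  # stored when a block has no row of a symbol; never read


class IdOverflowError(ValueError):
    """A delta does not fit the layout even at the smallest block size."""


@dataclass
class BlockTable:
    """Per-block, per-symbol destination-id checkpoints (the B table)."""

    b: int
    checkpoints: np.ndarray  # (n_blocks, 4) int64

    @property
    def n_checkpoints(self) -> int:
        return int(self.checkpoints.shape[0])


@dataclass
class SampleTable:
    """Per-sample, per-symbol destination-id checkpoints (the S table)."""

    s: int
    checkpoints: np.ndarray  # (n_samples, 4) int64

    @property
    def n_checkpoints(self) -> int:
        return int(self.checkpoints.shape[0])


def _block_checkpoints(
    code: np.ndarray, ids: np.ndarray, terminator_row: int, b: int
) -> tuple[np.ndarray, np.ndarray]:
    """Checkpoints restricted to each block, plus per-row deltas."""
    nrows = code.size
    n_blocks = -(-nrows // b)
    cp = np.full((n_blocks, N_DNA), CHECKPOINT_ABSENT, dtype=np.int64)
    delta = np.zeros(nrows, dtype=np.int64)
    for y in range(N_DNA):
        rows_y = np.flatnonzero(code == y)
        rows_y = rows_y[rows_y != terminator_row]
        if rows_y.size == 0:
            continue
        blk = rows_y // b
        first_blk, first_idx = np.unique(blk, return_index=True)
        cp[first_blk, y] = ids[rows_y[first_idx]]
        delta[rows_y] = ids[rows_y] - cp[blk, y]
    delta[terminator_row] = 0
    return cp, delta


def build_block_table(
    code: np.ndarray,
    ids: np.ndarray,
    terminator_row: int,
    b: int,
    delta_bits: int = 23,
) -> tuple[BlockTable, np.ndarray]:
    """Build the B table and per-row deltas, halving ``b`` on delta overflow.

    Mirrors the builder policy of shrinking the block size until every delta
    fits the fixed delta bit width of the blocked row layout.
    """
    if b < 1:
        raise ValueError("block size must be >= 1")
    limit = 1 << delta_bits
    while True:
        cp, delta = _block_checkpoints(code, ids, terminator_row, b)
        if int(delta.max(initial=0)) < limit:
            return BlockTable(b=b, checkpoints=cp), delta
        if b == 1:
            raise IdOverflowError(
                f"delta overflow at block size 1 (needs >= {delta_bits} bits)"
            )
        b = max(1, b // 2)


def build_sample_table(
    code: np.ndarray, ids: np.ndarray, terminator_row: int, s: int
) -> SampleTable:
    """Checkpoints every ``s`` rows: first at-or-after id per symbol."""
    if s < 1:
        raise ValueError("sampling rate must be >= 1")
    nrows = code.size
    n_samples = -(-nrows // s)
    cp = np.full((n_samples, N_DNA), CHECKPOINT_ABSENT, dtype=np.int64)
    starts = np.arange(n_samples) * s
    for y in range(N_DNA):
        rows_y = np.flatnonzero(code == y)
        rows_y = rows_y[rows_y != terminator_row]
        if rows_y.size == 0:
            continue
        pos = np.searchsorted(rows_y, starts, side="left")
        has = pos < rows_y.size
        cp[has, y] = ids[rows_y[pos[has]]]
    return SampleTable(s=s, checkpoints=cp)


def resolve_id_blocked(table: "MoveTable", q: int) -> int:
    """id = B[q // b][c] + delta[q]; the terminator row maps to row 0."""
    if q == table.terminator_row:
        return 0
    bt = table.block_table
    return int(bt.checkpoints[q // bt.b, table.code[q]] + table.delta[q])


def resolve_id_sampled(table: "MoveTable", q: int) -> int:
    """Reconstruct the id of row ``q`` from the S table by scan + fast-forward.

    Scan the rows from the last checkpoint up to (excluding) ``q``; the first
    row with q's symbol gives the starting offset ``f``, and the total BWT
    length of such rows gives the distance to add before fast-forwarding from
    the checkpoint's stored destination id.
    """
    if q == table.terminator_row:
        return 0
    st = table.sample_table
    y = int(table.code[q])
    start = (q // st.s) * st.s
    code = table.code
    term = table.terminator_row
    i0 = q
    d = 0
    for i in range(start, q):
        if i != term and code[i] == y:
            if i0 == q:
                i0 = i
            d += int(table.length[i])
    xi = int(st.checkpoints[q // st.s, y])
    v = int(table.f[i0]) + d
    length = table.length
    while v >= length[xi]:
        v -= int(length[xi])
        xi += 1
        if xi >= code.size:
            raise RuntimeError("fast-forward overran the table: index corruption")
    table._count_scan(q - start)
    return xi
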