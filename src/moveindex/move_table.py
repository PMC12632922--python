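"""The move structure: LF-mapping over the split row partition.

A move table row stores the symbol (2-bit code), the row length, the offset
``f`` of the row head's LF-image within its destination row, the destination
row id (directly, as a block delta, or not at all, depending on the variant)
and one trivial-threshold bit per mismatch symbol.  A BWT offset is carried
as a pair ``(u, v)``: row index and in-row offset, so navigation never needs
global coordinates.

The single sentinel character gets its own length-1 row.  Its 2-bit code
aliases symbol A; the table header records the row index (``terminator_row``)
and :meth:`MoveTable.char_at`, :meth:`MoveTable.reposition` and id resolution
special-case it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from . import id_compression as idc
from .core_text import (
    SENTINEL,
    SIGMA,
    RowPartition,
    SuffixBundle,
    Text,
    build_suffix_bundle,
    run_length_encode,
)
from .splitting import (
    SplitConfig,
    SplitReport,
    split_at_thresholds,
    split_by_length,
    splitting_stats,
)
from .thresholds import compute_thresholds, map_thresholds_to_rows

VARIANTS = ("default", "blocked", "sampled")

#: query-side symbol codes: A=0, C=1, G=2, T=3 (the 2-bit stored alphabet)
DNA_CODES = {c: i for i, c in enumerate("ACGT")}
SENTINEL_CHAR = -1  # char_at() result at the terminator position


class IndexCorruptionError(RuntimeError):
    pass


class BwtPosition(NamedTuple):
    """BWT offset as (row index u, in-row offset v), v in [0, row length)."""

    u: int
    v: int


class MoveRow(NamedTuple):
    c: int
    l: int
    f: int
    id: Optional[int]
    thr: tuple[int, ...]


@dataclass
class MoveTable:
    """Move structure over the final row partition; one of three variants."""

    variant: str
    n: int
    r_original: int
    code: np.ndarray  # (rows,) uint8, 2-bit symbol codes (A=0..T=3)
    length: np.ndarray  # (rows,) int64
    f: np.ndarray  # (rows,) int64
    thr: np.ndarray  # (rows, 4) int64 row-relative thresholds, col = DNA code
    terminator_row: int
    length_bits: int
    ids: Optional[np.ndarray] = None  # default variant
    delta: Optional[np.ndarray] = None  # blocked variant
    block_table: Optional[idc.BlockTable] = None
    sample_table: Optional[idc.SampleTable] = None
    split_report: Optional[SplitReport] = None
    true_ids: Optional[np.ndarray] = None  # build-time only, for cross-checks
    heads: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    ambiguous_substituted: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.heads is None:
            self.heads = np.concatenate([[0], np.cumsum(self.length)[:-1]])
        self.reset_counters()

    # -- bookkeeping -------------------------------------------------------
    def reset_counters(self) -> None:
        self.counters = {
            "lf_calls": 0,
            "fast_forward_steps": 0,
            "reposition_calls": 0,
            "reposition_scan_rows": 0,
            "id_scan_rows": 0,
        }

    def _count_scan(self, rows_scanned: int) -> None:
        self.counters["id_scan_rows"] += rows_scanned

    @property
    def row_count(self) -> int:
        return int(self.code.size)

    def row(self, q: int) -> MoveRow:
        rid = self.resolve_id(q) if self.variant != "sampled" else None
        return MoveRow(
            c=int(self.code[q]),
            l=int(self.length[q]),
            f=int(self.f[q]),
            id=rid,
            thr=tuple(int(x) for x in self.thr[q]),
        )

    @property
    def symbol_present(self) -> np.ndarray:
        """Which of the 4 DNA symbols occur in the text (terminator excluded)."""
        present = np.zeros(SIGMA, dtype=bool)
        for y in range(SIGMA):
            rows_y = np.flatnonzero(self.code == y)
            present[y] = bool((rows_y != self.terminator_row).any())
        return present

    # -- coordinate helpers ------------------------------------------------
    def position_of_offset(self, i: int) -> BwtPosition:
        u = int(np.searchsorted(self.heads, i, side="right") - 1)
        return BwtPosition(u, i - int(self.heads[u]))

    def offset_of_position(self, pos: BwtPosition) -> int:
        return int(self.heads[pos.u] + pos.v)

    def last_position(self) -> BwtPosition:
        r = self.row_count - 1
        return BwtPosition(r, int(self.length[r]) - 1)

    # -- navigation --------------------------------------------------------
    def resolve_id(self, q: int) -> int:
        if self.variant == "default":
            return int(self.ids[q])
        if self.variant == "blocked":
            return idc.resolve_id_blocked(self, q)
        return idc.resolve_id_sampled(self, q)

    def move_lf(self, pos: BwtPosition) -> BwtPosition:
        """(u, v) -> LF(u, v): add f, then fast-forward row by row."""
        u, v = pos
        if not 0 <= v < self.length[u]:
            raise IndexError(f"invalid position {pos}")
        self.counters["lf_calls"] += 1
        dest = self.resolve_id(u)
        vv = int(self.f[u]) + v
        length = self.length
        steps = 0
        while vv >= length[dest]:
            vv -= int(length[dest])
            dest += 1
            steps += 1
            if dest >= self.row_count:
                raise IndexCorruptionError("fast-forward ran past the last row")
        self.counters["fast_forward_steps"] += steps
        return BwtPosition(dest, vv)

    def char_at(self, pos: BwtPosition) -> int:
        """Symbol code at a position; the terminator position reports -1."""
        if pos.u == self.terminator_row:
            return SENTINEL_CHAR
        return int(self.code[pos.u])

    def reposition(self, pos: BwtPosition, c: int) -> BwtPosition:
        """Move to the nearest row of symbol ``c``, direction by threshold.

        Up lands on the row's tail (v = l-1), down on its head (v = 0).  Only
        called on a mismatch; with trivialized thresholds the stored bit alone
        decides.  At the terminator position a mismatch with the aliased
        symbol has no stored bit: scan down first, falling back to up.
        """
        u, v = pos
        self.counters["reposition_calls"] += 1
        if u == self.terminator_row and c == int(self.code[u]):
            hit = self._scan(u, c, up=False)
            if hit is None:
                hit = self._scan(u, c, up=True)
        else:
            if self.char_at(pos) == c:
                raise ValueError("reposition called without a mismatch")
            up = v < int(self.thr[u, c])
            hit = self._scan(u, c, up=up)
        if hit is None:
            raise IndexCorruptionError(f"no row with symbol {c} found from row {u}")
        return hit

    def _scan(self, u: int, c: int, up: bool) -> Optional[BwtPosition]:
        code = self.code
        term = self.terminator_row
        step = -1 if up else 1
        i = u + step
        scanned = 0
        while 0 <= i < self.row_count:
            scanned += 1
            if i != term and code[i] == c:
                self.counters["reposition_scan_rows"] += scanned
                if up:
                    return BwtPosition(i, int(self.length[i]) - 1)
                return BwtPosition(i, 0)
            i += step
        self.counters["reposition_scan_rows"] += scanned
        return None

    def enumerate_bwt(self) -> np.ndarray:
        """Expand rows back to the per-offset BWT (text codes, sentinel=0)."""
        out = np.repeat(self.code.astype(np.int64) + 1, self.length)
        out[self.heads[self.terminator_row]] = SENTINEL
        return out.astype(np.uint8)


def build_move_table(
    text: Text,
    cfg: SplitConfig = SplitConfig(),
    variant: str = "default",
    block_size: int = 2048,
    sample_rate: int = 50,
    delta_bits: int = 23,
    bundle: Optional[SuffixBundle] = None,
) -> MoveTable:
    """Full build pipeline: suffix bundle -> RLBWT -> thresholds -> splits ->
    head pointers -> variant id column.

    ``bundle`` may be supplied to reuse a precomputed suffix bundle (the
    oracle tests build several variants over one text).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if bundle is None:
        bundle = build_suffix_bundle(text)
    rlbwt = run_length_encode(bundle)
    ts = compute_thresholds(bundle, rlbwt)

    rows0 = RowPartition.from_rlbwt(rlbwt)
    rows1 = split_at_thresholds(rows0, ts) if cfg.do_threshold_split else rows0
    rows2 = split_by_length(rows1, cfg.l_max)
    report = splitting_stats(rows0, rows1, rows2)

    theta = map_thresholds_to_rows(ts, rows2)

    # Head pointers: LF is stable, so the LF-image of the q-th head of symbol
    # s is C(s) plus the total length of earlier symbol-s rows.
    nrows = rows2.row_count
    pi = np.empty(nrows, dtype=np.int64)
    for s in range(SIGMA + 1):
        idx = np.flatnonzero(rows2.sym == s)
        if idx.size == 0:
            continue
        before = np.concatenate([[0], np.cumsum(rows2.length[idx])[:-1]])
        pi[idx] = bundle.c_counts[s] + before
    xi = np.searchsorted(rows2.head, pi, side="right") - 1
    f = pi - rows2.head[xi]
    if (f < 0).any() or (f >= rows2.length[xi]).any():
        raise IndexCorruptionError("head pointer outside its destination row")

    # Per-symbol id monotonicity (the premise of both compressed variants).
    for s in range(1, SIGMA + 1):
        idx = np.flatnonzero(rows2.sym == s)
        if idx.size and (np.diff(xi[idx]) < 0).any():
            raise IndexCorruptionError("destination ids not monotone per symbol")

    term = int(np.flatnonzero(rows2.sym == SENTINEL)[0])
    code = np.where(rows2.sym == SENTINEL, 1, rows2.sym).astype(np.int64) - 1

    table = MoveTable(
        variant=variant,
        n=text.n,
        r_original=rlbwt.r,
        code=code.astype(np.uint8),
        length=rows2.length.astype(np.int64),
        f=f.astype(np.int64),
        thr=theta,
        terminator_row=term,
        length_bits=cfg.length_bits,
        split_report=report,
        true_ids=xi.astype(np.int64),
        heads=rows2.head.astype(np.int64),
        ambiguous_substituted=text.ambiguous_substituted,
    )
    if variant == "default":
        table.ids = xi.astype(np.int64)
    elif variant == "blocked":
        bt, delta = idc.build_block_table(
            table.code, xi, term, block_size, delta_bits=delta_bits
        )
        table.block_table = bt
        table.delta = delta
    else:
        table.sample_table = idc.build_sample_table(table.code, xi, term, sample_rate)
    return table
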