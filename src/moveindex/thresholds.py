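"""Thresholds between adjacent same-symbol BWT runs.

For two runs of the same symbol with no intervening run of that symbol, the
threshold is the BWT offset that splits the gap between them into an "up"
half (closer, in LCP terms, to the earlier run's tail) and a "down" half
(closer to the later run's head).  During a PML query a mismatch repositions
up when the current in-row offset is below the threshold and down otherwise.

The threshold is placed at the leftmost minimum of the LCP array over the
candidate interval; by the range-minimum argument this satisfies both LCP
dominance conditions, which :func:`verify_threshold` checks by brute force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_text import RLBWT, SIGMA, RowPartition, SuffixBundle


@dataclass
class ThresholdSet:
    """Per-symbol adjacent-run pairs with their chosen global thresholds.

    For each DNA symbol code c (1..4), ``pairs[c]`` is a ``(m, 3)`` int array
    of rows ``(i_run, j_run, t)`` ordered by run index, and ``run_tail[c]`` /
    ``run_head[c]`` are the tails/heads of all c-runs in BWT order (needed to
    classify arbitrary rows into the gaps between runs).
    """

    pairs: dict[int, np.ndarray]
    run_tail: dict[int, np.ndarray]
    run_head: dict[int, np.ndarray]

    @property
    def total_pairs(self) -> int:
        return sum(p.shape[0] for p in self.pairs.values())


def compute_thresholds(bundle: SuffixBundle, rlbwt: RLBWT) -> ThresholdSet:
    """Choose one valid threshold per adjacent same-symbol run pair.

    The candidate interval for pair (i, j) is ``(run[i].tail, run[j].head]``;
    the leftmost position of the minimum LCP value in it is returned, where
    ``lcp[k]`` is the LCP of sorted suffixes k-1 and k.
    """
    lcp = bundle.lcp
    pairs: dict[int, np.ndarray] = {}
    tails: dict[int, np.ndarray] = {}
    heads: dict[int, np.ndarray] = {}
    run_tail = rlbwt.tail
    for c in range(1, SIGMA + 1):
        idx = np.flatnonzero(rlbwt.sym == c)
        tails[c] = run_tail[idx]
        heads[c] = rlbwt.head[idx]
        out = []
        for a, b in zip(idx[:-1], idx[1:]):
            lo = int(run_tail[a]) + 1  # first candidate offset
            hi = int(rlbwt.head[b])  # last candidate offset (inclusive)
            window = lcp[lo : hi + 1]
            t = lo + int(np.argmin(window))  # argmin returns the leftmost minimum
            out.append((int(a), int(b), t))
        pairs[c] = np.array(out, dtype=np.int64).reshape(-1, 3)
    return ThresholdSet(pairs=pairs, run_tail=tails, run_head=heads)


def _lcp_between(lcp: np.ndarray, a: int, b: int) -> int:
    """LCP of sorted suffixes a and b (a < b): range minimum of lcp[a+1..b]."""
    if a == b:
        return int(1 << 60)
    if a > b:
        a, b = b, a
    return int(lcp[a + 1 : b + 1].min())


def verify_threshold(
    bundle: SuffixBundle, rlbwt: RLBWT, i: int, j: int, t: int
) -> bool:
    """Brute-force check of the two LCP dominance conditions for pair (i, j).

    True iff every offset before ``t`` in the gap has LCP with run[i]'s tail
    >= its LCP with run[j]'s head, and every offset from ``t`` on has the
    opposite (non-strict) dominance.
    """
    if rlbwt.sym[i] != rlbwt.sym[j] or not i < j:
        raise ValueError("runs i, j must be an ordered same-symbol pair")
    between = rlbwt.sym[i + 1 : j]
    if (between == rlbwt.sym[i]).any():
        raise ValueError("runs i, j are not adjacent for their symbol")
    tail_i = int(rlbwt.tail[i])
    head_j = int(rlbwt.head[j])
    if not tail_i < t <= head_j:
        raise ValueError(f"threshold {t} outside the legal interval ({tail_i}, {head_j}]")
    lcp = bundle.lcp
    for k in range(tail_i + 1, t):
        if _lcp_between(lcp, k, tail_i) < _lcp_between(lcp, k, head_j):
            return False
    for k in range(t, head_j):
        if _lcp_between(lcp, k, tail_i) > _lcp_between(lcp, k, head_j):
            return False
    return True


def map_thresholds_to_rows(ts: ThresholdSet, rows: RowPartition) -> np.ndarray:
    """Row-relative threshold offsets, shape ``(row_count, sigma)``.

    Column ``c-1`` (DNA code c) of row (head h, length l) holds
    ``clamp(t - h, 0, l)`` where t is the governing pair's global threshold:
    0 for rows before the first c-run (always reposition down), l for rows
    after the last c-run (always up).  The column matching a row's own symbol
    is unused and left 0; the interpretation at query time is
    ``in-row offset v < threshold -> up, else down``.
    """
    rows.validate()
    nrows = rows.row_count
    out = np.zeros((nrows, SIGMA), dtype=np.int64)
    h = rows.head
    l = rows.length
    for c in range(1, SIGMA + 1):
        col = c - 1
        tails = ts.run_tail[c]
        if tails.size == 0:
            continue  # symbol absent: never repositioned to, leave 0
        other = rows.sym != c
        # gap index: number of c-run tails at or before the row head, minus 1
        gap = np.searchsorted(tails, h[other], side="right") - 1
        theta = np.zeros(other.sum(), dtype=np.int64)
        after_last = gap == tails.size - 1
        theta[after_last] = l[other][after_last]
        mid = (gap >= 0) & ~after_last
        if mid.any():
            t_global = ts.pairs[c][gap[mid], 2]
            rel = t_global - h[other][mid]
            theta[mid] = np.clip(rel, 0, l[other][mid])
        out[np.flatnonzero(other), col] = theta
    return out
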