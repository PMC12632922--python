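"""Independent brute-force oracles used by the test suite.

Everything here works on global BWT offsets and the plain suffix bundle;
nothing imports the move table, so agreement between these and the index is
a genuine dual-route check.
"""

from __future__ import annotations

import numpy as np

from moveindex.core_text import SENTINEL, SuffixBundle, lf_direct
from moveindex.thresholds import ThresholdSet


def naive_lcp(strings_sorted: list[str]) -> list[int]:
    """Direct pairwise LCP of adjacent sorted suffixes."""
    out = [0]
    for a, b in zip(strings_sorted, strings_sorted[1:]):
        l = 0
        while l < min(len(a), len(b)) and a[l] == b[l]:
            l += 1
        out.append(l)
    return out


def counting_rank(bwt: np.ndarray, c: int, i: int) -> int:
    return int(np.count_nonzero(bwt[:i] == c))


def pml_oracle(
    bundle: SuffixBundle, ts: ThresholdSet, codes: np.ndarray
) -> np.ndarray:
    """Step-by-step PML on global BWT offsets, no move structure.

    Repositioning uses the global thresholds directly: up goes to the
    governing earlier run's tail, down to the later run's head.  The one
    deliberate mirror of the index's terminator rule: a mismatch at the
    sentinel's BWT offset with query symbol A (the code the sentinel row
    aliases) repositions down to the next A-run head, falling back to up.
    """
    bwt = bundle.bwt
    m = len(codes)
    pml = np.zeros(m, dtype=np.int64)
    i = bundle.n - 1
    present = {c: bool((bwt == c).any()) for c in range(1, 5)}
    for k in range(m - 1, -1, -1):
        c = int(codes[k]) + 1  # text symbol code
        if not present[c]:
            continue
        if bwt[i] == c:
            if k < m - 1:
                pml[k] = pml[k + 1] + 1
            i = lf_direct(bundle, i)
            continue
        tails = ts.run_tail[c]
        heads = ts.run_head[c]
        if bwt[i] == SENTINEL and c == 1:
            below = heads[heads > i]
            i2 = int(below[0]) if below.size else int(tails[tails < i][-1])
        else:
            gap = int(np.searchsorted(tails, i, side="right")) - 1
            if gap == -1:
                i2 = int(heads[0])
            elif gap == tails.size - 1:
                i2 = int(tails[-1])
            else:
                t = int(ts.pairs[c][gap, 2])
                i2 = int(tails[gap]) if i < t else int(heads[gap + 1])
        i = lf_direct(bundle, i2)
    return pml
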