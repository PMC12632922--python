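"""Text ingestion, suffix array / BWT / LCP construction, and run-length encoding.

This module holds the uncompressed ground truth everything else is tested
against: the suffix array and BWT of the concatenated pangenome, the LCP
array used to place thresholds, and a direct (non-move-structure)
implementation of the LF-mapping.

Coordinate conventions
----------------------
All arrays are 0-based internally.  The text is a ``numpy`` array of symbol
codes with the terminal sentinel coded 0 and A/C/G/T coded 1..4, so plain
integer comparison gives the lexicographic order with the sentinel smallest.
The sentinel occurs exactly once, at the last position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

SENTINEL = 0
SIGMA = 4  # DNA alphabet size, sentinel excluded

_CODE_TO_CHAR = np.array(list("$ACGT"))
_CHAR_TO_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _CHAR_TO_CODE[ord(_c)] = _i + 1
    _CHAR_TO_CODE[ord(_c.lower())] = _i + 1


class TextError(ValueError):
    """Raised for invalid input sequences or a violated text invariant."""


@dataclass(frozen=True)
class Text:
    """Concatenated pangenome with a single terminal sentinel.

    ``codes`` holds the symbol codes ($=0, A=1 .. T=4); ``boundaries`` records
    ``(name, start, length)`` for each input record, 0-based starts.
    """

    codes: np.ndarray
    boundaries: tuple[tuple[str, int, int], ...] = ()
    ambiguous_substituted: int = 0

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.uint8)
        object.__setattr__(self, "codes", codes)
        if codes.size < 2:
            raise TextError("text must contain at least one symbol plus the sentinel")
        sent = np.flatnonzero(codes == SENTINEL)
        if sent.size != 1 or sent[0] != codes.size - 1:
            raise TextError("exactly one sentinel, at the final position, is required")
        if codes.max() > SIGMA:
            raise TextError("symbol code outside the DNA alphabet")
        if self.boundaries and sum(b[2] for b in self.boundaries) + 1 != codes.size:
            raise TextError("record lengths do not sum to n - 1")

    @property
    def n(self) -> int:
        return int(self.codes.size)

    @property
    def sigma(self) -> int:
        return SIGMA

    def __str__(self) -> str:
        return "".join(_CODE_TO_CHAR[self.codes])


def ingest_fasta(
    records: Iterable[tuple[str, str]], policy: str = "substitute"
) -> Text:
    """Concatenate named DNA sequences into a :class:`Text`.

    ``policy`` controls non-ACGT symbols: ``"substitute"`` deterministically
    replaces them with ``A`` (count recorded on the returned object);
    ``"error"`` raises.
    """
    if policy not in ("substitute", "error"):
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    parts: list[np.ndarray] = []
    boundaries: list[tuple[str, int, int]] = []
    substituted = 0
    start = 0
    for name, seq in records:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        codes = _CHAR_TO_CODE[raw].astype(np.int16)
        bad = codes < 0
        if bad.any():
            if policy == "error":
                raise TextError(
                    f"record {name!r} contains {int(bad.sum())} non-ACGT symbol(s)"
                )
            substituted += int(bad.sum())
            codes[bad] = 1  # deterministic: ambiguity codes become A
        parts.append(codes.astype(np.uint8))
        boundaries.append((name, start, len(seq)))
        start += len(seq)
    if not parts or start == 0:
        raise TextError("no non-empty records to index")
    parts.append(np.array([SENTINEL], dtype=np.uint8))
    return Text(
        np.concatenate(parts),
        boundaries=tuple(boundaries),
        ambiguous_substituted=substituted,
    )


def text_from_string(s: str) -> Text:
    """Build a :class:`Text` from a plain string, e.g. ``"ACACGT$"``.

    A trailing ``$`` is accepted (and required to be final); if absent the
    sentinel is appended.
    """
    if "$" in s:
        if not s.endswith("$") or s.count("$") != 1:
            raise TextError("'$' may only appear once, at the end")
        s = s[:-1]
    return ingest_fasta([("seq", s)])


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy lexsorts)."""
    n = codes.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = codes.astype(np.int64)
    tmp = np.empty(n, dtype=np.int64)
    k = 1
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        sa = np.lexsort((second, rank))
        tmp[sa[0]] = 0
        differ = (rank[sa[1:]] != rank[sa[:-1]]) | (second[sa[1:]] != second[sa[:-1]])
        tmp[sa[1:]] = np.cumsum(differ)
        rank, tmp = tmp, rank
        if rank[sa[-1]] == n - 1:
            return sa.astype(np.int64)
        k *= 2


def _lcp_kasai(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """LCP array by Kasai's algorithm; lcp[j] = LCP(suffix sa[j-1], sa[j])."""
    n = codes.size
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    c = codes  # local alias, hot loop
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and c[i + h] == c[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


@dataclass
class SuffixBundle:
    """Suffix array, BWT, LCP array and symbol-count table of one text."""

    text: Text
    sa: np.ndarray
    bwt: np.ndarray
    lcp: np.ndarray
    c_counts: np.ndarray  # c_counts[c] = number of symbols lexicographically < c

    @property
    def n(self) -> int:
        return self.text.n

    @cached_property
    def _occ(self) -> np.ndarray:
        """occ[c, i] = occurrences of c in bwt[0:i]; oracle helper, O(sigma*n)."""
        n = self.n
        occ = np.zeros((SIGMA + 1, n + 1), dtype=np.int64)
        for c in range(SIGMA + 1):
            occ[c, 1:] = np.cumsum(self.bwt == c)
        return occ

    def bwt_string(self) -> str:
        return "".join(_CODE_TO_CHAR[self.bwt])


def build_suffix_bundle(text: Text) -> SuffixBundle:
    """Suffix-sort the text and derive BWT, LCP and cumulative counts."""
    codes = text.codes
    sa = _suffix_array(codes)
    bwt = codes[(sa - 1) % codes.size]
    lcp = _lcp_kasai(codes, sa)
    counts = np.bincount(codes, minlength=SIGMA + 1)
    c_counts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    return SuffixBundle(text=text, sa=sa, bwt=bwt, lcp=lcp, c_counts=c_counts)


def rank(bundle: SuffixBundle, c: int, i: int) -> int:
    """Occurrences of symbol ``c`` among the first ``i`` BWT characters."""
    if not 0 <= i <= bundle.n:
        raise IndexError(f"prefix length {i} out of range [0, {bundle.n}]")
    return int(bundle._occ[c, i])


def lf_direct(bundle: SuffixBundle, i: int) -> int:
    """LF(i) = C(L[i]) + rank_{L[i]}(i), computed directly on the BWT.

    0-based: the returned offset counts occurrences strictly before ``i``,
    so the sentinel's position maps to offset 0.
    """
    if not 0 <= i < bundle.n:
        raise IndexError(f"BWT offset {i} out of range [0, {bundle.n})")
    c = int(bundle.bwt[i])
    return int(bundle.c_counts[c] + bundle._occ[c, i])


@dataclass
class RLBWT:
    """Run-length encoded BWT: maximal equal-symbol runs in BWT order."""

    sym: np.ndarray  # run symbols (text codes, sentinel included)
    head: np.ndarray  # BWT offset of each run head
    length: np.ndarray

    @property
    def r(self) -> int:
        return int(self.sym.size)

    @property
    def tail(self) -> np.ndarray:
        return self.head + self.length - 1


def run_length_encode(bundle: SuffixBundle) -> RLBWT:
    bwt = bundle.bwt
    breaks = np.flatnonzero(np.diff(bwt.astype(np.int16)) != 0)
    head = np.concatenate([[0], breaks + 1]).astype(np.int64)
    length = np.diff(np.concatenate([head, [bwt.size]]))
    return RLBWT(sym=bwt[head].astype(np.int64), head=head, length=length)


def reconstruct_text(bundle: SuffixBundle) -> Text:
    """Invert the BWT by iterated LF-mapping; oracle for index correctness."""
    n = bundle.n
    bwt = bundle.bwt
    occ = bundle._occ
    c_counts = bundle.c_counts
    out = np.empty(n, dtype=np.uint8)
    out[n - 1] = SENTINEL
    i = 0  # BWM row 0 is the rotation starting with the sentinel
    for k in range(n - 2, -1, -1):
        c = int(bwt[i])
        if c == SENTINEL:
            raise TextError("BWT inversion cycle shorter than n: corrupt bundle")
        out[k] = c
        i = int(c_counts[c] + occ[c, i])
    if bwt[i] != SENTINEL:
        raise TextError("BWT inversion did not terminate at the sentinel")
    return Text(out)


@dataclass(frozen=True)
class RowPartition:
    """An ordered partition of the BWT into equal-symbol rows.

    Starts as the RLBWT run set and is refined by the splitting stages; rows
    keep the *true* symbol codes (sentinel included) until the move table is
    materialized.
    """

    sym: np.ndarray
    head: np.ndarray
    length: np.ndarray

    @property
    def row_count(self) -> int:
        return int(self.sym.size)

    @property
    def n(self) -> int:
        return int(self.head[-1] + self.length[-1]) if self.sym.size else 0

    @classmethod
    def from_rlbwt(cls, rlbwt: RLBWT) -> "RowPartition":
        return cls(
            sym=rlbwt.sym.copy(), head=rlbwt.head.copy(), length=rlbwt.length.copy()
        )

    def validate(self) -> None:
        if self.sym.size == 0:
            raise TextError("empty row partition")
        if self.head[0] != 0 or (self.length < 1).any():
            raise TextError("rows do not tile the BWT")
        if not np.array_equal(self.head[1:], (self.head + self.length)[:-1]):
            raise TextError("rows do not tile the BWT")


def naive_suffix_array(s: Sequence[int] | str) -> list[int]:
    """Quadratic suffix sort used only as an independent oracle."""
    items = list(s)
    return sorted(range(len(items)), key=lambda i: items[i:])
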