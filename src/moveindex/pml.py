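"""Pseudo Matching Length (PML) queries, plus the naive matching-statistics
oracle they are tested against.

PMLs approximate matching statistics from below: the pattern is consumed
right to left, one LF step per character; on a mismatch the position is moved
(threshold-directed) to the nearest row of the required symbol and the
running match length resets to zero.  Any stretch of consecutive matches
corresponds to a genuine substring of the indexed text, so PML[k] <= MS[k]
holds positionwise for every threshold choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .core_text import Text
from .move_table import DNA_CODES, MoveTable

_Q_CHAR_TO_CODE = np.full(256, -1, dtype=np.int8)
for _c, _i in DNA_CODES.items():
    _Q_CHAR_TO_CODE[ord(_c)] = _i
    _Q_CHAR_TO_CODE[ord(_c.lower())] = _i


@dataclass(frozen=True)
class Pattern:
    """A query read: name plus DNA codes (A=0..T=3) in read order."""

    name: str
    codes: np.ndarray
    ambiguous_substituted: int = 0

    @property
    def m(self) -> int:
        return int(self.codes.size)

    @classmethod
    def from_string(
        cls, name: str, seq: str, policy: str = "substitute"
    ) -> "Pattern":
        if len(seq) == 0:
            raise ValueError(f"read {name!r} is empty")
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        codes = _Q_CHAR_TO_CODE[raw].astype(np.int16)
        bad = codes < 0
        nbad = int(bad.sum())
        if nbad and policy == "error":
            raise ValueError(f"read {name!r} contains {nbad} non-ACGT symbol(s)")
        codes[bad] = 0  # deterministic: ambiguity codes become A
        return cls(name=name, codes=codes.astype(np.int8), ambiguous_substituted=nbad)


@dataclass
class PmlResult:
    name: str
    pml: np.ndarray  # length m, left-to-right read order

    def format(self) -> str:
        return ">" + self.name + "\n" + " ".join(map(str, self.pml.tolist()))


@dataclass
class MsResult:
    name: str
    ms: np.ndarray


def compute_pml(table: MoveTable, p: Pattern) -> PmlResult:
    """The PML recurrence over the move table.

    Starts at the final BWT offset; PML of the last pattern position is 0 by
    definition (movement still happens there).  A symbol absent from the
    whole text yields 0 and leaves the position unchanged.
    """
    m = p.m
    pml = np.zeros(m, dtype=np.int64)
    present = table.symbol_present
    pos = table.last_position()
    codes = p.codes
    last = m - 1
    for k in range(last, -1, -1):
        c = int(codes[k])
        if not present[c]:
            continue  # pml[k] stays 0, no movement
        if table.char_at(pos) == c:
            if k < last:
                pml[k] = pml[k + 1] + 1
            pos = table.move_lf(pos)
        else:
            pos = table.move_lf(table.reposition(pos, c))
    return PmlResult(name=p.name, pml=pml)


def compute_pml_batch(
    table: MoveTable, reads: Iterable[Pattern]
) -> Iterator[PmlResult]:
    """Order-preserving, per-read-independent PML computation."""
    for p in reads:
        yield compute_pml(table, p)


def matching_statistics_naive(text: Text, p: Pattern) -> MsResult:
    """Brute-force matching statistics: longest prefix of each pattern suffix
    occurring anywhere in the text.  O(m^2 n); oracle only."""
    t = str(text)
    seq = "".join("ACGT"[c] for c in p.codes)
    m = len(seq)
    ms = np.zeros(m, dtype=np.int64)
    for k in range(m):
        l = 0
        while k + l < m and seq[k : k + l + 1] in t:
            l += 1
        ms[k] = l
    return MsResult(name=p.name, ms=ms)
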