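"""Deterministic synthetic pangenomes, reads and adversarial texts.

The pangenome generator emulates what makes real pangenomes compressible: a
base genome plus closely related haplotype copies, so the concatenated text
length n grows linearly with the number of haplotypes while the BWT run
count r grows much more slowly.  It models substitutions and short indels
only — no structural variation, no sequencing-error profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PangenomeSpec:
    """Parameters of a synthetic pangenome; the seed is mandatory.

    Defaults model a small, tightly related haplotype panel: 0.1%
    substitution divergence and rare short indels.
    """

    base_length: int = 50_000
    n_haplotypes: int = 20
    substitution_rate: float = 0.001
    indel_rate: float = 1e-4
    max_indel_len: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.base_length < 1 or self.n_haplotypes < 1 or self.max_indel_len < 1:
            raise ValueError("sizes must be positive")


def _mutate(base: np.ndarray, spec: PangenomeSpec, rng: np.random.Generator) -> str:
    seq = base.copy()
    # substitutions: shift by 1..3 in base space so the symbol always changes
    sub = rng.random(seq.size) < spec.substitution_rate
    seq[sub] = (seq[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    # indels: sparse, equal chance of deletion and insertion, length 1..max
    n_indels = rng.binomial(seq.size, spec.indel_rate)
    if n_indels:
        pieces: list[np.ndarray] = []
        positions = np.sort(rng.integers(0, seq.size, size=n_indels))
        prev = 0
        for pos in positions:
            pos = int(max(pos, prev))
            pieces.append(seq[prev:pos])
            size = int(rng.integers(1, spec.max_indel_len + 1))
            if rng.random() < 0.5:
                prev = min(pos + size, seq.size)  # deletion
            else:
                pieces.append(rng.integers(0, 4, size=size))  # insertion
                prev = pos
        pieces.append(seq[prev:])
        seq = np.concatenate(pieces)
    return "".join(_BASES[seq])


def generate_pangenome(spec: PangenomeSpec) -> list[tuple[str, str]]:
    """One base sequence plus n_haplotypes - 1 mutated copies, seeded."""
    rng = np.random.default_rng(spec.seed)
    base = rng.integers(0, 4, size=spec.base_length)
    records = [("hap0", "".join(_BASES[base]))]
    for h in range(1, spec.n_haplotypes):
        records.append((f"hap{h}", _mutate(base, spec, rng)))
    return records


def generate_reads(
    records: list[tuple[str, str]],
    n_reads: int,
    read_length: int = 150,
    error_rate: float = 0.01,
    seed: int = 0,
    name_prefix: str = "read",
) -> list[tuple[str, str]]:
    """Uniform-start reads with per-base substitution errors, seeded.

    Start positions are uniform over all valid (record, offset) pairs, so
    reads never span record boundaries.
    """
    rng = np.random.default_rng(seed)
    starts_per_rec = np.array(
        [max(0, len(seq) - read_length + 1) for _, seq in records]
    )
    if starts_per_rec.sum() == 0:
        raise ValueError("read_length exceeds every record length")
    cum = np.cumsum(starts_per_rec)
    out: list[tuple[str, str]] = []
    for i in range(n_reads):
        g = int(rng.integers(0, cum[-1]))
        rec = int(np.searchsorted(cum, g, side="right"))
        start = g - (int(cum[rec - 1]) if rec else 0)
        seq = np.array(list(records[rec][1][start : start + read_length]))
        codes = np.searchsorted(_BASES, seq)
        err = rng.random(codes.size) < error_rate
        codes[err] = (codes[err] + rng.integers(1, 4, size=int(err.sum()))) % 4
        out.append((f"{name_prefix}{i}", "".join(_BASES[codes])))
    return out


def adversarial_fixtures() -> dict[str, str]:
    """Named corner-case texts (no trailing sentinel; the builder appends it).

    * ``long_run`` — a text whose BWT contains a run longer than 2**11, so
      length-splitting fires at every shipped bit width;
    * ``nontrivial_threshold`` — the smallest text found by seeded search
      whose index gains a row from thresholds-splitting;
    * ``periodic`` — long runs, minimal r;
    * ``alternating`` — found by seeded search: its BWT has all runs of
      length 1, so r = n, no compression, and neither splitting stage fires.
    """
    return {
        "long_run": "A" * 2600 + "C" + "A" * 2600,
        "nontrivial_threshold": "GGAAAG",
        "periodic": "AC" * 512,
        "alternating": "AGAGGACATACGCCCTGTTATCCC",
    }
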