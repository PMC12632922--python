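from __future__ import annotations

import numpy as np
import pytest

from moveindex import (
    PangenomeSpec,
    build_suffix_bundle,
    generate_pangenome,
    ingest_fasta,
    text_from_string,
)

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def seeded_texts(seed: int, count: int, n_min: int, n_max: int):
    """Deterministic random texts with their suffix bundles."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(count):
        n = int(rng.integers(n_min, n_max + 1))
        text = text_from_string(random_dna(rng, n))
        out.append((text, build_suffix_bundle(text)))
    return out


@pytest.fixture(scope="session")
def acacgt():
    return text_from_string("ACACGT$")


@pytest.fixture(scope="session")
def acacgt_bundle(acacgt):
    return build_suffix_bundle(acacgt)


@pytest.fixture(scope="session")
def small_corpus():
    """A dozen seeded texts for per-module oracle checks."""
    return seeded_texts(seed=11, count=12, n_min=30, n_max=600)


@pytest.fixture(scope="session")
def corpus50():
    """50 seeded texts (n <= 2000) shared by the acceptance suite."""
    return seeded_texts(seed=1729, count=50, n_min=60, n_max=2000)


@pytest.fixture(scope="session")
def pangenome_small():
    """Scaled-down synthetic pangenome: 10 haplotypes of a 15 kb base at
    0.1% divergence (the realistic conditions, sized for the test budget)."""
    spec = PangenomeSpec(
        base_length=15_000, n_haplotypes=10, substitution_rate=0.001, seed=42
    )
    records = generate_pangenome(spec)
    text = ingest_fasta(records)
    return records, text, build_suffix_bundle(text)
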