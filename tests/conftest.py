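"""Shared fixtures: deterministic random collections and small builds."""

from __future__ import annotations

import numpy as np
import pytest

import colbwt as cb

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    lut = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    return lut[rng.integers(0, len(lut), length)].tobytes().decode()


def related_collection(
    rng: np.random.Generator, d: int, length: int, rate: float = 0.03
) -> cb.DocumentCollection:
    """Haplotype-style collection: shared base plus independent SNVs."""
    base = rng.integers(0, 4, length)
    seqs = []
    for _ in range(d):
        s = base.copy()
        mask = rng.random(length) < rate
        s[mask] = (s[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
        seqs.append(BASES[s].tobytes().decode())
    return cb.collection_from_seqs(seqs)


def unrelated_collection(
    rng: np.random.Generator, d: int, max_length: int
) -> cb.DocumentCollection:
    seqs = [random_seq(rng, int(rng.integers(20, max_length + 1))) for _ in range(d)]
    return cb.collection_from_seqs(seqs)


def pinned_suffix_read(rng: np.random.Generator, d: int = 2, length: int = 400):
    """A build plus a read guaranteed to be processed without resets.

    Document 1 is drawn over {A,G,T} and ends with the text's only 'C';
    a read that is a suffix of document 1 therefore starts its backward
    pass at the unique C row (the genuine occurrence) and every extension
    matches, so PML[i] = m - i exactly.
    """
    docs = [random_seq(rng, length, "AGT") + "C"]
    for _ in range(d - 1):
        docs.append(random_seq(rng, length, "AGT"))
    coll = cb.collection_from_seqs(docs)
    build = cb.build_all(coll, id_bits=32)
    m = int(rng.integers(10, length // 2))
    read = docs[0][-m:]
    return build, read


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240517)


@pytest.fixture(scope="session")
def gatta_build() -> cb.BuildResult:
    """Two documents sharing the single multi-MUM "GATTA"."""
    return cb.build_all(cb.collection_from_seqs(["GATTACA", "GATTAGA"]), id_bits=32)


@pytest.fixture(scope="session")
def hap_build() -> cb.BuildResult:
    """A small haplotype panel with many multi-MUMs, wide ids, s=1."""
    rng = np.random.default_rng(7)
    coll = related_collection(rng, d=4, length=1500, rate=0.01)
    return cb.build_all(coll, mode="tunnels", sample_rate=1, id_bits=32, min_mum_len=1)
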