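"""Synthetic pangenomes and error-bearing long reads.

The generator emulates a haplotype panel: one uniform random base
sequence, from which each haplotype is derived by independent SNVs
(uniform alternative base) and, optionally, short indels with geometric
lengths.  Reads are sampled from the haplotypes with per-base SNV-style
errors; negative reads come from an independently drawn, unrelated
random genome.  Everything is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import colinear_pairs, extract_peaks, significant_peak_threshold
from .index import build_all
from .query import query_pml_cid
from .sequences import DocumentCollection, collection_from_seqs

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PangenomeSpec:
    base_len: int = 50_000
    d: int = 8
    snv_rate: float = 0.005
    indel_rate: float = 0.0
    indel_len_geom_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_len < 1 or self.d < 2:
            raise ValueError("base_len >= 1 and d >= 2 required")
        for rate in (self.snv_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def _mutate_snv(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Independent substitutions; the alternative base is uniform over the
    three non-reference bases."""
    out = codes.copy()
    mask = rng.random(codes.size) < rate
    shift = rng.integers(1, 4, int(mask.sum()))
    out[mask] = (out[mask] + shift) % 4
    return out


def _apply_indels(
    codes: np.ndarray, rate: float, geom_p: float, rng: np.random.Generator
) -> np.ndarray:
    if rate <= 0:
        return codes
    pieces: list[np.ndarray] = []
    i = 0
    sites = np.flatnonzero(rng.random(codes.size) < rate)
    for s in sites:
        if s < i:
            continue
        length = int(rng.geometric(geom_p))
        pieces.append(codes[i:s])
        if rng.random() < 0.5:  # deletion
            i = s + length
        else:  # insertion
            pieces.append(rng.integers(0, 4, length))
            i = s
    pieces.append(codes[i:])
    return np.concatenate(pieces) if pieces else codes


def simulate_pangenome(spec: PangenomeSpec) -> DocumentCollection:
    rng = np.random.default_rng(spec.seed)
    base = rng.integers(0, 4, spec.base_len)
    seqs = []
    for _ in range(spec.d):
        hap = _mutate_snv(base, spec.snv_rate, rng)
        hap = _apply_indels(hap, spec.indel_rate, spec.indel_len_geom_p, rng)
        seqs.append(_BASES[hap].tobytes().decode("ascii"))
    return collection_from_seqs(seqs, [f"hap{i + 1}" for i in range(spec.d)])


@dataclass
class ReadSpec:
    n_reads: int = 500
    read_len: int = 5_000
    snv_rate: float = 0.01
    seed: int = 0


@dataclass(frozen=True)
class Read:
    name: str
    seq: str
    label: bool  # True = drawn from the indexed collection
    origin_doc: int = -1
    origin_pos: int = -1


def simulate_reads(
    coll: DocumentCollection,
    spec: ReadSpec,
    positive_fraction: float = 1.0,
    neg_genome_len: int | None = None,
) -> list[Read]:
    """Labelled reads: positives from the collection's haplotypes with
    per-base SNV errors, negatives from an unrelated random genome."""
    rng = np.random.default_rng(spec.seed)
    lens = np.array([len(s) for s in coll.seqs], dtype=np.int64)
    eligible = np.flatnonzero(lens >= spec.read_len)
    if eligible.size == 0:
        raise ValueError("read_len exceeds every document length")
    n_pos = int(round(spec.n_reads * positive_fraction))
    neg_rng = np.random.default_rng(rng.integers(0, 2**31))
    neg_genome = (
        _random_genome(neg_rng, neg_genome_len or max(int(lens.max()), spec.read_len))
        if n_pos < spec.n_reads
        else ""
    )
    reads: list[Read] = []
    weights = lens[eligible] / lens[eligible].sum()
    for i in range(spec.n_reads):
        if i < n_pos:
            doc = int(rng.choice(eligible, p=weights))
            seq = coll.seqs[doc]
            start = int(rng.integers(0, len(seq) - spec.read_len + 1))
            codes = coll_codes(seq[start : start + spec.read_len])
            codes = _mutate_snv(codes, spec.snv_rate, rng)
            reads.append(
                Read(
                    name=f"pos_{i}",
                    seq=_BASES[codes].tobytes().decode("ascii"),
                    label=True,
                    origin_doc=doc,
                    origin_pos=start,
                )
            )
        else:
            start = int(rng.integers(0, len(neg_genome) - spec.read_len + 1))
            reads.append(
                Read(name=f"neg_{i}", seq=neg_genome[start : start + spec.read_len], label=False)
            )
    return reads


def coll_codes(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PeakExperimentResult:
    accuracy: float
    colinear_pairs: int
    total_pairs: int
    coverage: float
    n_reads: int
    degenerate: bool = False  # no adjacent significant pairs at all


def run_peak_experiment(
    coll: DocumentCollection,
    read_spec: ReadSpec,
    *,
    mode: str = "tunnels",
    sample_rate: int = 10,
    min_mum_len: int = 1,
    id_bits: int = 32,
    peak_threshold: int | None = None,
    null_k: int = 19,
) -> PeakExperimentResult:
    """Co-linear pair-calling accuracy on error-bearing positive reads.

    Every adjacent significant-peak pair within a positive read is a true
    co-linear pair (same read, same locus), so accuracy is the fraction
    of those pairs the id test actually calls co-linear.
    """
    build = build_all(
        coll, mode=mode, sample_rate=sample_rate, id_bits=id_bits, min_mum_len=min_mum_len
    )
    index = build.index
    thr = peak_threshold if peak_threshold is not None else significant_peak_threshold(null_k)
    reads = simulate_reads(coll, read_spec, positive_fraction=1.0)
    called = 0
    total = 0
    for read in reads:
        res = query_pml_cid(index, read.seq)
        c, pairs, _ = colinear_pairs(extract_peaks(res), thr)
        called += c
        total += pairs
    if total == 0:
        return PeakExperimentResult(
            accuracy=float("nan"), colinear_pairs=0, total_pairs=0,
            coverage=index.coverage(), n_reads=len(reads), degenerate=True,
        )
    return PeakExperimentResult(
        accuracy=called / total,
        colinear_pairs=called,
        total_pairs=total,
        coverage=index.coverage(),
        n_reads=len(reads),
    )
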