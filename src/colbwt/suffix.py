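"""Classical suffix structures: SA, LCP, DA, BWT, run-length BWT, move tables.

The suffix array is built by prefix doubling (Manber–Myers) vectorised
with numpy, which is near-linear in practice at the scales this package
targets; a naive quadratic sort is provided as an independent oracle for
tests.  The LCP array uses Kasai's algorithm.  LF/FL stepping is served
by run-indexed tables (the move-structure contract: stepping costs
amortised O(1) once the current run is tracked, with a fallback binary
search for arbitrary positions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import ConcatText


# ---------------------------------------------------------------------------
# suffix array construction


def build_suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array of an integer-coded text by prefix doubling."""
    n = int(text.size)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = text.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1 = rank[order]
        r2 = key2[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


def naive_suffix_array(text: np.ndarray) -> np.ndarray:
    """Quadratic suffix sort; test oracle only."""
    suffixes = [tuple(int(x) for x in text[i:]) for i in range(text.size)]
    return np.array(sorted(range(text.size), key=suffixes.__getitem__), dtype=np.int64)


def kasai_lcp(text: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """LCP array with LCP[0] = 0 and LCP[i] = lcp(suffix SA[i-1], suffix SA[i])."""
    n = int(text.size)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    t = text
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and t[i + h] == t[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


@dataclass
class SuffixStructures:
    """SA, LCP, DA and BWT of a concatenated collection.

    Retained in full to support brute-force oracles and the exact
    matching-statistics mode; the production query path never touches
    these arrays (it sees only the serialisable index surface).
    """

    ct: ConcatText
    sa: np.ndarray
    lcp: np.ndarray
    da: np.ndarray
    bwt: np.ndarray

    @property
    def n(self) -> int:
        return int(self.sa.size)


def build_suffix_structures(ct: ConcatText) -> SuffixStructures:
    sa = build_suffix_array(ct.text)
    lcp = kasai_lcp(ct.text, sa)
    da = ct.doc_of[sa].astype(np.int32)
    bwt = ct.text[(sa - 1) % ct.n]
    return SuffixStructures(ct=ct, sa=sa, lcp=lcp, da=da, bwt=bwt)


# ---------------------------------------------------------------------------
# run-length BWT


@dataclass
class RLBWT:
    """Maximal equal-symbol runs of the BWT."""

    starts: np.ndarray  # int64, strictly increasing, starts[0] == 0
    chars: np.ndarray  # int32 symbol per run
    lens: np.ndarray  # int64 length per run
    n: int

    @property
    def r(self) -> int:
        return int(self.starts.size)

    def run_of(self, p: int) -> int:
        return int(np.searchsorted(self.starts, p, side="right") - 1)

    def expand(self) -> np.ndarray:
        return np.repeat(self.chars, self.lens)


def run_length_encode(bwt: np.ndarray) -> RLBWT:
    n = int(bwt.size)
    boundary = np.empty(n, dtype=bool)
    boundary[0] = True
    boundary[1:] = bwt[1:] != bwt[:-1]
    starts = np.flatnonzero(boundary).astype(np.int64)
    lens = np.diff(np.append(starts, n))
    return RLBWT(starts=starts, chars=bwt[starts].astype(np.int32), lens=lens, n=n)


# ---------------------------------------------------------------------------
# move tables (run-indexed LF / FL)


@dataclass
class MoveTables:
    """Run-indexed LF/FL permutation tables.

    ``lf_dest[i]`` is LF of run i's first position; within a run LF is an
    offset shift.  FL uses the image intervals sorted by ``lf_dest`` (they
    partition [0, n)).  ``lf_dest_run`` caches the run containing
    ``lf_dest[i]`` so monotone stepping fast-forwards instead of binary
    searching.
    """

    n: int
    run_start: np.ndarray
    run_char: np.ndarray
    lf_dest: np.ndarray
    lf_dest_run: np.ndarray
    f_start: np.ndarray  # starts of LF-image intervals, sorted
    fl_dest: np.ndarray  # original run start of each F-interval
    first_dna_code: int

    @property
    def r(self) -> int:
        return int(self.run_start.size)

    def run_of(self, p: int) -> int:
        if not 0 <= p < self.n:
            raise IndexError(f"BWT position {p} out of range [0,{self.n})")
        return int(np.searchsorted(self.run_start, p, side="right") - 1)

    def lf(self, p: int) -> int:
        i = self.run_of(p)
        return int(self.lf_dest[i] + (p - self.run_start[i]))

    def lf_step(self, p: int, run: int) -> tuple[int, int]:
        """LF with run tracking; returns (LF(p), run containing LF(p))."""
        dest = int(self.lf_dest[run] + (p - self.run_start[run]))
        j = int(self.lf_dest_run[run])
        rs = self.run_start
        r = self.r
        while j + 1 < r and dest >= rs[j + 1]:
            j += 1
        return dest, j

    def fl(self, p: int) -> int:
        if not 0 <= p < self.n:
            raise IndexError(f"BWT position {p} out of range [0,{self.n})")
        j = int(np.searchsorted(self.f_start, p, side="right") - 1)
        return int(self.fl_dest[j] + (p - self.f_start[j]))

    def fl_range(self, lo: int, hi: int) -> tuple[int, int, bool]:
        """FL image of the inclusive range [lo, hi].

        Returns (FL(lo), FL(hi), contiguous) where *contiguous* means the
        image is exactly the block of consecutive positions
        [FL(lo), FL(lo) + (hi - lo)].
        """
        base = self.fl(lo)
        for k in range(1, hi - lo + 1):
            if self.fl(lo + k) != base + k:
                return base, self.fl(hi), False
        return base, base + (hi - lo), True


def build_move_tables(rl: RLBWT, first_dna_code: int) -> MoveTables:
    n = rl.n
    # C[c]: number of symbols smaller than c in the text == BWT.
    max_code = int(rl.chars.max()) if rl.r else 0
    counts = np.zeros(max_code + 2, dtype=np.int64)
    np.add.at(counts, rl.chars, rl.lens)
    C = np.zeros(max_code + 2, dtype=np.int64)
    C[1:] = np.cumsum(counts)[:-1]
    # occurrences of the run's own symbol before the run
    occ_before = np.zeros(rl.r, dtype=np.int64)
    per_char_cum: dict[int, int] = {}
    for i in range(rl.r):
        c = int(rl.chars[i])
        occ_before[i] = per_char_cum.get(c, 0)
        per_char_cum[c] = occ_before[i] + int(rl.lens[i])
    lf_dest = C[rl.chars] + occ_before
    lf_dest_run = np.searchsorted(rl.starts, lf_dest, side="right") - 1
    order = np.argsort(lf_dest, kind="stable")
    f_start = lf_dest[order]
    fl_dest = rl.starts[order]
    return MoveTables(
        n=n,
        run_start=rl.starts.copy(),
        run_char=rl.chars.copy(),
        lf_dest=lf_dest,
        lf_dest_run=lf_dest_run.astype(np.int64),
        f_start=f_start,
        fl_dest=fl_dest,
        first_dna_code=first_dna_code,
    )


def invert_bwt(mt: MoveTables, rl: RLBWT, sentinel_rank: int = 0) -> np.ndarray:
    """Reconstruct the text by backward stepping from the sentinel's rank.

    The text's last symbol is the sentinel, whose BWT rank is the rank of
    the (lexicographically least) suffix "$", i.e. rank 0.
    """
    n = rl.n
    bwt = rl.expand()
    out = np.empty(n, dtype=np.int32)
    p = sentinel_rank
    for k in range(n - 1, -1, -1):
        out[k] = bwt[p]
        p = mt.lf(p)
    # out[k] = T[k-1] shifted: BWT[rank of suffix k] = T[k-1]; rotate so the
    # sentinel sits last.
    return np.roll(out, -1)


# ---------------------------------------------------------------------------
# thresholds


@dataclass
class Thresholds:
    """MONI-style repositioning thresholds.

    For each symbol c and each pair of successive c-runs (j, j+1), stores
    the smallest LCP index t in (end_j, start_{j+1}] minimising LCP there.
    A mismatching position p between the runs repositions to run j+1's
    first row when p >= t, else to run j's last row.
    """

    # char code -> (run indices array, thresholds array of len(runs)-1)
    by_char: dict[int, tuple[np.ndarray, np.ndarray]]

    def runs_of(self, c: int) -> np.ndarray:
        entry = self.by_char.get(int(c))
        return entry[0] if entry is not None else np.empty(0, dtype=np.int64)


def compute_thresholds(ss: SuffixStructures, rl: RLBWT) -> Thresholds:
    lcp = ss.lcp
    n = ss.n
    by_char: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    # combined key makes argmin pick the smallest position on ties
    key = lcp * (n + 1) + np.arange(n)
    for c in np.unique(rl.chars):
        idx = np.flatnonzero(rl.chars == c).astype(np.int64)
        th = np.empty(max(idx.size - 1, 0), dtype=np.int64)
        for j in range(idx.size - 1):
            a = int(rl.starts[idx[j]] + rl.lens[idx[j]])  # end_j + 1
            b = int(rl.starts[idx[j + 1]])  # start_{j+1}
            th[j] = a + int(np.argmin(key[a : b + 1]))
        by_char[int(c)] = (idx, th)
    return Thresholds(by_char=by_char)


def naive_lf(ss: SuffixStructures) -> np.ndarray:
    """Direct LF permutation from the definition SA[LF(i)] = SA[i] - 1 mod n.

    Independent of the run-indexed tables; test oracle.
    """
    n = ss.n
    inv = np.empty(n, dtype=np.int64)
    inv[ss.sa] = np.arange(n)
    return inv[(ss.sa - 1) % n]
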