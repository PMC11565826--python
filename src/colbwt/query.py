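"""Pseudo-matching lengths and chain statistics in one right-to-left pass.

For a read P[1..m] the engine tracks a single BWT position p and a match
length l.  If the BWT symbol at p equals the current read symbol the
match extends (l += 1) and p takes one LF step; on mismatch, thresholds
reposition p to the nearest run of the wanted symbol (the run below when
p is at-or-above the threshold separating the flanking runs, the run
above otherwise), after which the symbol matches by construction
(l = 1).  After the LF step for position i, p corresponds to an
occurrence of P[i..] in the indexed text; PML[i] = l and CID[i] is the
tunnel id of the sub-run containing p (0 if unmarked).

N and any symbol absent from the index alphabet always mismatch and
force l back to 0 without moving p.

An exact matching-statistics oracle (binary search over the full suffix
array) is provided for tests; the production path above never touches
the suffix array or the text.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .index import ColBWTIndex
from .sequences import DNA_ORDER
from .suffix import SuffixStructures


@dataclass
class QueryResult:
    pml: np.ndarray  # int64, length m
    cid: np.ndarray  # int64, length m
    trace: np.ndarray | None  # tracked BWT position per step (test mode), -1 = none
    steps: int  # index operations performed (LF steps + threshold jumps)
    resets: int = 0  # mismatch repositionings (excluding the initial placement)

    @property
    def m(self) -> int:
        return int(self.pml.size)


def _query_cache(index: ColBWTIndex):
    """Plain-list mirrors of the index arrays for the hot loop."""
    cache = getattr(index, "_qcache", None)
    if cache is not None:
        return cache
    mt = index.mt
    run_start = mt.run_start.tolist()
    run_char = mt.run_char.tolist()
    lf_dest = mt.lf_dest.tolist()
    lf_dest_run = mt.lf_dest_run.tolist()
    seg_starts = index.col.seg_starts.tolist()
    seg_ends = (index.col.seg_starts + index.col.seg_lens).tolist()
    seg_ids = index.col.seg_ids.tolist()
    char_runs = {}
    for c, (ridx, thr) in index.thresholds.by_char.items():
        if c < index.base_code:
            continue  # separators/sentinel never match read symbols
        starts = [run_start[i] for i in ridx]
        ends = [
            run_start[i + 1] - 1 if i + 1 < len(run_start) else index.n - 1
            for i in ridx
        ]
        char_runs[int(c)] = (starts, ends, [int(i) for i in ridx], thr.tolist())
    codes = {}
    for i, ch in enumerate(DNA_ORDER):
        codes[ch] = index.base_code + i
    cache = (run_start, run_char, lf_dest, lf_dest_run, seg_starts, seg_ends,
             seg_ids, char_runs, codes)
    index._qcache = cache
    return cache


def query_pml_cid(index: ColBWTIndex, read: str, keep_trace: bool = False) -> QueryResult:
    """PML and CID arrays for one read (uppercase DNA string)."""
    (run_start, run_char, lf_dest, lf_dest_run, seg_starts, seg_ends, seg_ids,
     char_runs, codes) = _query_cache(index)
    m = len(read)
    pml = np.zeros(m, dtype=np.int64)
    cid = np.zeros(m, dtype=np.int64)
    trace = np.full(m, -1, dtype=np.int64) if keep_trace else None
    if m == 0:
        return QueryResult(pml=pml, cid=cid, trace=trace, steps=0)
    R = len(run_start)
    p = -1
    run = -1
    l = 0
    steps = 0
    resets = 0
    base = index.base_code
    n_code = base + DNA_ORDER.index("N")
    for i in range(m - 1, -1, -1):
        c = codes.get(read[i], -1)
        if c == n_code:
            c = -1  # N always mismatches, forcing a reset
        entry = char_runs.get(c) if c >= 0 else None
        if entry is None:
            l = 0
            continue  # pml/cid stay 0; tracked position unchanged
        if p >= 0 and run_char[run] == c:
            l += 1
        else:
            starts, ends, ridx, thr = entry
            steps += 1
            if p < 0:
                j = len(starts) - 1  # start of the last run of this symbol
                p = starts[j]
                run = ridx[j]
            else:
                resets += 1
                j = bisect_right(starts, p) - 1
                if j < 0:
                    p = starts[0]
                    run = ridx[0]
                elif j == len(starts) - 1:
                    p = ends[j]
                    run = ridx[j]
                elif p >= thr[j]:
                    p = starts[j + 1]
                    run = ridx[j + 1]
                else:
                    p = ends[j]
                    run = ridx[j]
            l = 1
        # LF step with run tracking
        dest = lf_dest[run] + (p - run_start[run])
        run = lf_dest_run[run]
        while run + 1 < R and dest >= run_start[run + 1]:
            run += 1
        p = dest
        steps += 1
        pml[i] = l
        k = bisect_right(seg_starts, p) - 1
        if k >= 0 and p < seg_ends[k]:
            cid[i] = seg_ids[k]
        if keep_trace:
            trace[i] = p
    return QueryResult(pml=pml, cid=cid, trace=trace, steps=steps, resets=resets)


# ---------------------------------------------------------------------------
# exact matching statistics (oracle mode)


@dataclass
class MatchingStatistics:
    lens: np.ndarray
    pos: np.ndarray  # one text position of the stated occurrence (-1 if len 0)


def query_ms_oracle(ss: SuffixStructures, read: str) -> MatchingStatistics:
    """Exact MS by per-suffix binary search over the full suffix array."""
    pat = ss.ct.encode(read)
    text = ss.ct.text
    sa = ss.sa
    n = ss.n
    m = len(read)
    lens = np.zeros(m, dtype=np.int64)
    pos = np.full(m, -1, dtype=np.int64)

    def match_len(start: int, pi: int) -> int:
        k = 0
        while start + k < n and pi + k < m and text[start + k] == pat[pi + k]:
            k += 1
        return k

    def suffix_less(start: int, pi: int) -> bool:
        k = match_len(start, pi)
        if pi + k == m:
            return False  # pattern suffix is a prefix of the text suffix
        if start + k == n:
            return True
        return bool(text[start + k] < pat[pi + k])

    for i in range(m):
        if pat[i] < 0:
            continue
        lo, hi = 0, n
        while lo < hi:
            mid = (lo + hi) // 2
            if suffix_less(int(sa[mid]), i):
                lo = mid + 1
            else:
                hi = mid
        best, best_pos = 0, -1
        for j in (lo - 1, lo):
            if 0 <= j < n:
                k = match_len(int(sa[j]), i)
                if k > best:
                    best, best_pos = k, int(sa[j])
        lens[i] = best
        pos[i] = best_pos
    return MatchingStatistics(lens=lens, pos=pos)
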