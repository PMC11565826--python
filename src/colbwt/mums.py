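"""Multi-maximal unique matches (multi-MUMs).

A multi-MUM of a collection of d documents is a string occurring exactly
once in every document that cannot be extended left or right without a
mismatch in some pair of occurrences.  Over the separator-joined suffix
structures every multi-MUM shows up as a width-d SA window satisfying
purely local criteria, which makes a single vectorised sweep over the SA
sufficient.  A substring-enumeration oracle over the raw documents is
provided for cross-checking.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .sequences import DocumentCollection
from .suffix import SuffixStructures


@dataclass(frozen=True)
class MultiMUM:
    """One multi-MUM: SA window start ``s``, width ``w`` and per-document
    content-local start offsets (index i = document i)."""

    s: int
    w: int
    positions: tuple[int, ...]
    id: int = 0  # 1-based label assigned when collected into a set


@dataclass
class MultiMUMSet:
    mums: list[MultiMUM] = field(default_factory=list)
    d: int = 0

    @property
    def u(self) -> int:
        return len(self.mums)

    @property
    def S(self) -> np.ndarray:
        return np.array([m.s for m in self.mums], dtype=np.int64)

    @property
    def W(self) -> np.ndarray:
        return np.array([m.w for m in self.mums], dtype=np.int64)

    def strings(self, coll: DocumentCollection) -> list[str]:
        out = []
        for m in self.mums:
            p = m.positions[0]
            out.append(coll.seqs[0][p : p + m.w])
        return out

    def as_keyset(self, coll: DocumentCollection) -> set[tuple[str, tuple[int, ...]]]:
        """(string, positions) set for exact comparisons between finders."""
        return {(s, m.positions) for s, m in zip(self.strings(coll), self.mums)}


def find_multimums(ss: SuffixStructures, d: int, min_len: int = 1) -> MultiMUMSet:
    """All multi-MUMs via the SA-window criteria.

    A window [i, i+d) is a multi-MUM with width
    ``w = min(LCP[i+1..i+d-1])`` iff ``w > LCP[i]``, ``w > LCP[i+d]``
    (0 past the array end), the window's d document indices are all
    distinct, and the d BWT symbols are not all equal.  Suffixes starting
    at separators cannot enter a window with w >= 1 because separator
    symbols are unique in the text.
    """
    if d < 2:
        raise ValueError("multi-MUM computation requires at least 2 documents")
    n = ss.n
    if n < d:
        return MultiMUMSet(d=d)
    lcp = ss.lcp
    da = ss.da.astype(np.int64)
    bwt = ss.bwt

    n_win = n - d + 1  # candidate window starts i in [0, n-d]
    if d == 2:
        w = lcp[1 : n_win + 1]
    else:
        interior = np.lib.stride_tricks.sliding_window_view(lcp[1:], d - 1)
        w = interior[:n_win].min(axis=1)
    lcp_left = lcp[:n_win]
    lcp_right = np.zeros(n_win, dtype=np.int64)
    lcp_right[: n - d] = lcp[d:]

    da_win = np.lib.stride_tricks.sliding_window_view(da, d)[:n_win]
    da_sorted = np.sort(da_win, axis=1)
    distinct = (np.diff(da_sorted, axis=1) > 0).all(axis=1)

    bwt_win = np.lib.stride_tricks.sliding_window_view(bwt, d)[:n_win]
    not_all_equal = (bwt_win != bwt_win[:, :1]).any(axis=1)

    min_w = max(int(min_len), 1)
    ok = (w >= min_w) & (w > lcp_left) & (w > lcp_right) & distinct & not_all_equal
    starts = np.flatnonzero(ok)

    mums: list[MultiMUM] = []
    for rank, i in enumerate(starts, start=1):
        i = int(i)
        docs = da[i : i + d]
        text_pos = ss.sa[i : i + d]
        local = np.empty(d, dtype=np.int64)
        local[docs] = text_pos - ss.ct.doc_start[docs]
        mums.append(
            MultiMUM(s=i, w=int(w[i]), positions=tuple(int(x) for x in local), id=rank)
        )
    return MultiMUMSet(mums=mums, d=d)


def brute_force_multimums(coll: DocumentCollection, min_len: int = 1) -> MultiMUMSet:
    """Definition-level oracle: enumerate substrings, keep those occurring
    exactly once in every document, then keep the unextendable ones.

    Intended for small inputs (total length up to a few thousand);
    independent of the suffix structures.
    """
    seqs = coll.seqs
    d = coll.d
    min_w = max(int(min_len), 1)
    found: list[MultiMUM] = []
    max_w = min(len(s) for s in seqs)
    for w in range(min_w, max_w + 1):
        counters = [Counter(s[i : i + w] for i in range(len(s) - w + 1)) for s in seqs]
        shared = [t for t, c in counters[0].items() if c == 1]
        any_alive = False
        for t in shared:
            occs = []
            unique = True
            for s, cnt in zip(seqs, counters):
                if cnt.get(t, 0) != 1:
                    unique = False
                    break
                occs.append(s.index(t))
            if not unique:
                continue
            any_alive = True
            # maximality: extendable iff the flanking symbol is in range and
            # identical across every document on that side
            left_ext = all(p > 0 for p in occs) and len(
                {s[p - 1] for s, p in zip(seqs, occs)}
            ) == 1
            right_ext = all(p + w < len(s) for s, p in zip(seqs, occs)) and len(
                {s[p + w] for s, p in zip(seqs, occs)}
            ) == 1
            if not left_ext and not right_ext:
                found.append(MultiMUM(s=-1, w=w, positions=tuple(occs)))
        # once no width-w string occurs in all documents at all, longer
        # widths cannot either
        if not any_alive and not any(
            all(cnt.get(t, 0) >= 1 for cnt in counters) for t in counters[0]
        ):
            break
    found.sort(key=lambda m: (m.positions[0], m.w))
    found = [
        MultiMUM(s=m.s, w=m.w, positions=m.positions, id=k + 1)
        for k, m in enumerate(found)
    ]
    return MultiMUMSet(mums=found, d=d)
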