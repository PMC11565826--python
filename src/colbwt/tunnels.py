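"""Multi-MUM tunnels: non-overlapping suffix intervals carved from the BWT.

Each multi-MUM occupies a height-d SA window.  Forward stepping (FL) from
that window produces, for as long as the image stays a contiguous block,
a sequence of *columns*: height-d single-symbol sub-runs of the BWT.  A
*tunnel* is such a column sequence; a tunnel *set* additionally requires
that no BWT position is claimed by two tunnels, which is enforced by
truncating a tunnel at the first collision with an earlier-claimed
position.  Tunnels are processed longest-first (ties by SA rank) so the
widest matches keep their full extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mums import MultiMUMSet
from .suffix import MoveTables, RLBWT, SuffixStructures


@dataclass
class Tunnel:
    mum_id: int
    width: int  # w of the source multi-MUM
    col_starts: list[int]  # start of column x at index x-1; each column spans d rows
    d: int

    @property
    def w_prime(self) -> int:
        return len(self.col_starts)


@dataclass
class TunnelSet:
    tunnels: list[Tunnel] = field(default_factory=list)
    d: int = 0
    n: int = 0
    mode: str = "tunnels"

    def claimed_positions(self) -> set[int]:
        out: set[int] = set()
        for t in self.tunnels:
            for q in t.col_starts:
                out.update(range(q, q + self.d))
        return out

    def n_columns(self) -> int:
        return sum(t.w_prime for t in self.tunnels)

    def position_map(self) -> dict[int, tuple[int, int]]:
        """BWT position -> (mum_id, column index x >= 1); later tunnels win
        on overlap (only possible in mode='all')."""
        out: dict[int, tuple[int, int]] = {}
        for t in self.tunnels:
            for x, q in enumerate(t.col_starts, start=1):
                for p in range(q, q + self.d):
                    out[p] = (t.mum_id, x)
        return out


def build_tunnels(
    mums: MultiMUMSet,
    mt: MoveTables,
    rl: RLBWT,
    mode: str = "tunnels",
) -> TunnelSet:
    """Forward-step every multi-MUM window into tunnel columns.

    mode='tunnels': a step is accepted only while (a) the FL image is a
    contiguous block, (b) the step count does not exceed the multi-MUM
    width, and (c) in mode='tunnels' no image position was already
    claimed; the first violation ends the tunnel (truncation for (c)).

    mode='all': the claim check is dropped; overlapping positions belong
    to whichever tunnel was processed last (worst-case linear space).
    """
    if mode not in ("tunnels", "all"):
        raise ValueError(f"unknown tunnel mode {mode!r}")
    d = mums.d
    n = mt.n
    claimed = np.zeros(n, dtype=bool)
    order = sorted(mums.mums, key=lambda m: (-m.w, m.s))
    tunnels: list[Tunnel] = []
    run_char = rl.chars
    run_starts = rl.starts
    for m in order:
        cols: list[int] = []
        lo, hi = m.s, m.s + d - 1
        for _x in range(1, m.w + 1):  # (b): at most w steps
            flo, fhi, contig = mt.fl_range(lo, hi)
            if not contig:
                break
            if mode == "tunnels" and claimed[flo : fhi + 1].any():
                break
            # Cor. 1 sanity: a contiguous image reached within w steps is a
            # single-symbol block (all source suffixes share their first
            # symbol); assert cheaply via the run containing flo.
            j = int(np.searchsorted(run_starts, flo, side="right") - 1)
            run_end = int(run_starts[j + 1]) if j + 1 < rl.r else n
            if fhi >= run_end:
                break  # straddles a run boundary: not a single-symbol column
            cols.append(flo)
            if mode == "tunnels":
                claimed[flo : fhi + 1] = True
            lo, hi = flo, fhi
        if cols:
            tunnels.append(Tunnel(mum_id=m.id, width=m.w, col_starts=cols, d=d))
    tunnels.sort(key=lambda t: t.mum_id)
    return TunnelSet(tunnels=tunnels, d=d, n=n, mode=mode)


@dataclass
class TunnelReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_tunnel_set(
    ts: TunnelSet, ss: SuffixStructures, mums: MultiMUMSet, mt: MoveTables
) -> TunnelReport:
    """Exhaustively check the tunnel-set invariants (test mode).

    Checks: pairwise disjointness of claimed positions (via the
    cardinality identity sum(d * w') == |claimed|), the single-symbol
    height-d column property, that LF of each tunnel's first column start
    lands in the source multi-MUM's SA window, and the bound
    (#distinct column starts) <= n / d.
    """
    rep = TunnelReport()
    d = ts.d
    bwt = ss.bwt
    claimed = ts.claimed_positions()
    if ts.mode == "tunnels" and ts.n_columns() * d != len(claimed):
        rep.violations.append(
            f"overlap: {ts.n_columns() * d} column cells but {len(claimed)} distinct positions"
        )
    col_starts = {q for t in ts.tunnels for q in t.col_starts}
    if len(col_starts) > ts.n // d:
        rep.violations.append(f"{len(col_starts)} column starts exceeds n/d = {ts.n // d}")
    by_id = {m.id: m for m in mums.mums}
    for t in ts.tunnels:
        src = by_id[t.mum_id]
        for x, q in enumerate(t.col_starts, start=1):
            col = bwt[q : q + d]
            if col.size != d or not (col == col[0]).all():
                rep.violations.append(
                    f"tunnel {t.mum_id} column {x} at {q} is not a height-{d} single-symbol block"
                )
        back = mt.lf(t.col_starts[0])
        if back != src.s:
            rep.violations.append(
                f"tunnel {t.mum_id}: LF of first column start {t.col_starts[0]} "
                f"is {back}, not the multi-MUM window start {src.s}"
            )
    return rep
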