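"""The queryable marked index: RLBWT split into id-carrying sub-runs.

Tunnel columns (optionally sub-sampled: offsets 0, s, 2s, ... from the
first column of each tunnel) are written into the run-length BWT as
*marked sub-runs*.  Each marked sub-run carries the id of its multi-MUM
tunnel, binned into ``id_bits`` bits with 0 reserved for "unmarked"
(binning can alias distinct tunnels — false positives of id equality are
allowed by design, false negatives are not).  The index object bundles
everything the production query path may touch: sub-runs, move tables,
thresholds and the alphabet map — never the suffix array or the text.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
import numpy as np

from .mums import MultiMUMSet, find_multimums
from .sequences import ConcatText, DNA_ORDER, DocumentCollection, augment_revcomp, concatenate
from .suffix import (
    MoveTables,
    RLBWT,
    SuffixStructures,
    Thresholds,
    build_move_tables,
    build_suffix_structures,
    compute_thresholds,
    run_length_encode,
)
from .tunnels import TunnelSet, build_tunnels

logger = logging.getLogger(__name__)

MAGIC = b"COLBWT\x01"


def bin_id(mum_id: int, id_bits: int) -> int:
    """Fold a 1-based tunnel id into id_bits, keeping 0 for 'unmarked'."""
    cap = (1 << id_bits) - 1
    return 1 + ((mum_id - 1) % cap)


@dataclass
class ColRLBWT:
    """Sub-run view of the BWT with tunnel ids.

    ``sub_starts/sub_chars/sub_lens/sub_ids`` enumerate every sub-run in
    BWT order; unmarked sub-runs have id 0.  ``seg_starts/seg_lens/
    seg_ids`` list only the marked segments (sorted, disjoint) for O(log)
    id lookup.
    """

    sub_starts: np.ndarray
    sub_chars: np.ndarray
    sub_lens: np.ndarray
    sub_ids: np.ndarray
    seg_starts: np.ndarray
    seg_lens: np.ndarray
    seg_ids: np.ndarray
    n: int
    d: int
    sample_rate: int
    id_bits: int
    mode: str

    @property
    def r_prime(self) -> int:
        return int(self.sub_starts.size)

    def id_at(self, p: int) -> int:
        if not 0 <= p < self.n:
            raise IndexError(f"position {p} out of range [0,{self.n})")
        j = int(np.searchsorted(self.seg_starts, p, side="right") - 1)
        if j >= 0 and p < self.seg_starts[j] + self.seg_lens[j]:
            return int(self.seg_ids[j])
        return 0

    def expand_bwt(self) -> np.ndarray:
        return np.repeat(self.sub_chars, self.sub_lens)


def sampled_columns(ts: TunnelSet, sample_rate: int) -> list[tuple[int, int]]:
    """(column start, mum_id) pairs kept after sub-sampling.

    Offsets are measured from each tunnel's first column and the offset-0
    column is always marked, so a match extending >= s consecutive steps
    inside a tunnel is guaranteed to cross a sampled column.
    """
    out = []
    for t in ts.tunnels:
        for off in range(0, t.w_prime, sample_rate):
            out.append((t.col_starts[off], t.mum_id))
    return out


def build_colbwt(rl: RLBWT, ts: TunnelSet, sample_rate: int = 1, id_bits: int = 8) -> ColRLBWT:
    if sample_rate < 1:
        raise ValueError("sample_rate must be >= 1")
    if id_bits not in (8, 16, 32):
        raise ValueError("id_bits must be 8, 16 or 32")
    n = rl.n
    d = ts.d
    cols = sampled_columns(ts, sample_rate)

    # per-position id image of the marked columns; in mode='all' overlaps
    # resolve to the last writer (tunnel processing order)
    ids = np.zeros(n, dtype=np.int64)
    n_aliased = 0
    seen_bins: dict[int, int] = {}
    for q, mid in cols:
        b = bin_id(mid, id_bits)
        if b in seen_bins and seen_bins[b] != mid:
            n_aliased += 1
        seen_bins[b] = mid
        ids[q : q + d] = b
    if n_aliased:
        logger.info("id binning aliased %d columns into %d-bit ids", n_aliased, id_bits)

    # boundaries: run starts plus edges of every sampled column
    col_edges = np.array(
        sorted({q for q, _ in cols} | {min(q + d, n) for q, _ in cols}), dtype=np.int64
    )
    bounds = np.unique(np.concatenate([rl.starts, col_edges]))
    bounds = bounds[bounds < n]
    sub_starts = bounds
    sub_lens = np.diff(np.append(bounds, n))
    run_idx = np.searchsorted(rl.starts, sub_starts, side="right") - 1
    sub_chars = rl.chars[run_idx]
    sub_ids = ids[sub_starts]

    marked = np.flatnonzero(sub_ids != 0)
    return ColRLBWT(
        sub_starts=sub_starts,
        sub_chars=sub_chars.astype(np.int32),
        sub_lens=sub_lens,
        sub_ids=sub_ids,
        seg_starts=sub_starts[marked],
        seg_lens=sub_lens[marked],
        seg_ids=sub_ids[marked],
        n=n,
        d=d,
        sample_rate=int(sample_rate),
        id_bits=int(id_bits),
        mode=ts.mode,
    )


@dataclass
class ColBWTIndex:
    """Everything the production query path is allowed to see."""

    col: ColRLBWT
    mt: MoveTables
    thresholds: Thresholds
    n: int
    d: int
    r: int
    u: int  # number of multi-MUMs
    names: list[str] = field(default_factory=list)

    @property
    def base_code(self) -> int:
        return self.d

    def code_of(self, ch: str) -> int:
        return self.d + DNA_ORDER.index(ch)

    def coverage(self) -> float:
        """Fraction of BWT positions inside marked sub-runs."""
        return float(self.col.seg_lens.sum()) / self.n if self.n else 0.0


@dataclass
class BuildResult:
    """Full pipeline output; intermediates retained for tests/oracles."""

    coll: DocumentCollection
    ct: ConcatText
    ss: SuffixStructures
    rl: RLBWT
    mt: MoveTables
    thresholds: Thresholds
    mums: MultiMUMSet
    tunnels: TunnelSet
    index: ColBWTIndex


def build_all(
    coll: DocumentCollection,
    *,
    mode: str = "tunnels",
    sample_rate: int = 1,
    id_bits: int = 8,
    min_mum_len: int = 1,
    revcomp: bool = False,
) -> BuildResult:
    """Run the whole construction pipeline on a collection."""
    if revcomp:
        coll = augment_revcomp(coll)
    ct = concatenate(coll)
    ss = build_suffix_structures(ct)
    rl = run_length_encode(ss.bwt)
    mt = build_move_tables(rl, first_dna_code=ct.base_code)
    thr = compute_thresholds(ss, rl)
    mums = find_multimums(ss, ct.d, min_len=min_mum_len)
    ts = build_tunnels(mums, mt, rl, mode=mode)
    col = build_colbwt(rl, ts, sample_rate=sample_rate, id_bits=id_bits)
    index = ColBWTIndex(
        col=col, mt=mt, thresholds=thr, n=ct.n, d=ct.d, r=rl.r, u=mums.u,
        names=list(ct.names),
    )
    logger.info(
        "built index: n=%d d=%d r=%d r'=%d u=%d tunnels=%d coverage=%.1f%%",
        ct.n, ct.d, rl.r, col.r_prime, mums.u, len(ts.tunnels), 100 * index.coverage(),
    )
    return BuildResult(
        coll=coll, ct=ct, ss=ss, rl=rl, mt=mt, thresholds=thr, mums=mums,
        tunnels=ts, index=index,
    )


def build_index(coll: DocumentCollection, **kwargs) -> ColBWTIndex:
    return build_all(coll, **kwargs).index


# ---------------------------------------------------------------------------
# serialization


class IndexFormatError(ValueError):
    """Raised on bad magic, version or truncated index data."""


def serialize(index: ColBWTIndex) -> bytes:
    header = {
        "n": index.n,
        "d": index.d,
        "r": index.r,
        "u": index.u,
        "names": index.names,
        "sample_rate": index.col.sample_rate,
        "id_bits": index.col.id_bits,
        "mode": index.col.mode,
        "thr_chars": sorted(index.thresholds.by_char),
    }
    arrays = {
        "sub_starts": index.col.sub_starts,
        "sub_chars": index.col.sub_chars,
        "sub_lens": index.col.sub_lens,
        "sub_ids": index.col.sub_ids,
        "run_start": index.mt.run_start,
        "run_char": index.mt.run_char,
        "lf_dest": index.mt.lf_dest,
        "lf_dest_run": index.mt.lf_dest_run,
        "f_start": index.mt.f_start,
        "fl_dest": index.mt.fl_dest,
    }
    for c, (runs, th) in index.thresholds.by_char.items():
        arrays[f"thr_runs_{c}"] = runs
        arrays[f"thr_pos_{c}"] = th
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    payload = buf.getvalue()
    head = json.dumps(header).encode()
    return MAGIC + len(head).to_bytes(4, "little") + head + payload


def deserialize(blob: bytes) -> ColBWTIndex:
    if blob[: len(MAGIC)] != MAGIC:
        raise IndexFormatError("bad magic bytes: not a colbwt index (or wrong version)")
    off = len(MAGIC)
    hlen = int.from_bytes(blob[off : off + 4], "little")
    off += 4
    try:
        header = json.loads(blob[off : off + hlen].decode())
        arrays = np.load(io.BytesIO(blob[off + hlen :]))
        sub_starts = arrays["sub_starts"]
        sub_lens = arrays["sub_lens"]
        sub_ids = arrays["sub_ids"]
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise IndexFormatError(f"truncated or corrupt index data: {exc}") from exc
    marked = np.flatnonzero(sub_ids != 0)
    col = ColRLBWT(
        sub_starts=sub_starts,
        sub_chars=arrays["sub_chars"],
        sub_lens=sub_lens,
        sub_ids=sub_ids,
        seg_starts=sub_starts[marked],
        seg_lens=sub_lens[marked],
        seg_ids=sub_ids[marked],
        n=int(header["n"]),
        d=int(header["d"]),
        sample_rate=int(header["sample_rate"]),
        id_bits=int(header["id_bits"]),
        mode=header["mode"],
    )
    mt = MoveTables(
        n=int(header["n"]),
        run_start=arrays["run_start"],
        run_char=arrays["run_char"],
        lf_dest=arrays["lf_dest"],
        lf_dest_run=arrays["lf_dest_run"],
        f_start=arrays["f_start"],
        fl_dest=arrays["fl_dest"],
        first_dna_code=int(header["d"]),
    )
    by_char = {
        int(c): (arrays[f"thr_runs_{c}"], arrays[f"thr_pos_{c}"])
        for c in header["thr_chars"]
    }
    return ColBWTIndex(
        col=col,
        mt=mt,
        thresholds=Thresholds(by_char=by_char),
        n=int(header["n"]),
        d=int(header["d"]),
        r=int(header["r"]),
        u=int(header["u"]),
        names=list(header["names"]),
    )
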