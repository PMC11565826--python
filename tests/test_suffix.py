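"""Suffix structures against naive oracles; move-table stepping; thresholds."""

import numpy as np
import pytest

import colbwt as cb
from colbwt.suffix import (
    build_suffix_array,
    invert_bwt,
    naive_lf,
    naive_suffix_array,
)

from conftest import related_collection, unrelated_collection


def _random_build(rng, i):
    if i % 3 == 0:
        coll = unrelated_collection(rng, int(rng.integers(2, 5)), 80)
    else:
        coll = related_collection(rng, int(rng.integers(2, 5)), int(rng.integers(30, 120)))
    return cb.build_all(coll)


def test_suffix_array_matches_naive_sort(rng):
    for i in range(15):
        b = _random_build(rng, i)
        assert (b.ss.sa == naive_suffix_array(b.ct.text)).all()


def test_lcp_matches_direct_comparison(rng):
    for i in range(8):
        b = _random_build(rng, i)
        t = b.ct.text
        n = b.ct.n
        for r in range(1, n):
            a, c = int(b.ss.sa[r - 1]), int(b.ss.sa[r])
            k = 0
            while a + k < n and c + k < n and t[a + k] == t[c + k]:
                k += 1
            assert int(b.ss.lcp[r]) == k
        assert int(b.ss.lcp[0]) == 0


def test_bwt_definition_and_sentinel_only_text():
    coll = cb.collection_from_seqs(["ACAC", "ACCA"])
    b = cb.build_all(coll)
    n = b.ct.n
    assert (b.ss.bwt == b.ct.text[(b.ss.sa - 1) % n]).all()
    # degenerate single-symbol text behaves
    sa = build_suffix_array(np.array([0], dtype=np.int32))
    assert sa.tolist() == [0]


def test_bwt_inversion_reconstructs_text(rng):
    for i in range(6):
        b = _random_build(rng, i)
        assert (invert_bwt(b.mt, b.rl) == b.ct.text).all()


def test_lf_fl_are_mutually_inverse_permutations(rng):
    b = cb.build_all(related_collection(rng, 3, 70))
    n = b.ct.n
    lf_oracle = naive_lf(b.ss)
    for i in range(n):
        assert b.mt.lf(i) == lf_oracle[i]
        assert b.mt.fl(int(lf_oracle[i])) == i
        assert b.mt.lf(b.mt.fl(i)) == i
    # n successive LF steps from any position return to it (single cycle)
    p = 5 % n
    seen = set()
    q = p
    for _ in range(n):
        seen.add(q)
        q = b.mt.lf(q)
    assert q == p and len(seen) == n


def test_lf_step_run_tracking_agrees_with_lf(rng):
    b = cb.build_all(related_collection(rng, 3, 90))
    for p in range(b.ct.n):
        run = b.mt.run_of(p)
        dest, drun = b.mt.lf_step(p, run)
        assert dest == b.mt.lf(p)
        assert b.mt.run_of(dest) == drun


def test_fl_range_contiguity_flag(rng):
    b = cb.build_all(related_collection(rng, 3, 120, rate=0.1))
    n = b.ct.n
    found_noncontig = False
    for lo in range(0, n - 3):
        hi = lo + 2
        flo, fhi, contig = b.mt.fl_range(lo, hi)
        images = [b.mt.fl(p) for p in range(lo, hi + 1)]
        expected = images == list(range(images[0], images[0] + 3))
        assert contig == expected
        assert flo == images[0] and fhi == images[-1]
        found_noncontig |= not contig
    assert found_noncontig  # interleaved FL images do occur and are flagged


def test_out_of_range_positions_rejected(gatta_build):
    with pytest.raises(IndexError):
        gatta_build.mt.lf(gatta_build.ct.n)
    with pytest.raises(IndexError):
        gatta_build.mt.fl(-1)


@pytest.mark.parametrize(
    "bwt,expected",
    [
        ("AAACCA", [("A", 3), ("C", 2), ("A", 1)]),
        ("AAAA", [("A", 4)]),
        ("ACGT", [("A", 1), ("C", 1), ("G", 1), ("T", 1)]),
    ],
)
def test_run_length_encode_examples(bwt, expected):
    codes = np.frombuffer(bwt.encode(), dtype=np.uint8).astype(np.int32)
    rl = cb.run_length_encode(codes)
    got = [(chr(c), int(l)) for c, l in zip(rl.chars, rl.lens)]
    assert got == expected
    assert rl.r == len(expected)
    assert int(rl.lens.sum()) == len(bwt)


def test_run_count_matches_scan_oracle(rng):
    bwt = rng.integers(0, 3, 500).astype(np.int32)
    rl = cb.run_length_encode(bwt)
    assert rl.r == 1 + int((bwt[1:] != bwt[:-1]).sum())
    assert (rl.expand() == bwt).all()


def test_thresholds_match_exhaustive_argmin(rng):
    for trial in range(5):
        b = cb.build_all(related_collection(rng, 3, 160, rate=0.08))
        lcp = b.ss.lcp
        for c, (ridx, th) in b.thresholds.by_char.items():
            starts = b.rl.starts[ridx]
            ends = starts + b.rl.lens[ridx] - 1
            assert th.size == max(ridx.size - 1, 0)
            for j in range(ridx.size - 1):
                a = int(ends[j]) + 1
                bb = int(starts[j + 1])
                seg = lcp[a : bb + 1]
                best = min(seg)
                expect = a + min(i for i, v in enumerate(seg) if v == best)
                assert int(th[j]) == expect
                # stored position lies between the two runs it separates
                assert ends[j] < th[j] <= starts[j + 1]


def test_single_run_symbol_has_no_thresholds(gatta_build):
    for c, (ridx, th) in gatta_build.thresholds.by_char.items():
        if ridx.size == 1:
            assert th.size == 0
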