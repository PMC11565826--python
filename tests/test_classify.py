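"""Peak extraction, co-linear pairs, null calibration and the four schemes."""

import numpy as np
import pytest

import colbwt as cb
from colbwt.classify import (
    Peak,
    _window_majority,
    colinear_pairs,
    merge_colinear,
    significant_peak_threshold,
)
from colbwt.query import QueryResult

from conftest import random_seq, related_collection


def _qr(pml, cid=None):
    pml = np.asarray(pml, dtype=np.int64)
    cid = np.zeros_like(pml) if cid is None else np.asarray(cid, dtype=np.int64)
    return QueryResult(pml=pml, cid=cid, trace=None, steps=0)


@pytest.mark.parametrize(
    "pml,expected",
    [
        ([4, 3, 2, 1], [(0, 3, 4)]),
        ([3, 2, 1, 0, 5, 4, 3, 2, 1], [(0, 2, 3), (4, 8, 5)]),
        ([0, 0, 0], []),
        ([2, 2], [(0, 0, 2), (1, 1, 2)]),  # a non-decrement splits peaks
        ([1, 5, 4], [(0, 0, 1), (1, 2, 5)]),
    ],
)
def test_extract_peaks_follows_decrement_rule(pml, expected):
    peaks = cb.extract_peaks(_qr(pml))
    assert [(p.start, p.end, p.height) for p in peaks] == expected


def test_peak_boundary_ids_are_first_and_last_nonzero():
    peaks = cb.extract_peaks(_qr([3, 2, 1], [0, 7, 9]))
    assert peaks[0].first_id == 7 and peaks[0].last_id == 9
    peaks = cb.extract_peaks(_qr([3, 2, 1], [0, 0, 0]))
    assert peaks[0].first_id == 0 and peaks[0].last_id == 0


@pytest.mark.parametrize("k,expected", [(19, 10), (5, 3), (0, 1), (1, 1)])
def test_significant_peak_threshold_formula(k, expected):
    assert significant_peak_threshold(k) == expected


def _peak(start, end, height, first_id, last_id):
    return Peak(start=start, end=end, height=height, first_id=first_id, last_id=last_id)


def test_colinear_pairs_id_matching():
    a = _peak(0, 9, 10, 7, 7)
    b = _peak(12, 21, 10, 7, 7)
    c = _peak(24, 33, 10, 9, 9)
    assert colinear_pairs([a, b], 5)[0] == 1
    assert colinear_pairs([a, c], 5)[0] == 0
    zero = _peak(0, 9, 10, 0, 0)
    assert colinear_pairs([zero, b], 5)[0] == 0  # zero ids never co-linear


def test_colinear_pairs_skip_insignificant_peaks():
    a = _peak(0, 9, 10, 3, 3)
    small = _peak(10, 11, 2, 8, 8)
    b = _peak(12, 21, 10, 3, 3)
    colinear, pairs, chosen = colinear_pairs([a, small, b], 5)
    assert pairs == 1 and colinear == 1  # small peak dropped, survivors paired
    assert chosen == [(a, b)]


def test_merge_colinear_is_monotone_and_shaped(rng):
    pml = np.array([5, 4, 3, 1, 9, 8, 7, 6, 5, 4], dtype=np.int64)
    a = _peak(0, 2, 5, 4, 4)
    b = _peak(4, 9, 9, 4, 4)
    aug = merge_colinear(pml, [(a, b)])
    assert (aug >= pml).all()
    # positions in [start1, end2] behave like one match ending at end2
    assert aug[0] == 10 and aug[3] == 7 and aug[9] == 4


def test_window_majority_semantics():
    pml = np.array([0] * 10 + [9] * 10, dtype=np.int64)
    # two windows of 10: one passes at k=5 -> not a strict majority
    assert _window_majority(pml, 5, 10)[0] is False
    # final partial window counts as a window
    verdict, n_win, passed = _window_majority(np.array([9] * 15), 5, 10)
    assert n_win == 2 and passed == 2 and verdict


def test_calibration_deterministic_and_k_attained(rng):
    coll = related_collection(rng, 3, 3000, rate=0.01)
    b = cb.build_all(coll, sample_rate=1, id_bits=32)
    null1 = cb.calibrate_null(b.index, coll, n_null=40, len_null=500, seed=5)
    null2 = cb.calibrate_null(b.index, coll, n_null=40, len_null=500, seed=5)
    assert (null1.k, null1.rho_null) == (null2.k, null2.rho_null)
    assert null1.peak_threshold == significant_peak_threshold(null1.k)
    # k is attained >= min_count times and no larger value is
    pmls = []
    rng2 = np.random.default_rng(5)
    lens = np.array([len(s) for s in coll.seqs], dtype=np.float64)
    eligible = np.flatnonzero(lens >= 500)
    weights = lens[eligible] / lens[eligible].sum()
    for _ in range(40):
        doc = int(rng2.choice(eligible, p=weights))
        s = coll.seqs[doc]
        st = int(rng2.integers(0, len(s) - 500 + 1))
        pmls.append(cb.query_pml_cid(b.index, s[st : st + 500][::-1]).pml)
    counts = np.bincount(np.concatenate(pmls))
    assert counts[null1.k] >= 5
    assert not (counts[null1.k + 1 :] >= 5).any()


def test_calibration_rejects_short_reference():
    coll = cb.collection_from_seqs(["ACGTACGT", "ACGTACGA"])
    b = cb.build_all(coll)
    with pytest.raises(ValueError, match="shorter"):
        cb.calibrate_null(b.index, coll, n_null=5, len_null=100)


@pytest.fixture(scope="module")
def classified_fixture():
    rng = np.random.default_rng(99)
    coll = related_collection(rng, 3, 4000, rate=0.005)
    b = cb.build_all(coll, sample_rate=1, id_bits=32)
    null = cb.calibrate_null(b.index, coll, n_null=60, len_null=600, seed=3)
    return b, null


def test_matching_read_positive_random_read_negative(classified_fixture, rng):
    b, null = classified_fixture
    coll = b.coll
    pos_read = coll.seqs[0][500:1400]
    res = cb.classify_read(cb.query_pml_cid(b.index, pos_read), null)
    assert res.baseline and res.scheme_b and res.scheme_c
    neg_read = random_seq(rng, 900)
    res = cb.classify_read(cb.query_pml_cid(b.index, neg_read), null)
    assert not (res.baseline or res.scheme_a or res.scheme_b or res.scheme_c)


def test_scheme_c_is_baseline_or_a(classified_fixture, rng):
    b, null = classified_fixture
    for _ in range(12):
        read = (
            b.coll.seqs[0][200:900]
            if rng.random() < 0.5
            else random_seq(rng, 700)
        )
        res = cb.classify_read(cb.query_pml_cid(b.index, read), null)
        assert res.scheme_c == (res.baseline or res.scheme_a)


def test_summarize_counts():
    stats = cb.summarize([True, True, False, False], [True, False, False, True])
    assert stats["sensitivity"] == 0.5
    assert stats["specificity"] == 0.5
    assert stats["accuracy"] == 0.5
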