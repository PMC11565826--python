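"""Peak extraction, null calibration and read classification.

Because a PML either extends by one (moving left) or resets, the PML
array of a read decomposes into *peaks*: maximal stretches decreasing by
exactly 1 left-to-right.  Each peak is one exact-match region.  Two
consecutive *significant* peaks (height >= the significant-peak
threshold; smaller peaks are ignored) are called *co-linear* when the
last tunnel id seen in the first peak equals the first id seen in the
second and both are nonzero — the coarse-grained evidence that both
matches come from the same reference locus.

Classification is calibrated on a null distribution of PMLs obtained by
querying reversed reference substrings (random sequences with the
reference's base composition).  k is the largest PML occurring at least
``min_count`` times in the null; the significant-peak threshold defaults
to ceil((k+1)/2); rho_null is the expected per-base rate of co-linear
pairs under the null.  Schemes:

  baseline  majority of non-overlapping windows contain a PML > k
  a         (#co-linear pairs) / read length > rho_null
  b         baseline after merging each co-linear pair into one
            uninterrupted pseudo-match
  c         baseline OR a
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .index import ColBWTIndex
from .query import QueryResult, query_pml_cid
from .sequences import DocumentCollection


@dataclass(frozen=True)
class Peak:
    start: int  # read positions, inclusive span
    end: int
    height: int  # PML at start
    first_id: int  # first nonzero CID within the span (0 if none)
    last_id: int  # last nonzero CID within the span (0 if none)


def extract_peaks(result: QueryResult) -> list[Peak]:
    """Maximal stretches where PML decreases by exactly 1 left-to-right."""
    pml = result.pml
    cid = result.cid
    m = int(pml.size)
    peaks: list[Peak] = []
    i = 0
    while i < m:
        if pml[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < m and pml[j + 1] == pml[j] - 1 and pml[j + 1] > 0:
            j += 1
        ids = cid[i : j + 1]
        nz = np.flatnonzero(ids)
        first_id = int(ids[nz[0]]) if nz.size else 0
        last_id = int(ids[nz[-1]]) if nz.size else 0
        peaks.append(
            Peak(start=i, end=j, height=int(pml[i]), first_id=first_id, last_id=last_id)
        )
        i = j + 1
    return peaks


def significant_peak_threshold(k: int) -> int:
    """Default cutoff ceil((k+1)/2): a significant pair's cumulative height
    must be able to exceed the null threshold k."""
    return (k + 2) // 2


def significant_peaks(peaks: list[Peak], peak_threshold: int) -> list[Peak]:
    return [p for p in peaks if p.height >= peak_threshold]


def colinear_pairs(peaks: list[Peak], peak_threshold: int) -> tuple[int, int, list[tuple[Peak, Peak]]]:
    """Count adjacent co-linear pairs over the significant-peak subsequence.

    Returns (co-linear count, total adjacent significant pairs, the
    co-linear pairs themselves).
    """
    sig = significant_peaks(peaks, peak_threshold)
    pairs = 0
    colinear = 0
    chosen: list[tuple[Peak, Peak]] = []
    for a, b in zip(sig, sig[1:]):
        pairs += 1
        if a.last_id != 0 and a.last_id == b.first_id:
            colinear += 1
            chosen.append((a, b))
    return colinear, pairs, chosen


@dataclass
class NullModel:
    k: int  # largest PML occurring >= min_count times in the null
    peak_threshold: int
    rho_null: float  # expected co-linear pairs per null base
    min_count: int = 5
    window: int = 150


def calibrate_null(
    index: ColBWTIndex,
    coll: DocumentCollection,
    n_null: int = 500,
    len_null: int = 2000,
    min_count: int = 5,
    window: int = 150,
    seed: int = 0,
) -> NullModel:
    """Null model from reversed (not complemented) reference substrings."""
    rng = np.random.default_rng(seed)
    lens = np.array([len(s) for s in coll.seqs], dtype=np.float64)
    if int(lens.max()) < len_null:
        raise ValueError(
            f"reference documents shorter than len_null={len_null}"
        )
    eligible = np.flatnonzero(lens >= len_null)
    weights = lens[eligible] / lens[eligible].sum()
    results: list[QueryResult] = []
    for _ in range(n_null):
        doc = int(rng.choice(eligible, p=weights))
        seq = coll.seqs[doc]
        start = int(rng.integers(0, len(seq) - len_null + 1))
        null_seq = seq[start : start + len_null][::-1]
        results.append(query_pml_cid(index, null_seq))
    pooled = np.concatenate([r.pml for r in results])
    counts = np.bincount(pooled)
    attained = np.flatnonzero(counts >= min_count)
    k = int(attained.max()) if attained.size else 0
    thr = significant_peak_threshold(k)
    total_pairs = 0
    total_bases = 0
    for r in results:
        c, _, _ = colinear_pairs(extract_peaks(r), thr)
        total_pairs += c
        total_bases += r.m
    rho = total_pairs / total_bases if total_bases else 0.0
    return NullModel(k=k, peak_threshold=thr, rho_null=rho, min_count=min_count, window=window)


@dataclass
class ClassificationResult:
    baseline: bool
    scheme_a: bool
    scheme_b: bool
    scheme_c: bool
    n_windows: int = 0
    windows_passed: int = 0
    colinear: int = 0
    sig_pairs: int = 0
    read_len: int = 0

    def verdict(self, scheme: str) -> bool:
        return getattr(self, "baseline" if scheme == "baseline" else f"scheme_{scheme}")


def _window_majority(pml: np.ndarray, k: int, window: int) -> tuple[bool, int, int]:
    m = int(pml.size)
    n_win = max(1, -(-m // window))  # final partial window counts as a window
    passed = 0
    for w in range(n_win):
        chunk = pml[w * window : (w + 1) * window]
        if chunk.size and int(chunk.max()) > k:
            passed += 1
    return passed * 2 > n_win, n_win, passed


def merge_colinear(pml: np.ndarray, pairs: list[tuple[Peak, Peak]]) -> np.ndarray:
    """Augment PMLs as if each co-linear pair were one uninterrupted match
    ending at the second peak's end; never decreases any value."""
    aug = pml.copy()
    for a, b in pairs:
        span = np.arange(a.start, b.end + 1)
        aug[span] = np.maximum(aug[span], b.end - span + 1)
    return aug


def classify_read(result: QueryResult, null: NullModel) -> ClassificationResult:
    pml = result.pml
    m = int(pml.size)
    baseline, n_win, passed = _window_majority(pml, null.k, null.window)
    peaks = extract_peaks(result)
    colinear, sig_pairs, chosen = colinear_pairs(peaks, null.peak_threshold)
    scheme_a = (colinear / m if m else 0.0) > null.rho_null
    aug = merge_colinear(pml, chosen)
    scheme_b, _, _ = _window_majority(aug, null.k, null.window)
    scheme_c = baseline or scheme_a
    return ClassificationResult(
        baseline=baseline,
        scheme_a=scheme_a,
        scheme_b=scheme_b,
        scheme_c=scheme_c,
        n_windows=n_win,
        windows_passed=passed,
        colinear=colinear,
        sig_pairs=sig_pairs,
        read_len=m,
    )


def summarize(labels: list[bool], verdicts: list[bool]) -> dict[str, float]:
    """Sensitivity / specificity / accuracy of verdicts against truth labels."""
    tp = sum(1 for t, v in zip(labels, verdicts) if t and v)
    fn = sum(1 for t, v in zip(labels, verdicts) if t and not v)
    tn = sum(1 for t, v in zip(labels, verdicts) if not t and not v)
    fp = sum(1 for t, v in zip(labels, verdicts) if not t and v)
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": (tp + tn) / len(labels) if labels else float("nan"),
    }
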