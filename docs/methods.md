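# Methods

This note records the model, the parameter choices, the numerical
decisions and the known limits of the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Text model and coordinates

Documents are DNA strings over {A,C,G,T,N}. The indexed text is the
concatenation `T1 #1 T2 #2 ... T(d-1) #(d-1) Td $` with integer codes
`$ = 0 < #1 < ... < #(d-1) < A < C < G < N < T`. Distinct per-document
separators (rather than a single terminator) make cross-document suffix
comparison total and guarantee that no match, and in particular no
multi-MUM, spans a document boundary: a separator symbol occurs exactly
once, so it can never appear inside a common prefix of two distinct
suffixes. All coordinates are 0-based half-open internally; the CLI
reports BED-like 0-based half-open intervals. N is an ordinary fifth
symbol in the text (no masking); in *reads* it is treated as
always-mismatching and forces a PML reset.

Reverse-complement augmentation appends each document's reverse
complement to the document itself, forward strand first, joined
directly; a `junction="n"` option inserts a single N at the junction
instead. Direct joining is the default because the junction k-mers it
fabricates are vanishingly rare at genome scale and a second symbol
class costs more than it buys.

## Construction

The suffix array is built by numpy-vectorised prefix doubling
(Manber–Myers), `O(n log n)` with small constants and adequate well
beyond the megabase scale this package targets; a naive quadratic sort
acts as the independent oracle in tests. LCP is Kasai's algorithm; DA is
a table lookup; the BWT follows from its definition. No prefix-free
parsing or grammar machinery is used: those are large-scale construction
devices, not part of the method's contract.

LF/FL are served by run-indexed tables in the move-structure style: per
run, the image of its first position plus the run containing that image,
so that monotone stepping fast-forwards a run pointer instead of binary
searching (amortised constant per step; arbitrary positions fall back to
a binary search). FL is the inverse table, built by sorting the LF
images, which partition `[0, n)`.

Thresholds are computed directly from the full LCP array: for symbol `c`
and successive `c`-runs `j`, `j+1` ending/starting at rows `e_j`,
`s_{j+1}`, the threshold is the smallest LCP index in `(e_j, s_{j+1}]`
attaining the minimum there (ties to the smallest position; any argmin
preserves PML correctness, the tie-break only fixes determinism). A
mismatching tracked position at-or-above the threshold repositions to
the *following* run's first row, below it to the *preceding* run's last
row — the row whose suffix shares the longer context with the current
one.

## Multi-MUMs and tunnels

The finder sweeps all width-`d` SA windows with vectorised numpy and
applies the window criteria (interior LCP minimum exceeding both
flanking LCPs, distinct document array entries, BWT symbols not all
equal, width at least `max(min_len, 1)`). Because every window with
width ≥ 1 has all suffixes sharing a first symbol and separators are
unique, windows of separator-starting suffixes are excluded for free.
`min_len` defaults to 1 in the library (correctness work) and 20 at the
CLI (a practical default for genome-scale collections). The pairwise
case `d = 2` is accepted.

Tunnels forward-step each multi-MUM window for at most `w` steps,
keeping a step only if the FL image is a contiguous block (checked as
consecutive integers over all `d` rows) and, in `tunnels` mode, claims
no already-claimed position. Claims are tracked in a plain boolean array
— the desk-scale stand-in for a predecessor structure; any membership
structure meeting the same contract would do. Processing order is
descending width, ties by ascending SA rank: deterministic, and
longest-first maximises expected coverage since a truncated wide tunnel
loses more than a truncated narrow one. In `all` mode the claim check is
dropped and overlapped positions keep the id written last in processing
order (worst-case linear space; provided for coverage studies).

A contiguous image reached within `w` steps is automatically a
single-symbol block (all source suffixes still agree on their first
symbol inside the match), so each accepted column is a height-`d`
sub-run of one BWT run; the builder nevertheless asserts this cheaply.

## Marked index

Sampled columns — offsets `0, s, 2s, ...` from each tunnel's first
column — are carved into the RLBWT as id-carrying sub-runs. Offset 0 is
always marked so the guarantee "a match extending ≥ s consecutive steps
inside a tunnel crosses a sampled column" holds from the tunnel head
(any `s` consecutive column offsets contain one ≡ 0 mod `s`). Ids are
stored as `1 + ((id - 1) mod (2^bits - 1))`, reserving 0 for unmarked;
binning can alias distinct tunnels (false positives of id equality,
never false negatives), which is logged at build time. The sub-run count
satisfies the countable bound `r' ≤ r + 2·(distinct marked column
starts)` checked on every build in tests. Serialisation is a single
container: magic + version byte, JSON header, npz payload; written at
run time only.

## Queries

One pass per read, right to left, tracking `(position, run, length)`.
Match: length + 1 and an LF step. Mismatch: threshold repositioning as
above, then length 1 after the LF step (the repositioned row matches the
current symbol by construction). The initial position is the start of
the *last* run of the read's final symbol — an arbitrary but fixed
choice; the first position therefore always reports PML 1, and a read
processed with no resets reports exactly `PML[i] = m - i` (0-based).
`CID[i]` is looked up after the LF step, when the tracked position
corresponds to an occurrence of `P[i..]`, by binary search over the
marked segments. Per-read work is at most two index operations per
position, surfaced as a step counter and asserted in tests.

Because PMLs track a *single* occurrence, a reset can fire even when
some other occurrence would extend (the tracked haplotype diverges);
this is the standard price of PMLs over full matching statistics and the
reason `PML ≤ MS` pointwise, which the tests verify against an exact
suffix-array oracle. The production path touches only sub-runs, move
tables and thresholds; the suffix array and text live in the separate
build-result object used by oracles.

## Classification

Peaks are maximal stretches where PML decreases by exactly 1
left-to-right; zero positions belong to no peak. Peaks below the
significant-peak threshold are dropped and the survivors paired
consecutively; a pair is co-linear iff the first peak's last nonzero id
equals the second's first nonzero id (both nonzero). The null model
draws `n_null = 500` substrings of `len_null = 2000` (defaults;
configurable) from the reference, reverses them (composition-preserving
random sequences), and pools their PMLs: `k` is the largest value
attained ≥ 5 times, the significant-peak threshold is `⌈(k+1)/2⌉` —
two stacked significant peaks can out-weigh one chance match of length
`k` — and `rho_null` is the per-base co-linear pair rate over the null.
Scheme b's merge gives positions in `[start1, end2]` the value
`max(PML[i], end2 - i + 1)`, i.e. one uninterrupted match ending at the
second peak's end; it never decreases a value. Window majority is
strict (> half), and a final partial window counts as a window.

## Synthetic data

The generator draws one uniform base sequence and derives each haplotype
by independent per-site SNVs (uniform alternative base) and optional
geometric-length indels (default off: the peak experiments are SNV
studies). Reads are substrings of haplotypes with independent per-base
substitution errors; negatives come from an unrelated random genome.
This emulates the *contract-relevant* features of a pangenome — shared
sequence broken by per-haplotype variation — but not shared/population-
structured variants, structural variation, nanopore error profiles
(indel-dominated) or base-composition bias. Passing tests therefore
demonstrate the index and classifier machinery, not benchmark-level
accuracy on real data.

Because haplotype SNVs are independent, the density of positions at
which *any* of `d` haplotypes differs is `1 - (1 - p)^d` for per-
haplotype rate `p`, and the mean multi-MUM length is roughly its
inverse. Co-linear pair calling reads an id within ~`s` bases on each
side of every read error, so its accuracy is governed by the ratio of
that window to the mean multi-MUM length: the toy experiment at 1%
pairwise divergence (`p = 0.005`, `d = 8`, mean multi-MUM ≈ 25 bp)
yields low pair-calling accuracy, while dropping divergence by an order
of magnitude (long multi-MUMs, the regime of real human haplotype
panels) sends it above 0.9 — the trend the experiment harness exposes.
Extending marks beyond multi-MUM boundaries ("smearing") or chaining
multi-MUMs would lift the fragmented-MUM regime but is out of scope
here.

Experiment problem sizes (8 × 50 kb panels, hundreds of kilobase-scale
reads, thousands of 1 kb mixture reads) were chosen as the smallest
scales at which every quantity of interest — coverage, pair counts,
null calibration — is well populated.

## Known limitations

- No locate support (no SA samples): queries report lengths and ids,
  not reference coordinates.
- `mode=all` keeps last-writer ids on overlaps; id multiplicity is not
  represented.
- The in-memory build (full SA/LCP) bounds practical collection size to
  a few megabases; the query side itself is `O(r + n/d)`.
- Streaming / adaptive-sampling classification (pausing mid-read) is an
  interface hook only; the classifier consumes whole reads.
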