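# Methods

This note records the model implemented by `moveindex`, the numerical and
design choices that were genuinely open, and what the test suite does and
does not establish.

## Index model

The text T is the concatenation of the input records over Σ = {A,C,G,T} with
a single terminal sentinel `$` smaller than every base (codes: $=0, A=1 …
T=4 internally; the query-facing 2-bit alphabet is A=0 … T=3). All arrays
are 0-based internally; logs and docs use 1-based positions where they
narrate BWM rows.

The build pipeline is: suffix array → BWT → LCP (Kasai) → run-length
encoding → thresholds → thresholds-splitting → length-splitting → head
pointers → variant id column. The suffix array uses numpy prefix doubling
(O(n log² n)); correctness, not construction speed, is the contract, and a
quadratic sort oracle cross-checks it in the tests. Head pointers exploit
LF's stability: the LF-image of the q-th row head of symbol s is
C(s) + (total length of earlier s-rows), so π is a per-symbol cumulative
sum, ξ a binary search of π over row heads, and f = π − head(ξ).

### Thresholds

For adjacent same-symbol runs (i, j) the threshold is chosen as the leftmost
position of the minimum of the LCP array over the candidate interval
(tail(i), head(j)]. Any position satisfying the two LCP dominance conditions
is valid; the leftmost minimum satisfies both by the range-minimum argument
and is deterministic. A brute-force verifier checks both conditions
directly on every computed threshold in the tests.

Direction convention: in-row offset v repositions **up** when v < t and
**down** when v ≥ t (the threshold itself belongs to the "down" half). The
narrative convention "j ≤ t goes up" that circulates for move-structure
repositioning is off by one from the LCP conditions; we follow the
conditions. Rows before the first run of a symbol store t = 0 (always down);
rows after the last store t = ℓ (always up). Under this convention the
relative threshold clamp(t − h, 0, ℓ) makes the (partition-independent)
decision i < t, so splitting rows never changes any repositioning outcome —
which is why both splitting stages are query-invariant, a property the tests
assert by comparing PMLs across unsplit, thresholds-split and length-split
builds.

### Splitting

Thresholds-splitting cuts each row at every distinct strictly-interior
relative threshold (coincident cut points from different symbols are cut
once). Since there is at most one threshold per adjacent run pair and at
most r pairs, the row count at most doubles. Length-splitting replaces a
row of length ℓ > ℓ_max by ⌈ℓ/ℓ_max⌉ sub-rows, all but the last of length
ℓ_max; exact multiples produce no zero-length remainder. Order: thresholds
first, then length, then pointers — pointers are computed once on the final
row set and never remapped.

### The sentinel row

The sentinel forms its own length-1 run. The 2-bit symbol field cannot
encode a fifth symbol, so the row stores code 0 (A) and the header records
its index. Three consequences, all handled explicitly:

* its destination is always row 0 (LF of the sentinel is offset 0), so id
  resolution special-cases it in every variant;
* checkpoint construction and sampled-mode scans skip it when collecting
  symbol-A rows — counting it would break the per-symbol monotonicity the
  id compression relies on;
* a mismatch with query symbol A *at* the sentinel position has no stored
  threshold bit; repositioning there scans down first and falls back to up.
  Any deterministic choice is sound: a PML only counts consecutive matches
  actually walked through the text, so PML ≤ MS holds for every reposition
  rule; the choice only (marginally) affects lower-bound tightness.

### Id compression

Blocked: block size b = 2048 by default; if any in-block delta overflows the
23-bit field the block size is halved and the table rebuilt (at b = 1 every
delta is 0, so the loop terminates). A block with no row of some symbol
stores checkpoint 0; it is provably never dereferenced, because a query row
of symbol y inside a block guarantees a y-row between the block start and
itself. Checkpoint ids are stored in 5 bytes; with 4 symbols that is
20 bytes per checkpoint, which is what makes the S-table sizes come out at
20/(s·3) of the row table — 13.33% at s = 50, 6.67% at s = 100.

Sampled: checkpoints every s rows (default 50) store, per symbol, the id of
the first at-or-after row of that symbol. Resolution scans at most s−1 rows
to accumulate the BWT length of same-symbol rows passed, then fast-forwards
from the checkpoint id; ids are resolved lazily at query time with no
caching, so the reported scan statistics reflect the true work.

### PML recurrence

PML[m] = 0 literally, even when the last base matches (the comparison still
drives the first movement); movement also occurs at k = 1. The query starts
at the final BWT offset. A base absent from the entire text scores 0 and
leaves the position unchanged. Reads containing ambiguity codes are
substituted deterministically (N→A) before querying, as is the reference at
build time (count recorded in the index header).

## Serialization

One self-describing container per index: a 62-byte header (magic `MV2I`,
version, variant, bit widths, n, r, row count, block size / sampling rate,
terminator row, checkpoint count, ambiguity count), the fixed-width
little-endian row array (8/6/3 bytes per row for default/blocked/sampled;
fields packed LSB-first), then the checkpoint table (40-bit ids). Every
field is width-checked before writing; a non-trivial threshold at
serialization time is a hard error naming the row (it means the build
skipped thresholds-splitting). Deserialization is total: magic/version/
truncation problems raise before any partial table is returned, and
re-serialization of a loaded index is byte-identical.

## Synthetic data

The pangenome generator emulates what makes pangenomes compressible — a
random base genome plus haplotype copies at 0.1% substitution divergence and
rare short indels (rate 1e-4, length ≤ 10) by default, so n grows linearly
with haplotype count while r grows slowly. It does not model structural
variation, mutation hotspots, or real base composition; a green test
therefore establishes index correctness on repetitive DNA-like text, not
biological realism. Reads are uniform-start substrings with i.i.d.
substitution errors (default length 150, rate 1%, chosen as a generic
short-read regime); no quality model. Adversarial fixtures cover the
corners the generators would rarely hit: a BWT run longer than 2¹¹ (forces
length-splitting at all shipped widths), the smallest searched text whose
index gains a row from thresholds-splitting, a periodic text (minimal r) and
a searched text whose BWT has all runs of length 1 (r = n, neither splitting
stage fires).

The test corpus is scaled to the suite's time budget: 50 seeded texts of up
to 2 kb are checked exhaustively (every BWT offset, every row, every variant),
and the "realistic" pangenome fixture is 10 haplotypes of a 15 kb base
rather than a full-size collection. Percentages such as rows added by
thresholds-splitting are asserted as properties (> 0, ≤ 2r), never pinned to
the published dataset-specific values, which desk-scale fixtures cannot
reproduce.

## Known limitations

* Fast-forward scans are unbounded (no balanced run-splitting); a debug
  guard caps them at the row count to catch corruption. Observed means on
  synthetic pangenomes are ≪ 1 step per LF.
* Multi-record input is concatenated with a single terminal sentinel and no
  per-record separators, keeping the alphabet at 4+1 symbols and the stated
  bit budgets; matches spanning a record boundary are a known (rare)
  artifact.
* Queries are forward-strand only; callers wanting both strands query the
  reverse complement explicitly. Only PML queries are supported — no count/
  locate, SMEMs, or suffix-array sampling.
* The suffix-array builder holds several O(n) int64 arrays; it is sized for
  desk-scale texts (tens of Mb), not production pangenomes.
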