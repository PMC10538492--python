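# Methods

## The structure and its semantics

The package indexes a collection `D = {T_1, …, T_d}` of documents (one
document = one classification unit; a unit may be a group of genomes joined
into one string).  The concatenation appends **one separator per document**.
Separators compare smaller than every alphabet symbol and, between
themselves, by text position (earlier < later).  Two consequences define all
lcp semantics in the package:

* a longest common prefix between *distinct* suffixes never extends past a
  separator (two separators at different positions never match);
* a suffix's lcp with itself is its full length, separator included — so the
  own-document entry of a profile always equals the suffix length.

Internally the text is an integer array in which separator `j` has code `j`
and the `k`-th alphabet symbol has code `d + k`; the displayed text and BWT
collapse all separators to `#`.  BWT runs are computed on the collapsed
view, so a block of separators is a single run (the only place where
`DA[i] ≠ DA[LF(i)]`).  The alphabet defaults to `ACGTN` with `N` an ordinary
symbol — no wildcard matching.

All public coordinates are 1-based (SA values, document indices, BWT
intervals, read offsets); numpy arrays are internally 0-indexed by rank.

## Profile constructions

`profiles_naive` evaluates the defining max-lcp expression pairwise in
`O(n²)`; it is the ground truth the other constructions are tested against.

`profiles_two_pass` uses the nearest-neighbour property: the best suffix of
document `j` for rank `i` is the nearest preceding or following rank with
`DA = j`, and the lcp to it is the running minimum of the LCP array over the
gap.  Two sweeps (forward for predecessors, backward for successors)
produce the full matrix in `O(nd)`; this is the vectorized route used for
larger builds.

`profiles_streaming` emits only the `2r` run-boundary samples in one
left-to-right scan of (BWT, SA, LCP, DA).  At rank `i` it assembles the
profile of rank `LF(i)` — the suffix `BWT[i]·T[SA[i]..n]`:

* predecessor halves come from a table `Pred[doc][char]`, stored in
  "+1" form (`0` = no such suffix seen yet), updated with
  `min(·, LCP[i] + 1)` at each rank and reset to the suffix length + 1 for
  `(DA[LF(i)], BWT[i])`;
* successor halves are resolved by a FIFO queue of pending profiles: each
  rank enters as `(pos, char, doc, lcp)`, later ranks preceded by the same
  character fold `lcp + 1` into every pending profile (iterating
  newest-to-oldest while taking running minima of the queued LCP values
  reproduces each pairwise lcp exactly);
* a counter table `LQC[doc][char]` detects completion: once every document
  has a queued suffix preceded by a tuple's character, the nearest
  same-character successor of each document has been seen, and — because
  lcp to later ranks is non-increasing — the profile is final.  Complete
  profiles are popped from the queue front only, which keeps the queued
  ranks contiguous (this contiguity is what makes the running-minimum fold
  correct).

Two bookkeeping choices the prose description of such a scan leaves open
were fixed as follows, with correctness defined by equivalence to sampling
the naive matrix: the `+1` for the prepended character is applied at
insertion and at each fold (never at emission), and separator-preceded
ranks enter the queue *already final* (cross-document entries zero, own
entry the suffix length) but still carry their LCP value so the fold chain
is unbroken.  At end of scan the queue is flushed: documents that never
supplied a same-character successor simply leave the predecessor-side
bound in place.

`truncate` caps stored values (default 255, one byte per entry).  A capped
value compares identically against any threshold up to the cap, so listings
for match lengths ≤ cap are unchanged; longer matches may over-list.  The
untruncated variant conceptually needs `⌈log₂ n⌉` bits per entry.

## Queries

Backward search maintains the invariant that after matching the last `q`
characters, profile entry `j` is ≥ `q` exactly for the documents containing
the matched suffix.  Case 1 (the interval contains a run boundary of the
next character) adopts the sample stored at that boundary; case 2 (interval
inside one run) adds one to every entry.  The first character is case 1
over the full range, which always contains a boundary of that character's
runs when the character occurs.  When several boundaries fall inside the
interval any of them is valid; the implementation picks the lowest
position, preferring a run start on ties, purely for determinism.  Patterns
with out-of-alphabet characters return the empty marker (they occur
nowhere); the empty pattern is rejected.

The locate baseline enumerates the SA interval and maps every occurrence
through the document-boundary table; it doubles as a second oracle in the
tests, and its per-occurrence operation count is exposed for the work
comparison (profile path: exactly `d` comparisons after the search).

The one-document baseline reports the document at the first run start
inside the interval (else a run end inside it).  When an interval lies
strictly inside a single run no boundary is available; the implementation
then returns the document of the interval's first suffix — the toehold
value a run-length index carries through contained intervals — so the
reported document always contains the match.

Matching statistics (longest match starting at each read position) are
computed by streaming the reversed read through a suffix automaton of the
reversed text — linear-time per read after a linear-time automaton build —
and validated against quadratic substring search.  MEMs are the matching
statistics filtered to left-maximal positions (`p = 1` or
`MS[p-1] ≤ MS[p]`); each MEM's interval and final profile come from a
backward search of the MEM string.

## Classification

Reads vote by MEM length: each MEM of length ≥ `min_len` (default 15) adds
its length to every document in its listing (full mode) or to the single
baseline document (one-doc mode).  Argmax assigns the read; a tied top
weight — and a read with no surviving MEM — is reported *unclassified*
rather than broken arbitrarily, which keeps accuracy honest (unclassified
counts as an error).  Reported accuracy is therefore a conservative
definition; a tool breaking ties at random would score between the two
modes' values.

## Synthetic data

The generator emulates strain-level benchmarks structurally: one dataset
ancestor; class ancestors at a *between-class* divergence; class members at
a *within-class* divergence; reads from uniform forward-strand positions
with per-base error `1 − accuracy`.  Mutations and read errors share one
process: i.i.d. per-site events split substitution:insertion:deletion =
50:25:25, indel lengths geometric with mean 1.5.  Real nanopore error
profiles are more deletion-heavy and context-dependent; any fixed split
suffices for the structural comparison made here.  Divergence tiers:

| tier    | between-class | within-class | emulates                      |
|---------|--------------|--------------|--------------------------------|
| genus   | 0.20         | 0.01         | different genera (~80% identity) |
| species | 0.05         | 0.005        | congeneric species (~95%)      |
| strain  | 0.005        | 0.002        | same-species strains (≥99.5%)  |

Defaults are the strain-tier study conditions at desk scale: 4 classes,
one 20 kb genome each, 500 reads/class of 1 kb at 95% accuracy.  These are
stand-ins for benchmarks built on tens to hundreds of real genomes and
50,000 reads per class; passing tests demonstrate the algorithms and the
direction of the full-listing vs one-doc comparison, not absolute accuracy
on real genomes (no rearrangements, no reverse strand, no gene content
differences, uniform base composition).  Multi-genome classes are joined
with a single `N` so exact matches cannot span two genomes.  All
randomness flows from the config seed; identical configs give identical
datasets.

Reads are forward-strand only, and queries do not reverse-complement; a
production tool would index both strands or canonicalize reads.

## Numerical and design choices

* Suffix sorting by prefix doubling (`O(n log² n)` with numpy sorts);
  correctness is defined by the brute-force oracle, and the desk-scale
  targets (n up to a few hundred kb) build in seconds.
* LCP by Kasai's algorithm on the encoded text.
* LF is computed by the ISA formula and cross-checked against the
  counts-plus-rank construction in the tests.
* Rank queries use per-character sorted position lists with binary search;
  no succinct structures (a deliberate non-goal at desk scale).
* Index serialization is a versioned JSON container (documents, labels,
  runs, SA samples, profiles, width cap, content hash); structures are
  rebuilt deterministically on load, so save → load → save is
  byte-identical, and version or hash mismatches are rejected.
* Test problem sizes: randomized sweeps use collections of total length up
  to ~200 over 2–6 documents (where the quadratic oracles are instant);
  classification runs the 4-class tiers above.

## Known limitations

* Space for the full profile structure grows linearly in `d`; hundreds of
  classes would need the sparse or top-k variants, which are not
  implemented (no established query semantics to test against).
* The streaming construction's queue scan is worst-case quadratic in the
  queue length; the two-pass route is the practical default for large
  builds, with streaming validated equivalent on the randomized suite.
* Document listing reports presence only, not per-document frequencies.
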