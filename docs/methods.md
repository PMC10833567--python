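# Methods

## Model of a small RNA-seq read

Every read is assumed to follow the generalized structure

```
[5' random-mer, 0..N bp] [true small RNA] [3' random-mer, 0..N bp] [tail] [filler to read length]
```

where the tail is a literal 3' adapter sequence, a poly(A) run
(template-switching kits), or absent (reads deposited post-trimming).
Random-mer *bases* are random per read, but a library's random-mer
*lengths* are fixed by the preparation protocol — that asymmetry is what
detection exploits. The method assumes sense-strand reads (small RNA-seq
libraries are directional) and that a usable fraction of reads contains an
exact, full-length match to some catalog mature sequence; samples
dominated by non-templated isomiRs violate that assumption and will yield
few anchors.

## Detection procedure

**Anchoring.** All catalog matures of length ≥ 16 nt (shorter ones are
excluded: a 16-mer's chance-hit probability in a 50-bp read is ≈ 35·4⁻¹⁶,
so spurious anchors are negligible; shorter patterns would not be) are
compiled into an Aho-Corasick automaton whose goto/failure structure is
collapsed into a DFA, so matching is one transition per base. When a read
contains several matures, the longest is taken, then the leftmost, then
the lexicographically smallest name — a deterministic policy favouring the
most specific anchor. Matching is exact: N bases never match, and no
mismatches are tolerated.

**Extension.** If the matched mature has precursor context (located by
exact substring search, preferring the precursor whose name shares the
longest prefix with the mature's — the miRBase naming convention), the
match is widened one base at a time in each direction while the read
agrees with the precursor. Extension is exact-match: tolerating even one
mismatch would absorb a random-mer base ~25% of the time per boundary and
bias the inferred lengths. Extension is idempotent and never exceeds read
or precursor bounds.

**Tally.** Each matched read splits into upstream / core / downstream.
For every downstream and every shift k = 0..m (default m = 8), the n-bp
window (default n = 12) starting at k is tallied. n = 12 because real
adapters are either ≥ 12 bp or absent and a 12-mer excludes chance
agreement; m = 8 covers the 0–5 bp random-mers of current kits with
headroom. Within a dataset, windows inside the adapter are identical
across reads (counts plateau near the number of matched reads), while
windows overlapping random-mer bases scatter over 4^j variants.

**Collapse.** Per shift, only the top 5 records are kept (ties to the
lexicographically smaller fragment — which also guarantees the all-A
poly(A) diagonal survives ties). A record at shift k+1 is the *child* of a
record at shift k when its first n−1 bases equal the parent's last n−1
bases, i.e. the same underlying template slid one base. Every kept record
with no kept parent seeds a chain; a chain advances to its highest-count
child only when the child/parent count ratio lies in
(`ratio_cutoff`, `max_jump`] = (1.2, 10] by default:

* the **lower bound** (1.2) separates a genuine boundary jump from the
  plateau inside the adapter, whose counts vary only through sequencing
  error (tens of percent at worst);
* the **upper bound** (10) requires the jump to be explainable by shedding
  one uniformly random base, which concentrates about 1/4 of the child's
  reads in the best variant parent (~4×, with 2.5× headroom for skew).
  Without it, a count-of-3 error artifact whose suffix coincides with the
  adapter can seed a chain that leaps onto the adapter's plateau mid-way
  with a ratio in the hundreds and terminate at a deep shift whose count
  exceeds the true boundary record's by plateau noise.

Chain terminals form the candidate pool.

**Call.** If at least `none_fraction` (default 0.5) of matched reads have
an empty downstream, the library is already trimmed → class `none`.
Otherwise the highest-count pool record wins (ties → smaller shift, then
fragment), with one refinement: if a same-shift pool record whose last
n−1 bases equal the winner's first n−1 bases holds at least
`winner/max_jump` counts, the winner moves to it. Such a pair — two
substantial windows at one shift related by a one-base template extension
— cannot arise from a fixed-length random-mer; it arises when the
adapter's first base coincides with the 3' end of many anchor sequences
(or their templated flank), so part of the reads split the
insert/adapter boundary one base late. The refinement reports the adapter
from its true start. A winner supported by fewer than `min_support`
(default 0.1) of tallied downstreams is noise → `none`. A winner fragment
≥ `polyA_fraction` (default 0.9) adenine is class `polyA`. The winner's
shift is the 3' random-mer length; the 5' random-mer length is inferred
independently as the mode of upstream lengths (ties toward the smaller
value — extension absorbs the last 5' random-mer base with probability
~1/4, shortening some upstreams, and the mode is robust to that).

**Streaming.** Reads are consumed in `batch_size` = 10,000-read batches;
scanning stops at the first batch boundary with ≥ `min_matches` = 1,000
anchored reads. At end-of-file with fewer, the call proceeds from ≥ 100
matches but is flagged `low_confidence`; below 100 it is refused.

## Simulator

The suite generator emulates a validation design of nine read structures
(all combinations of 5'/3' random-mer presence with literal-adapter,
poly(A), and no-adapter tails). Defaults: 20 datasets per scenario,
10,000 reads each, 50-bp reads, random-mer lengths drawn once per dataset
uniformly from 1–5 bp, 12-nt poly(A), 0.25% per-base substitution error
applied uniformly, adapters drawn from a pool of eight random 25-mers
derived from the suite seed (a user pool file can replace it; random
pools avoid asserting specific commercial sequences). True reads are
sampled from a synthetic catalog of 50 random matures (18–24 nt, each
embedded mid-precursor between 20-bp random flanks, regenerated until no
mature occurs in any other precursor), with each end independently
shortened by 0–2 bp to emulate trimming/isomiR variants. Reads carrying a
tail are padded with random bases to 50 bp and truncated at 50 bp, as a
fixed-cycle sequencer would; no-adapter (negative-control) datasets stay
unpadded at their natural lengths, since they model reads that were
already trimmed. The whole suite — catalog, pool, every base — is a pure
function of the base seed.

What the simulator does *not* emulate: realistic isomiR end-length
distributions (shortening is uniform rather than canonical-dominated),
platform quality profiles, indels, adapter dimers, and non-uniform mature
abundance. Passing the suite therefore demonstrates correct inference
under the assumed read grammar with substitution noise, not robustness to
every artifact of real libraries. One consequence of the aggressive
uniform shortening is worth noting: when a drawn adapter's first base
coincides with many mature 3' ends, up to half the anchored reads split
the boundary one base late — rarer in real data, but the winner
refinement above handles it either way.

**Scoring.** A dataset counts as recovered iff the called class matches
the truth, the called adapter equals the true adapter's first 12 bases
(class `sequence` only), and both random-mer lengths are exact;
no-adapter datasets must yield class `none` with zero lengths.

## Problem sizes and runtime

The validation suite (180 datasets × 10,000 reads) generates and scores
in roughly two minutes on one core; detection alone is well under a
second per dataset because the stop rule caps work at the first 10,000
reads whenever ≥ 10% of reads anchor. Tests use smaller replicas (tens to
thousands of reads) except the acceptance suite, which runs the full
default configuration.

## Known limitations

* Anchoring requires exact full-length mature hits; heavily 3'-modified
  libraries or sparse catalogs reduce matches until the floor (100) blocks
  calling.
* The adapter is reported as exactly the winning 12-mer; it is not
  extended further 3', which is sufficient for trimming but not a full
  adapter reconstruction.
* Mixed random-mer lengths within one library (no current kit produces
  them) would blur the count jump the collapse relies on.
* Reverse-complement matching is deliberately omitted (sense-strand
  protocol assumption).
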