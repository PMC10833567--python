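"""The adapter-detection algorithm: region splitting, shifted-fragment
tallying, top-k selection, parent/child collapse, and the final call.

The generalized read structure is

    [5' random-mer][true small RNA][3' random-mer][3' adapter | poly(A) | nothing][filler]

Once a read is anchored by a reference match and extended with precursor
context, everything downstream of the anchor is random-mer followed by
adapter. Sliding an n-bp window 0..m bases into each downstream sequence
and tallying the windows makes the adapter stand out: window counts jump
~4-fold at the shift where the random bases end and the (constant) adapter
begins, then plateau. The parent/child collapse walks those jumps — a
child one shift further whose count exceeds its parent's by more than
``ratio_cutoff`` (default 1.2) wins — so the terminal record's fragment is
the adapter and its shift is the 3' random-mer length.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field, replace
from statistics import multimode

from .errors import InsufficientSignalError
from .io_fastq import Read, read_fastq_batches
from .reference import AhoCorasick, MatchSpan, ReferenceCatalog, build_automaton, extend_match, find_match

#: Below this many reference matches at end-of-file, refuse to call.
MIN_MATCHES_FLOOR = 100


@dataclass(frozen=True)
class RegionSplit:
    """Partition of a read around its extended reference match."""

    upstream: str
    core: str
    downstream: str


@dataclass(frozen=True)
class FragmentRecord:
    """One tally entry: an n-bp window at a given shift into the downstream."""

    shift: int
    fragment: str
    count: int


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the detector.

    n_frag=12 because real 3' adapters are either longer than 12 bp or
    absent, and 12 bp excludes chance matches; m_shift=8 comfortably covers
    the 0-5 bp random-mers seen in current kits plus UMI-free designs;
    ratio_cutoff=1.2 accepts the ~4x count jump at the random-mer/adapter
    boundary while rejecting the plateau inside the adapter even with >10%
    of windows lost to sequencing error. max_jump=10 is the ceiling on an
    acceptable jump: shedding one uniform random base concentrates ~1/4 of
    the flow in the best variant parent (~4x jump, with headroom for skew),
    whereas a child hundreds of times its parent means the parent is a
    sequencing-error artifact whose suffix happens to match, not a
    random-mer variant, and certifies no boundary.
    """

    n_frag: int = 12
    m_shift: int = 8
    top_k: int = 5
    ratio_cutoff: float = 1.2
    max_jump: float = 10.0
    batch_size: int = 10_000
    min_matches: int = 1_000
    none_fraction: float = 0.5
    min_support: float = 0.1
    polyA_fraction: float = 0.9

    def __post_init__(self):
        if self.n_frag < 1 or self.m_shift < 0 or self.top_k < 1 or self.ratio_cutoff <= 0:
            raise ValueError("invalid detection parameters")


@dataclass(frozen=True)
class AdapterCall:
    """Final report for one sample.

    ``adapter_class`` is ``sequence`` (a literal 3' adapter, reported as
    its first n_frag bases), ``polyA`` (homopolymer tail), or ``none``
    (reads are already adapter-free). The random-mer lengths are the bases
    to remove from each end after (or in place of) adapter trimming.
    """

    adapter_class: str
    adapter_seq: str
    len_5p_randmer: int
    len_3p_randmer: int
    n_reads_scanned: int
    n_matched: int
    winner_count: int
    support_fraction: float
    low_confidence: bool = False


def split_read(read: Read, extended: MatchSpan) -> RegionSplit:
    """Split a read into upstream / matched core / downstream."""
    seq = read.sequence
    return RegionSplit(seq[: extended.start], seq[extended.start : extended.end], seq[extended.end :])


def tally_downstream(
    downstreams: list[str], params: DetectionParams
) -> tuple[list[FragmentRecord], int, int]:
    """Tally every n-bp window at shifts 0..m over all downstream sequences.

    Returns (records, n_tallied, n_empty): n_tallied is the number of
    downstreams contributing at least one window, n_empty the number of
    zero-length downstreams (reads with nothing after the insert).
    """
    n, m = params.n_frag, params.m_shift
    counts: Counter[tuple[int, str]] = Counter()
    n_tallied = 0
    n_empty = 0
    for d in downstreams:
        if not d:
            n_empty += 1
            continue
        if len(d) >= n:
            n_tallied += 1
            for k in range(0, min(m, len(d) - n) + 1):
                counts[(k, d[k : k + n])] += 1
    records = [FragmentRecord(k, frag, c) for (k, frag), c in counts.items()]
    records.sort(key=lambda r: (r.shift, -r.count, r.fragment))
    return records, n_tallied, n_empty


def top_records(records: list[FragmentRecord], params: DetectionParams) -> list[FragmentRecord]:
    """Keep at most top_k records per shift (highest counts; ties to the
    lexicographically smaller fragment), sorted by (shift, -count, fragment)."""
    by_shift: dict[int, list[FragmentRecord]] = {}
    for rec in records:
        by_shift.setdefault(rec.shift, []).append(rec)
    kept: list[FragmentRecord] = []
    for shift in sorted(by_shift):
        group = sorted(by_shift[shift], key=lambda r: (-r.count, r.fragment))
        kept.extend(group[: params.top_k])
    return kept


def is_child(parent: FragmentRecord, child: FragmentRecord) -> bool:
    """True iff ``child`` is ``parent`` shifted one base further into the
    downstream: shift increases by 1 and the child's first n-1 bases equal
    the parent's last n-1 bases."""
    return (
        child.shift == parent.shift + 1
        and child.fragment[:-1] == parent.fragment[1:]
    )


def collapse_records(
    kept: list[FragmentRecord], params: DetectionParams
) -> list[FragmentRecord]:
    """Collapse top records along parent/child chains; return the candidate pool.

    Every kept record with no parent in ``kept`` seeds a chain. Each chain
    is walked in increasing shift: among the current record's children the
    highest-count one (ties to the lexicographically smaller fragment) is
    examined, and the walk advances iff ratio_cutoff < child_count /
    parent_count <= max_jump, else the chain terminates. The pool is the
    deduplicated set of chain terminals.

    The upper bound matters: a rare error-variant record (an erroneous
    copy of an adapter window, count of a few) would otherwise seed a
    chain that "jumps" onto the true adapter's diagonal mid-plateau with a
    preposterous ratio, and terminate there with a count that can beat the
    true boundary record by plateau noise. A genuine random-mer boundary
    jump is ~4x (one random base, four variants), never hundreds.
    """
    by_shift: dict[int, list[FragmentRecord]] = {}
    for rec in kept:
        by_shift.setdefault(rec.shift, []).append(rec)

    def children_of(rec: FragmentRecord) -> list[FragmentRecord]:
        return [c for c in by_shift.get(rec.shift + 1, []) if is_child(rec, c)]

    has_parent = set()
    for rec in kept:
        for c in children_of(rec):
            has_parent.add((c.shift, c.fragment))

    pool: dict[tuple[int, str], FragmentRecord] = {}
    for seed in kept:
        if (seed.shift, seed.fragment) in has_parent:
            continue
        current = seed
        while True:
            children = children_of(current)
            if not children:
                break
            best = min(children, key=lambda c: (-c.count, c.fragment))
            ratio = best.count / current.count
            if params.ratio_cutoff < ratio <= params.max_jump:
                current = best
            else:
                break
        pool[(current.shift, current.fragment)] = current
    return sorted(pool.values(), key=lambda r: (r.shift, -r.count, r.fragment))


def call_adapter(
    pool: list[FragmentRecord],
    n_tallied: int,
    n_empty: int,
    n_matched: int,
    params: DetectionParams,
) -> tuple[str, str, int, int, float]:
    """Turn the candidate pool into (class, adapter_seq, len_3p, winner_count,
    support_fraction).

    Reads whose downstream is empty carry no adapter at all; when at least
    ``none_fraction`` of matched reads look like that, the library is
    already trimmed and the class is ``none``. Otherwise the pool record
    with the highest count wins (ties to smaller shift, then fragment); a
    winner supported by fewer than ``min_support`` of the tallied
    downstreams is noise and the class falls back to ``none``. A winner
    fragment that is >= ``polyA_fraction`` adenine is a poly(A) tail.

    Winner refinement: when the adapter's first base coincides with the 3'
    end of many anchor sequences (or their templated precursor flanks), a
    large read subset splits the anchor/adapter boundary one base late and
    the one-base-shifted adapter window can out-count the canonical one at
    the same shift. A fixed-length random-mer can never produce two
    substantial same-shift records related by a one-base template
    extension, so when a pool record at the winner's shift extends the
    winner's template one base 5' (its last 11 bases equal the winner's
    first 11) with count >= winner/max_jump, the winner moves to it.
    """
    if n_matched < 1:
        raise InsufficientSignalError("no matched reads to call from", n_matched=n_matched)
    if n_empty / n_matched >= params.none_fraction or not pool:
        return "none", "", 0, 0, 0.0
    winner = min(pool, key=lambda r: (-r.count, r.shift, r.fragment))
    seen = {winner.fragment}
    while True:
        extensions = [
            p
            for p in pool
            if p.shift == winner.shift
            and p.fragment not in seen
            and p.fragment[1:] == winner.fragment[:-1]
            and p.count >= winner.count / params.max_jump
        ]
        if not extensions:
            break
        winner = min(extensions, key=lambda r: (-r.count, r.fragment))
        seen.add(winner.fragment)
    support = winner.count / max(n_tallied, 1)
    if support < params.min_support:
        return "none", "", 0, 0, 0.0
    a_frac = winner.fragment.count("A") / len(winner.fragment)
    adapter_class = "polyA" if a_frac >= params.polyA_fraction else "sequence"
    return adapter_class, winner.fragment, winner.shift, winner.count, support


def infer_five_prime(upstream_lengths: list[int]) -> int:
    """Modal upstream length, ties toward the smaller value.

    Precursor extension occasionally absorbs the last random-mer base (a
    random base matches the templated flank with probability 1/4 per
    boundary), shortening some upstreams by a base or two; the mode is
    robust to that, and breaking ties low avoids over-trimming.
    """
    if not upstream_lengths:
        raise InsufficientSignalError("no upstream lengths to infer from", n_matched=0)
    return min(multimode(upstream_lengths))


def detect_adapter(
    fastq_path: str | os.PathLike,
    catalog: ReferenceCatalog,
    params: DetectionParams | None = None,
    matcher: AhoCorasick | None = None,
) -> AdapterCall:
    """Run the full detection workflow on one FASTQ file.

    Streams ``batch_size``-read batches, anchoring each read with the
    reference automaton and extending with precursor context; stops
    consuming input at the first batch boundary where at least
    ``min_matches`` reads have matched (most libraries resolve within the
    first 10K reads). At end-of-file with fewer matches it proceeds if at
    least ``MIN_MATCHES_FLOOR`` were found (the call is flagged
    ``low_confidence``), else raises :class:`InsufficientSignalError`.

    A prebuilt ``matcher`` may be passed to amortize automaton
    construction over many samples sharing one catalog.
    """
    if params is None:
        params = DetectionParams()
    if matcher is None:
        matcher = build_automaton(catalog)

    upstream_lengths: list[int] = []
    downstreams: list[str] = []
    n_scanned = 0
    n_matched = 0
    for batch in read_fastq_batches(fastq_path, params.batch_size):
        for read in batch:
            n_scanned += 1
            span = find_match(read, matcher)
            if span is None:
                continue
            extended = extend_match(read, span, catalog)
            parts = split_read(read, extended)
            upstream_lengths.append(len(parts.upstream))
            downstreams.append(parts.downstream)
            n_matched += 1
        if n_matched >= params.min_matches:
            break

    if n_matched < MIN_MATCHES_FLOOR:
        raise InsufficientSignalError(
            f"only {n_matched} reference matches in {n_scanned} reads "
            f"(need >= {MIN_MATCHES_FLOOR} to call)",
            n_matched=n_matched,
        )

    records, n_tallied, n_empty = tally_downstream(downstreams, params)
    kept = top_records(records, params)
    pool = collapse_records(kept, params)
    adapter_class, adapter_seq, len_3p, winner_count, support = call_adapter(
        pool, n_tallied, n_empty, n_matched, params
    )
    len_5p = 0 if adapter_class == "none" else infer_five_prime(upstream_lengths)
    return AdapterCall(
        adapter_class=adapter_class,
        adapter_seq=adapter_seq,
        len_5p_randmer=len_5p,
        len_3p_randmer=len_3p,
        n_reads_scanned=n_scanned,
        n_matched=n_matched,
        winner_count=winner_count,
        support_fraction=support,
        low_confidence=n_matched < params.min_matches,
    )
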