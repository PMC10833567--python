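"""Region splitting, shifted-fragment tallying, collapse, and the full call."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnadapt.detect import (
    DetectionParams,
    FragmentRecord,
    call_adapter,
    collapse_records,
    detect_adapter,
    infer_five_prime,
    is_child,
    split_read,
    tally_downstream,
    top_records,
)
from srnadapt.errors import InsufficientSignalError
from srnadapt.io_fastq import Read
from srnadapt.reference import MatchSpan
from tests._bruteforce import brute_pipeline
from tests.conftest import LET7_MATURE

PARAMS = DetectionParams()


def rec(shift, fragment, count):
    return FragmentRecord(shift, fragment, count)


def test_split_read_partitions():
    read = Read("r", "NNNN" + "ACGTACGTACGTACGTAC" + "AAAA")
    parts = split_read(read, MatchSpan(4, 22, "m"))
    assert (parts.upstream, parts.core, parts.downstream) == ("NNNN", read.sequence[4:22], "AAAA")
    assert parts.upstream + parts.core + parts.downstream == read.sequence
    whole = split_read(read, MatchSpan(0, len(read.sequence), "m"))
    assert whole.upstream == "" and whole.downstream == ""


def test_tally_counts_empties_and_boundaries():
    records, n_tallied, n_empty = tally_downstream(["", ""], PARAMS)
    assert records == [] and n_tallied == 0 and n_empty == 2
    # downstream of exactly n bases: one record at shift 0
    records, n_tallied, n_empty = tally_downstream(["A" * 12], PARAMS)
    assert records == [rec(0, "A" * 12, 1)] and n_tallied == 1 and n_empty == 0


def test_tally_shifted_windows():
    # 10 copies of CCCC + A*12: windows exist at shifts 0..4 only
    downstreams = ["CCCC" + "A" * 12] * 10
    records, n_tallied, _ = tally_downstream(downstreams, PARAMS)
    by_shift = {r.shift: r for r in records}
    assert set(by_shift) == {0, 1, 2, 3, 4}
    assert all(r.count == 10 for r in records)
    assert by_shift[4].fragment == "A" * 12
    assert by_shift[0].fragment == "CCCC" + "A" * 8
    assert n_tallied == 10


@settings(derandomize=True, max_examples=100)
@given(downstreams=st.lists(st.text(alphabet="ACGT", max_size=30), max_size=40))
def test_tally_conservation(downstreams):
    """For every shift k, counts over fragments at k sum to the number of
    downstreams of length >= k + n."""
    records, _, _ = tally_downstream(downstreams, PARAMS)
    for k in range(PARAMS.m_shift + 1):
        total = sum(r.count for r in records if r.shift == k)
        assert total == sum(1 for d in downstreams if len(d) >= k + PARAMS.n_frag)


def test_top_records_caps_per_shift():
    records = [rec(0, f"{b}AAAAAAAAAAA", c) for b, c in zip("ACGTACG", [9, 8, 7, 6, 5, 4, 3])]
    kept = top_records(records, PARAMS)
    assert sorted(r.count for r in kept) == [5, 6, 7, 8, 9]
    # count ties within top_k keep both
    tied = [rec(1, "A" * 12, 5), rec(1, "C" * 12, 5)]
    assert len(top_records(tied, PARAMS)) == 2
    assert top_records([], PARAMS) == []


def test_is_child_worked_example():
    # shifting CTGTTGGAATTC one base into the downstream yields TGTTGGAATTCT
    assert is_child(rec(0, "CTGTTGGAATTC", 10), rec(1, "TGTTGGAATTCT", 10))
    assert not is_child(rec(0, "CTGTTGGAATTC", 10), rec(2, "TGTTGGAATTCT", 10))
    assert is_child(rec(0, "A" * 12, 10), rec(1, "A" * 12, 10))  # homopolymer self-child


@settings(derandomize=True, max_examples=200)
@given(
    parent=st.text(alphabet="ACGT", min_size=12, max_size=12),
    child=st.text(alphabet="ACGT", min_size=12, max_size=12),
    shifts=st.tuples(st.integers(0, 8), st.integers(0, 8)),
)
def test_is_child_matches_suffix_prefix_definition(parent, child, shifts):
    p, c = rec(shifts[0], parent, 1), rec(shifts[1], child, 1)
    expected = shifts[1] == shifts[0] + 1 and parent[1:] == child[:-1]
    assert is_child(p, c) == expected


def test_collapse_jump_is_followed():
    # random-mer base then poly(A): the 4x jump into the tail is accepted
    kept = [rec(0, "C" + "A" * 11, 25), rec(1, "A" * 12, 100)]
    pool = collapse_records(kept, PARAMS)
    assert pool == [rec(1, "A" * 12, 100)]


def test_collapse_plateau_terminates():
    # poly(A) with no random-mer: the decaying self-child is rejected
    kept = [rec(0, "A" * 12, 100), rec(1, "A" * 12, 25)]
    pool = collapse_records(kept, PARAMS)
    assert pool == [rec(0, "A" * 12, 100)]


def test_collapse_single_record_and_subset_invariant():
    assert collapse_records([rec(3, "G" * 12, 7)], PARAMS) == [rec(3, "G" * 12, 7)]


def test_collapse_ignores_noise_parent_jump():
    """A tiny error-artifact record whose suffix matches the adapter must
    not certify a boundary: its chain may not jump onto the adapter's
    plateau with a preposterous count ratio."""
    adapter = "GACCTATTATATGTGAAGCACG"
    kept = [
        rec(k, adapter[k : k + 12], 700 + k)  # plateau, counts drift upward
        for k in range(0, 8)
    ]
    # error variant of the shift-5 window (first base wrong), count 3
    noise = "T" + adapter[6:17]
    kept.append(rec(5, noise, 3))
    pool = collapse_records(sorted(kept, key=lambda r: (r.shift, -r.count)), PARAMS)
    winner = min(pool, key=lambda r: (-r.count, r.shift, r.fragment))
    assert (winner.shift, winner.fragment) == (0, adapter[:12])


def test_collapse_accepts_boundary_jump_below_ceiling():
    """A genuine ~4x variant-parent jump still advances the chain even when
    a same-diagonal parent sits just below the cutoff (blurred poly(A)
    boundary with a 1-base random-mer)."""
    kept = [
        rec(0, "A" * 12, 955),
        rec(0, "C" + "A" * 11, 256),
        rec(1, "A" * 12, 1127),
        rec(2, "A" * 12, 302),
    ]
    pool = collapse_records(kept, PARAMS)
    winner = min(pool, key=lambda r: (-r.count, r.shift, r.fragment))
    assert (winner.shift, winner.count) == (1, 1127)


@pytest.mark.parametrize(
    "pool,n_tallied,n_empty,n_matched,expected",
    [
        ([rec(4, "TGGAATTCTCGG", 900)], 950, 0, 1000, ("sequence", "TGGAATTCTCGG", 4)),
        ([rec(4, "TGGAATTCTCGG", 900)], 950, 800, 1000, ("none", "", 0)),
        ([rec(3, "A" * 12, 700)], 900, 0, 1000, ("polyA", "A" * 12, 3)),
        ([rec(0, "TGGAATTCTCGG", 50)], 900, 0, 1000, ("none", "", 0)),  # support < 0.1
    ],
)
def test_call_adapter_rules(pool, n_tallied, n_empty, n_matched, expected):
    klass, seq, len_3p, count, support = call_adapter(pool, n_tallied, n_empty, n_matched, PARAMS)
    assert (klass, seq, len_3p) == expected
    if klass == "sequence":
        assert count == 900 and support == pytest.approx(900 / 950)


def test_call_adapter_prefers_same_shift_template_extension():
    """When many anchors end with the adapter's first base, reads split the
    boundary one base late and the shifted adapter window can out-count the
    canonical one at the same shift; the winner must move to the record
    whose window starts one base earlier in the same template."""
    adapter = "CTTTCAGCTAAATC"
    pool = [
        rec(0, adapter[1:13], 710),  # boundary-shifted subset, slightly larger
        rec(0, adapter[0:12], 563),
    ]
    klass, seq, len_3p, count, _ = call_adapter(pool, 1400, 0, 1500, PARAMS)
    assert (klass, seq, len_3p, count) == ("sequence", adapter[:12], 0, 563)
    # a noise-level same-shift record must not pull the winner
    pool = [rec(0, adapter[0:12], 900), rec(0, "G" + adapter[0:11], 4)]
    _, seq, _, count, _ = call_adapter(pool, 1000, 0, 1000, PARAMS)
    assert seq == adapter[:12] and count == 900


def test_call_adapter_requires_matches():
    with pytest.raises(InsufficientSignalError):
        call_adapter([], 0, 0, 0, PARAMS)


@pytest.mark.parametrize(
    "lengths,expected",
    [([0, 0, 0, 0], 0), ([4, 4, 4, 4, 5, 3], 4), ([2, 2, 3, 3], 2)],
)
def test_infer_five_prime_mode(lengths, expected):
    assert infer_five_prime(lengths) == expected


def test_infer_five_prime_empty():
    with pytest.raises(InsufficientSignalError):
        infer_five_prime([])


@settings(derandomize=True, max_examples=200, deadline=None)
@given(data=st.data())
def test_pipeline_matches_bruteforce(data):
    """tally -> top -> collapse -> call agrees record-for-record with a
    literal brute-force enumeration under randomized parameters."""
    n = data.draw(st.integers(2, 6))
    m = data.draw(st.integers(0, 4))
    top_k = data.draw(st.integers(1, 5))
    ratio = data.draw(st.floats(0.5, 3.0))
    max_jump = data.draw(st.floats(3.0, 30.0))
    params = DetectionParams(n_frag=n, m_shift=m, top_k=top_k, ratio_cutoff=ratio, max_jump=max_jump)
    downstreams = data.draw(
        st.lists(st.text(alphabet="ACG", max_size=12), min_size=1, max_size=60)
    )
    n_matched = len(downstreams)

    records, n_tallied, n_empty = tally_downstream(downstreams, params)
    kept = top_records(records, params)
    pool = collapse_records(kept, params)
    call = call_adapter(pool, n_tallied, n_empty, n_matched, params)

    b_counts, b_kept, b_pool, b_call = brute_pipeline(downstreams, params, n_matched)
    assert {(r.shift, r.fragment): r.count for r in records} == dict(b_counts)
    assert {(r.shift, r.fragment): r.count for r in kept} == b_kept
    assert {(r.shift, r.fragment): r.count for r in pool} == b_pool
    assert call == b_call
    # pool is always a subset of the kept records
    assert {(r.shift, r.fragment) for r in pool} <= {(r.shift, r.fragment) for r in kept}


def make_adapter_reads(n_reads, adapter, len_5p, len_3p, seed, read_len=50):
    rng = random.Random(seed)
    reads = []
    for i in range(n_reads):
        seq = (
            "".join(rng.choice("ACGT") for _ in range(len_5p))
            + LET7_MATURE
            + "".join(rng.choice("ACGT") for _ in range(len_3p))
            + adapter
        )
        seq += "".join(rng.choice("ACGT") for _ in range(max(0, read_len - len(seq))))
        reads.append(seq[:read_len])
    return reads


def test_detect_adapter_end_to_end(small_catalog, fastq_writer):
    adapter = "TGGAATTCTCGGGTGCCAAGG"
    path = fastq_writer(make_adapter_reads(600, adapter, 4, 2, seed=5))
    call = detect_adapter(path, small_catalog, DetectionParams(min_matches=100))
    assert call.adapter_class == "sequence"
    assert call.adapter_seq == adapter[:12]
    assert (call.len_5p_randmer, call.len_3p_randmer) == (4, 2)
    assert call.n_matched >= 100 and not call.low_confidence
    # determinism: same file, same params, identical call
    assert detect_adapter(path, small_catalog, DetectionParams(min_matches=100)) == call


def test_detect_adapter_insufficient_signal(small_catalog, fastq_writer):
    path = fastq_writer(["ACGTACGTACGTACGTACGTACGT"] * 200)
    with pytest.raises(InsufficientSignalError) as exc:
        detect_adapter(path, small_catalog)
    assert exc.value.n_matched == 0


def test_detect_adapter_low_confidence_below_min_matches(small_catalog, fastq_writer):
    adapter = "TGGAATTCTCGGGTGCCAAGG"
    path = fastq_writer(make_adapter_reads(150, adapter, 0, 0, seed=6))
    call = detect_adapter(path, small_catalog)  # EOF with 150 < 1000 matches
    assert call.low_confidence and call.adapter_seq == adapter[:12]
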