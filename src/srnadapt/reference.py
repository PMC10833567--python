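"""Reference catalog, Aho-Corasick matching, and precursor-based extension.

The mature small RNA sequences (e.g. miRBase mature.fa) are the anchors:
an exact occurrence of a mature inside a raw read pins down where the true
insert sits, and the precursor (hairpin) context then lets the match be
extended base-by-base so that templated flanking bases are not mistaken
for random-mer or adapter sequence.
"""

from __future__ import annotations

import os
from collections import deque
from dataclasses import dataclass, field
from typing import Iterator

from Bio import SeqIO

from .errors import CatalogError
from .io_fastq import Read, normalize_sequence

#: Matures shorter than this are excluded from the matching set: in 50-bp
#: reads a 16-mer has a chance-hit probability of about 35 * 4**-16 per
#: read, short enough to keep spurious anchors negligible.
MIN_MATURE_LEN = 16


@dataclass
class ReferenceCatalog:
    """Mature sequences plus optional precursor context.

    ``mature_context[name] = (precursor_name, offset)`` records where the
    mature sits (0-based) inside its precursor; matures without context are
    still usable, extension is simply a no-op for them.
    """

    matures: list[tuple[str, str]]
    precursors: dict[str, str] = field(default_factory=dict)
    mature_context: dict[str, tuple[str, int]] = field(default_factory=dict)
    min_mature_len: int = MIN_MATURE_LEN

    def usable_matures(self) -> list[tuple[str, str]]:
        return [(n, s) for n, s in self.matures if len(s) >= self.min_mature_len]

    def mature_seq(self, name: str) -> str:
        for n, s in self.matures:
            if n == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class MatchSpan:
    """Half-open 0-based interval of a read covered by (an extension of) a mature."""

    start: int
    end: int
    mature_name: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")


def _read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, normalize_sequence(str(rec.seq))))
    return records


def load_catalog(
    mature_fasta: str | os.PathLike,
    precursor_fasta: str | os.PathLike | None = None,
    min_mature_len: int = MIN_MATURE_LEN,
) -> ReferenceCatalog:
    """Build a catalog from mature (and optionally precursor) FASTA files.

    FASTA may be RNA- or DNA-alphabet and line-wrapped; the record name is
    the first whitespace-delimited header token. Context is assigned by
    exact substring search, preferring the precursor whose name shares the
    longest prefix with the mature's name (miRBase convention: mature
    ``xxx-mir-1-5p`` lives in precursor ``xxx-mir-1``).
    """
    matures = _read_fasta(mature_fasta)
    catalog = ReferenceCatalog(matures=matures, min_mature_len=min_mature_len)
    if not catalog.usable_matures():
        raise CatalogError(
            f"no usable matures (length >= {min_mature_len}) in {mature_fasta}"
        )
    if precursor_fasta is not None:
        precursor_records = _read_fasta(precursor_fasta)
        catalog.precursors = dict(precursor_records)
        order = [name for name, _ in precursor_records]
        for mat_name, mat_seq in matures:
            ranked = sorted(
                order,
                key=lambda p: (-_common_prefix_len(mat_name, p), order.index(p)),
            )
            for prec_name in ranked:
                offset = catalog.precursors[prec_name].find(mat_seq)
                if offset >= 0:
                    catalog.mature_context[mat_name] = (prec_name, offset)
                    break
    return catalog


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


class AhoCorasick:
    """Multi-pattern exact matcher over DNA text.

    Built once from the catalog's usable matures; a single left-to-right
    pass over a read reports every occurrence of every pattern (overlaps
    included). The goto/failure construction is compiled into a full DFA
    over the observed alphabet so traversal is one dict lookup per base.
    """

    def __init__(self, patterns: dict[str, str]):
        if not patterns:
            raise CatalogError("cannot build an automaton with zero patterns")
        self.patterns = dict(patterns)
        # trie construction: state 0 is the root
        goto: list[dict[str, int]] = [{}]
        out: list[list[tuple[int, str]]] = [[]]
        for name, pat in patterns.items():
            state = 0
            for ch in pat:
                nxt = goto[state].get(ch)
                if nxt is None:
                    goto.append({})
                    out.append([])
                    nxt = len(goto) - 1
                    goto[state][ch] = nxt
                state = nxt
            out[state].append((len(pat), name))
        # failure links by BFS, then collapse into a DFA
        fail = [0] * len(goto)
        queue: deque[int] = deque()
        for state in goto[0].values():
            queue.append(state)
        while queue:
            state = queue.popleft()
            for ch, nxt in goto[state].items():
                queue.append(nxt)
                f = fail[state]
                while f and ch not in goto[f]:
                    f = fail[f]
                fail[nxt] = goto[f].get(ch, 0) if goto[f].get(ch, 0) != nxt else 0
                out[nxt] = out[nxt] + out[fail[nxt]]
        # DFA: delta[state][ch] defined for every (state, ch) seen in the trie
        alphabet = {ch for trans in goto for ch in trans}
        delta: list[dict[str, int]] = [dict() for _ in goto]
        for ch in alphabet:
            delta[0][ch] = goto[0].get(ch, 0)
        for state in _bfs_order(goto):
            if state == 0:
                continue
            for ch in alphabet:
                delta[state][ch] = goto[state].get(ch, delta[fail[state]][ch])
        self._delta = delta
        self._out = out

    def iter_matches(self, text: str) -> Iterator[tuple[int, int, str]]:
        """Yield (end_exclusive, length, pattern_name) for every occurrence."""
        delta = self._delta
        out = self._out
        state = 0
        for i, ch in enumerate(text):
            state = delta[state].get(ch, 0)
            if out[state]:
                for length, name in out[state]:
                    yield i + 1, length, name


def _bfs_order(goto: list[dict[str, int]]) -> list[int]:
    order = [0]
    queue: deque[int] = deque([0])
    while queue:
        state = queue.popleft()
        for nxt in goto[state].values():
            order.append(nxt)
            queue.append(nxt)
    return order


def build_automaton(catalog: ReferenceCatalog) -> AhoCorasick:
    """Compile the catalog's usable matures into a multi-pattern matcher."""
    usable = catalog.usable_matures()
    if not usable:
        raise CatalogError("catalog has no usable matures")
    # duplicate sequences under different names: keep the lexicographically
    # smallest name so the tie policy in find_match stays deterministic
    by_seq: dict[str, str] = {}
    for name, seq in usable:
        if seq not in by_seq or name < by_seq[seq]:
            by_seq[seq] = name
    return AhoCorasick({name: seq for seq, name in by_seq.items()})


def find_match(read: Read, matcher: AhoCorasick) -> MatchSpan | None:
    """Best mature occurrence in the read, or None.

    Tie policy when several matures occur: longest mature first, then
    leftmost start, then lexicographically smallest name — deterministic
    and favouring the most specific anchor.
    """
    best: tuple[int, int, str] | None = None  # (-length, start, name)
    for end, length, name in matcher.iter_matches(read.sequence):
        key = (-length, end - length, name)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    neg_length, start, name = best
    return MatchSpan(start, start - neg_length, name)


def extend_match(read: Read, span: MatchSpan, catalog: ReferenceCatalog) -> MatchSpan:
    """Widen a mature match while read bases equal the precursor's flanks.

    Extension is exact (no mismatches tolerated): tolerating even one
    mismatch would absorb a random-mer base about 25% of the time and bias
    the inferred random-mer lengths downward. Without precursor context the
    span is returned unchanged. Extension is idempotent.
    """
    context = catalog.mature_context.get(span.mature_name)
    if context is None:
        return span
    prec_name, offset = context
    precursor = catalog.precursors[prec_name]
    seq = read.sequence
    start, end = span.start, span.end
    # align precursor coordinates with the span: the span may already be an
    # extension, so locate the mature verbatim inside it
    rel = seq[start:end].find(catalog.mature_seq(span.mature_name))
    if rel < 0:  # span no longer contains the mature verbatim; nothing to do
        return span
    p_start = offset - rel
    p_end = p_start + (end - start)
    while start > 0 and p_start > 0 and seq[start - 1] == precursor[p_start - 1]:
        start -= 1
        p_start -= 1
    while end < len(seq) and p_end < len(precursor) and seq[end] == precursor[p_end]:
        end += 1
        p_end += 1
    return MatchSpan(start, end, span.mature_name)
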