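"""Streaming FASTQ I/O, sample sheets, and report/trim-spec writers.

Reads are delivered in fixed-size batches so the detector can apply its
stop rule at batch boundaries without ever holding a whole file in memory.
gzip compression is recognised by magic bytes, not by file extension.
"""

from __future__ import annotations

import gzip
import io
import json
import os
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastqParseError, SampleSheetError

GZIP_MAGIC = b"\x1f\x8b"

_RNA_TO_DNA = str.maketrans("uU", "tT")


@dataclass(frozen=True)
class Read:
    """A single-end sequencing read.

    ``sequence`` is uppercase DNA over {A,C,G,T,N}; U is converted to T on
    ingest so RNA-alphabet references and reads interoperate.
    """

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self):
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class SampleSheetEntry:
    sample_id: str
    fastq_path: str


def open_text_auto(path: str | os.PathLike) -> IO[str]:
    """Open a text file, transparently decompressing gzip.

    Detection is by the two gzip magic bytes, so a mislabelled ``.fastq``
    that is really compressed (or vice versa) still parses.
    """
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="ascii")
    return io.TextIOWrapper(raw, encoding="ascii")


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert U to T."""
    return seq.translate(_RNA_TO_DNA).upper()


def read_fastq_batches(
    path: str | os.PathLike, batch_size: int
) -> Iterator[list[Read]]:
    """Yield lists of ``batch_size`` reads (final batch may be shorter).

    Reads are delivered in file order with sequences normalized to
    uppercase DNA. An empty file yields nothing. A malformed 4-line record
    raises :class:`FastqParseError` naming the record index.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    batch: list[Read] = []
    n_records = 0
    with open_text_auto(path) as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqParseError(
                    f"malformed FASTQ record at index {n_records}: {exc}",
                    record_index=n_records,
                ) from exc
            read_id = title.split(None, 1)[0] if title else ""
            batch.append(Read(read_id, normalize_sequence(seq), qual))
            n_records += 1
            if len(batch) == batch_size:
                yield batch
                batch = []
    if batch:
        yield batch


def write_fastq(reads: Iterable[Read], path: str | os.PathLike) -> None:
    """Write reads as 4-line FASTQ; gzip output iff the path ends in .gz."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as handle:
        for read in reads:
            qual = read.quality if read.quality is not None else "I" * len(read.sequence)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def parse_sample_sheet(path: str | os.PathLike) -> list[SampleSheetEntry]:
    """Parse a tab-delimited sample sheet: column 1 = sample ID, column 2 = FASTQ path.

    Lines starting with ``#`` are skipped; extra columns are ignored.
    """
    entries: list[SampleSheetEntry] = []
    seen: set[str] = set()
    with open(path, "rt") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise SampleSheetError(
                    f"line {lineno}: expected >= 2 tab-delimited columns "
                    f"(sample_id, fastq_path), got {line!r}"
                )
            sample_id, fastq_path = fields[0].strip(), fields[1].strip()
            if sample_id in seen:
                raise SampleSheetError(f"line {lineno}: duplicate sample_id {sample_id!r}")
            seen.add(sample_id)
            entries.append(SampleSheetEntry(sample_id, fastq_path))
    return entries


REPORT_COLUMNS = [
    "sample_id",
    "adapter_class",
    "adapter_seq",
    "len_5p_randmer",
    "len_3p_randmer",
    "n_reads_scanned",
    "n_matched",
    "winner_count",
    "support_fraction",
]


def write_report(calls, path: str | os.PathLike) -> None:
    """Write a TSV with one row per (sample_id, AdapterCall) pair.

    ``calls`` may also contain (sample_id, dict) rows so the CLI can record
    per-sample failures without a full AdapterCall.
    """
    with open(path, "wt") as handle:
        handle.write("\t".join(REPORT_COLUMNS) + "\n")
        for sample_id, call in calls:
            if isinstance(call, dict):
                row = {col: call.get(col, "") for col in REPORT_COLUMNS}
                row["sample_id"] = sample_id
            else:
                row = {
                    "sample_id": sample_id,
                    "adapter_class": call.adapter_class,
                    "adapter_seq": call.adapter_seq,
                    "len_5p_randmer": call.len_5p_randmer,
                    "len_3p_randmer": call.len_3p_randmer,
                    "n_reads_scanned": call.n_reads_scanned,
                    "n_matched": call.n_matched,
                    "winner_count": call.winner_count,
                    "support_fraction": f"{call.support_fraction:.6f}",
                }
            handle.write("\t".join(str(row[col]) for col in REPORT_COLUMNS) + "\n")


def write_trim_spec(call, sample_id: str, path: str | os.PathLike) -> None:
    """Write one JSON object with the fields a trimmer needs.

    ``adapter`` is the 3' adapter sequence (empty for poly(A) or no
    adapter), ``cut_5p``/``cut_3p`` are the random-mer lengths to remove,
    and ``polyA`` says whether the 3' tail is a poly(A) run (trim with a
    poly(A) routine rather than a sequence match).
    """
    spec = {
        "sample_id": sample_id,
        "adapter": call.adapter_seq if call.adapter_class == "sequence" else "",
        "cut_5p": call.len_5p_randmer,
        "cut_3p": call.len_3p_randmer,
        "polyA": call.adapter_class == "polyA",
    }
    with open(path, "wt") as handle:
        json.dump(spec, handle)
        handle.write("\n")
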