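import pytest

from srnadapt.io_fastq import Read, write_fastq
from srnadapt.reference import ReferenceCatalog

# a let-7-family-like mature embedded in a hairpin with known flanks
LET7_MATURE = "TGAGGTAGTAGGTTGTATAGTT"
LET7_PREC = "CGGGGTGAGG" + LET7_MATURE + "GGTCTGAGGT"
MIR2_MATURE = "ACCGATCGTTAGCACTGA"
MIR2_PREC = "TTACCATGCA" + MIR2_MATURE + "CATTGCCAAG"


@pytest.fixture
def small_catalog() -> ReferenceCatalog:
    return ReferenceCatalog(
        matures=[("let-7x", LET7_MATURE), ("mir-2x", MIR2_MATURE)],
        precursors={"let-7x": LET7_PREC, "mir-2x": MIR2_PREC},
        mature_context={"let-7x": ("let-7x", 10), "mir-2x": ("mir-2x", 10)},
    )


@pytest.fixture
def fastq_writer(tmp_path):
    def _write(sequences, name="reads.fastq"):
        path = tmp_path / name
        reads = [Read(f"r{i}", seq, "I" * len(seq)) for i, seq in enumerate(sequences)]
        write_fastq(reads, path)
        return path

    return _write
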