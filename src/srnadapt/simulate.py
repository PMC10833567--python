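"""Nine-scenario read-structure simulator with ground-truth sidecars.

Each scenario fixes which structural elements a library carries:

    1  3' adapter only                  5  poly(A) tail only
    2  5' random-mer + 3' adapter       6  5' random-mer + poly(A)
    3  3' random-mer + 3' adapter       7  3' random-mer + poly(A)
    4  both random-mers + 3' adapter    8  both random-mers + poly(A)
    9  no adapter (negative control: already-trimmed reads)

A dataset draws its random-mer lengths once (uniform 1-5 bp per flagged
end) and one adapter from a pool; every read then gets fresh random bases
for the random-mers, a true small RNA sampled from the catalog (ends
shortened 0-2 bp to emulate isomiR/trimming variants), the 3' tail, random
filler up to the read length, and per-base substitution errors. Scenario 9
reads stay unpadded and variable-length, as really-post-trimmed reads are.

The true reads are catalog-derived rather than sampled from a public run,
so the suite is self-contained and a pure function of its base seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError
from .io_fastq import Read, write_fastq
from .reference import MIN_MATURE_LEN, ReferenceCatalog

BASES = np.array(list("ACGT"))

#: scenario_id -> (has_5p_randmer, has_3p_randmer, tail_kind)
SCENARIOS: dict[int, tuple[bool, bool, str]] = {
    1: (False, False, "adapter"),
    2: (True, False, "adapter"),
    3: (False, True, "adapter"),
    4: (True, True, "adapter"),
    5: (False, False, "polyA"),
    6: (True, False, "polyA"),
    7: (False, True, "polyA"),
    8: (True, True, "polyA"),
    9: (False, False, "none"),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Configuration for one simulated dataset."""

    scenario_id: int
    n_reads: int = 10_000
    read_len: int = 50
    error_rate: float = 0.0025
    polyA_len: int = 12
    randmer_min: int = 1
    randmer_max: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.scenario_id not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario_id}")

    @property
    def has_5p_randmer(self) -> bool:
        return SCENARIOS[self.scenario_id][0]

    @property
    def has_3p_randmer(self) -> bool:
        return SCENARIOS[self.scenario_id][1]

    @property
    def tail_kind(self) -> str:
        return SCENARIOS[self.scenario_id][2]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth emitted alongside one simulated dataset."""

    dataset_id: str
    adapter_class: str
    adapter_seq: str
    len_5p: int
    len_3p: int
    seed: int


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length)) if length else ""


def generate_catalog(
    n_matures: int = 50,
    mature_len_range: tuple[int, int] = (18, 24),
    flank_len: int = 20,
    seed: int = 0,
    out_dir: str | os.PathLike | None = None,
) -> ReferenceCatalog:
    """Random mature/precursor catalog standing in for a real reference.

    Each mature (uniform ACGT, length uniform in ``mature_len_range``) is
    embedded in a precursor = random 5' flank + mature + random 3' flank.
    Matures are regenerated until no mature occurs in any other precursor,
    so anchoring is unambiguous. When ``out_dir`` is given, ``mature.fa``
    and ``hairpin.fa`` are written there. Deterministic given ``seed``.
    """
    if n_matures < 1:
        raise ValueError("n_matures must be >= 1")
    if mature_len_range[0] < MIN_MATURE_LEN:
        raise ValueError(f"mature lengths must be >= {MIN_MATURE_LEN}")
    rng = np.random.default_rng(seed)
    matures: list[tuple[str, str]] = []
    precursors: dict[str, str] = {}
    context: dict[str, tuple[str, int]] = {}
    for i in range(n_matures):
        name = f"mir-{i + 1}"
        for _ in range(100):
            length = int(rng.integers(mature_len_range[0], mature_len_range[1] + 1))
            mat = _random_seq(rng, length)
            clash = any(mat in p for p in precursors.values()) or any(
                m in mat or mat in m for _, m in matures
            )
            if not clash:
                break
        else:
            raise GenerationError(f"could not generate a unique mature after 100 tries ({name})")
        for _ in range(100):
            prec = _random_seq(rng, flank_len) + mat + _random_seq(rng, flank_len)
            # fresh flanks must not create an occurrence of an earlier mature
            if not any(m in prec for _, m in matures):
                break
        else:
            raise GenerationError(f"could not embed {name} without a clash")
        matures.append((name, mat))
        precursors[name] = prec
        context[name] = (name, flank_len)
    catalog = ReferenceCatalog(matures=matures, precursors=precursors, mature_context=context)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "mature.fa", "wt") as fh:
            for name, seq in matures:
                fh.write(f">{name}\n{seq}\n")
        with open(out / "hairpin.fa", "wt") as fh:
            for name, seq in precursors.items():
                fh.write(f">{name}\n{seq}\n")
    return catalog


def default_adapter_pool(rng: np.random.Generator, n_adapters: int = 8, length: int = 25) -> list[str]:
    """Random 25-mer adapter pool (per-suite, derived from the seed)."""
    return [_random_seq(rng, length) for _ in range(n_adapters)]


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def simulate_dataset(
    spec: ScenarioSpec,
    catalog: ReferenceCatalog,
    adapter_pool: list[str],
    out_path: str | os.PathLike,
    dataset_id: str | None = None,
) -> TruthRecord:
    """Write one FASTQ dataset and return its ground truth.

    Random-mer lengths and the adapter are dataset-level draws; random-mer
    *bases* are fresh per read. Reads with a tail are padded with random
    nucleotides to ``read_len`` (and truncated to it when the construct
    runs longer, as a fixed-cycle sequencer would); scenario-9 reads are
    left at their natural length.
    """
    if spec.tail_kind == "adapter" and any(len(a) < 20 for a in adapter_pool):
        raise ValueError("adapter pool entries must be >= 20 bp")
    rng = np.random.default_rng(spec.seed)
    if dataset_id is None:
        dataset_id = f"scenario{spec.scenario_id}_seed{spec.seed}"

    len_5p = int(rng.integers(spec.randmer_min, spec.randmer_max + 1)) if spec.has_5p_randmer else 0
    len_3p = int(rng.integers(spec.randmer_min, spec.randmer_max + 1)) if spec.has_3p_randmer else 0
    if spec.tail_kind == "adapter":
        adapter = adapter_pool[int(rng.integers(len(adapter_pool)))]
        adapter_class = "sequence"
    elif spec.tail_kind == "polyA":
        adapter = "A" * spec.polyA_len
        adapter_class = "polyA"
    else:
        adapter = ""
        adapter_class = "none"

    mature_seqs = [seq for _, seq in catalog.matures]
    reads: list[Read] = []
    for i in range(spec.n_reads):
        mature = mature_seqs[int(rng.integers(len(mature_seqs)))]
        trim5 = int(rng.integers(0, 3))
        trim3 = int(rng.integers(0, 3))
        insert = mature[trim5 : len(mature) - trim3]
        seq = _random_seq(rng, len_5p) + insert + _random_seq(rng, len_3p)
        if spec.tail_kind != "none":
            seq += adapter
            if len(seq) < spec.read_len:
                seq += _random_seq(rng, spec.read_len - len(seq))
            seq = seq[: spec.read_len]
        seq = _apply_errors(rng, seq, spec.error_rate)
        reads.append(Read(f"{dataset_id}_r{i}", seq, "I" * len(seq)))
    write_fastq(reads, out_path)
    return TruthRecord(
        dataset_id=dataset_id,
        adapter_class=adapter_class,
        adapter_seq=adapter,
        len_5p=len_5p,
        len_3p=len_3p,
        seed=spec.seed,
    )


MANIFEST_COLUMNS = [
    "dataset_id",
    "scenario_id",
    "fastq_path",
    "adapter_class",
    "adapter_seq",
    "len_5p",
    "len_3p",
    "seed",
]


def simulate_suite(
    out_dir: str | os.PathLike,
    datasets_per_scenario: int = 20,
    base_seed: int = 0,
    n_reads: int = 10_000,
    n_matures: int = 50,
    gzip_fastq: bool = False,
) -> Path:
    """Generate the full nine-scenario suite; return the manifest path.

    Writes a synthetic catalog (``mature.fa``/``hairpin.fa``), one FASTQ
    per dataset, and ``manifest.tsv`` with one truth row per dataset. The
    whole suite — catalog, adapter pool, every read — is a pure function
    of ``base_seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(base_seed)
    catalog_seed = int(master.integers(2**31))
    pool_rng = np.random.default_rng(int(master.integers(2**31)))
    catalog = generate_catalog(n_matures=n_matures, seed=catalog_seed, out_dir=out)
    adapter_pool = default_adapter_pool(pool_rng)

    rows = []
    ext = ".fastq.gz" if gzip_fastq else ".fastq"
    for scenario_id in sorted(SCENARIOS):
        for rep in range(datasets_per_scenario):
            seed = int(master.integers(2**31))
            dataset_id = f"s{scenario_id}_rep{rep + 1}"
            fastq_path = out / f"{dataset_id}{ext}"
            spec = ScenarioSpec(scenario_id=scenario_id, n_reads=n_reads, seed=seed)
            truth = simulate_dataset(spec, catalog, adapter_pool, fastq_path, dataset_id=dataset_id)
            rows.append(
                {
                    "dataset_id": dataset_id,
                    "scenario_id": scenario_id,
                    "fastq_path": str(fastq_path),
                    "adapter_class": truth.adapter_class,
                    "adapter_seq": truth.adapter_seq,
                    "len_5p": truth.len_5p,
                    "len_3p": truth.len_3p,
                    "seed": seed,
                }
            )
    manifest_path = out / "manifest.tsv"
    with open(manifest_path, "wt") as fh:
        fh.write(f"# base_seed={base_seed}\n")
        pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(fh, sep="\t", index=False)
    return manifest_path


def load_manifest(manifest_path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(
        manifest_path, sep="\t", comment="#", keep_default_na=False, dtype={"adapter_seq": str}
    )


def score_dataset(truth: dict, call: dict, n_frag: int = 12) -> bool:
    """One dataset scores correct iff class, adapter identity (first
    ``n_frag`` bases for literal adapters), and both random-mer lengths all
    match the truth; for adapter-free truth the call must be class none
    with both lengths zero."""
    if truth["adapter_class"] == "none":
        return (
            call["adapter_class"] == "none"
            and int(call["len_5p_randmer"]) == 0
            and int(call["len_3p_randmer"]) == 0
        )
    if call["adapter_class"] != truth["adapter_class"]:
        return False
    if truth["adapter_class"] == "sequence" and call["adapter_seq"] != truth["adapter_seq"][:n_frag]:
        return False
    return (
        int(call["len_5p_randmer"]) == int(truth["len_5p"])
        and int(call["len_3p_randmer"]) == int(truth["len_3p"])
    )


def score_suite(
    manifest_path: str | os.PathLike, calls_path: str | os.PathLike
) -> tuple[dict[int, float], float]:
    """Score a detection report against a suite manifest.

    ``calls_path`` is a report TSV whose sample_id column holds dataset
    IDs. Returns (per-scenario accuracy, overall accuracy). A manifest
    dataset with no call row is a scoring error.
    """
    manifest = load_manifest(manifest_path)
    calls = pd.read_csv(calls_path, sep="\t", keep_default_na=False, dtype={"adapter_seq": str})
    calls = calls.set_index("sample_id")
    per_scenario: dict[int, list[bool]] = {}
    for _, truth in manifest.iterrows():
        if truth["dataset_id"] not in calls.index:
            raise KeyError(f"no call for dataset {truth['dataset_id']!r}")
        call = calls.loc[truth["dataset_id"]].to_dict()
        ok = score_dataset(truth.to_dict(), call)
        per_scenario.setdefault(int(truth["scenario_id"]), []).append(ok)
    accuracies = {sc: float(np.mean(v)) for sc, v in sorted(per_scenario.items())}
    overall = float(np.mean([ok for v in per_scenario.values() for ok in v]))
    return accuracies, overall
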