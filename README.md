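# srnadapt

Reference-anchored, prior-free detection of 3' adapter sequences and 5'/3'
random-mer lengths in small RNA sequencing reads — plus the nine-scenario
read-structure simulator used to validate it.

## The problem

Small RNA-seq inserts (~18–24 nt miRNAs) are shorter than the read length,
so every read runs into the 3' adapter — and different library preparation
kits produce very different read structures. Besides a plain
`insert + adapter` layout, kits insert random-mers (NEXTFLEX's NNNN,
QIAseq/D-Plex 12-bp UMIs, SMARTer/CATS template-switching motifs) at either
end of the insert, or replace the adapter with a low-complexity poly(A)
tail. Public datasets frequently omit or mislabel this information, and
k-mer-overrepresentation adapter detectors cannot see through random-mers
or homopolymer tails. Anyone reprocessing deposited small RNA-seq data
needs the generalized structure

```
[5' random-mer] [true small RNA] [3' random-mer] [3' adapter | poly(A) | nothing] [filler]
```

resolved per sample: the two random-mer lengths and the adapter.

## The method

1. **Anchor.** Build an Aho-Corasick automaton over a catalog of mature
   small RNA sequences (e.g. miRBase `mature.fa`) and locate exact
   occurrences inside raw reads in a single pass per read.
2. **Extend.** Widen each match base-by-base while the read agrees with the
   mature's precursor (hairpin) context, so templated flanking bases are
   not mistaken for random-mer or adapter sequence.
3. **Split & tally.** Split each matched read into upstream / core /
   downstream. For every downstream, extract the *n*-bp window (default
   n = 12) at every shift k = 0..m (default m = 8) and tally
   (shift, fragment) counts.
4. **Collapse.** Keep the top 5 fragments per shift, link records where the
   fragment at shift k+1 is the shift-k fragment slid one base
   (parent/child), and walk chains: advance to the best child only on a
   count jump consistent with shedding one random base
   (ratio in (1.2, 10]). Chain terminals form the candidate pool.
5. **Call.** The highest-count pool record wins: its fragment is the 3'
   adapter (12 bp suffices for any trimmer), its shift is the 3' random-mer
   length. A ≥90%-adenine winner is classified poly(A); mostly-empty
   downstreams mean the reads are already trimmed (class `none`). The 5'
   random-mer length is the mode of upstream lengths.

Scanning streams 10,000-read batches and stops as soon as 1,000 reads have
matched the reference, so runtime is independent of file size.

## Worked example

Simulate one dataset per scenario against a 50-mature synthetic catalog,
then detect on the scenario-4 dataset (random-mers at both ends plus a
literal 3' adapter — the NEXTFLEX-style structure):

```bash
srnadapt simulate --out suite --seed 7 --datasets-per-scenario 1
srnadapt detect --fastq suite/s4_rep1.fastq --seq suite/mature.fa \
                --precursor suite/hairpin.fa --out calls
cat calls/report.tsv
```

```
sample_id  adapter_class  adapter_seq   len_5p_randmer  len_3p_randmer  n_reads_scanned  n_matched  winner_count  support_fraction
s4_rep1    sequence       CAAAGCGTTAAT  2               1               10000            1827       1024          0.560482
```

Reading the row: of 10,000 reads scanned, 1,827 contained an exact catalog
mature; the winning 12-bp window `CAAAGCGTTAAT` at shift 1 was supported by
1,024 of the tallied downstreams (56%), so the library carries a literal 3'
adapter starting `CAAAGCGTTAAT`, preceded by a 1-bp 3' random-mer, with a
2-bp random-mer at the 5' end. The simulator's ground truth for this
dataset is adapter `CAAAGCGTTAATCAGCTTTGTCGTT` with random-mer lengths
(2, 1) — the call matches (the reported adapter is the first 12 bases).
`calls/s4_rep1.trimspec.json` holds the same result as a machine-readable
trim recipe:

```json
{"sample_id": "s4_rep1", "adapter": "CAAAGCGTTAAT", "cut_5p": 2, "cut_3p": 1, "polyA": false}
```

For many samples at once, pass a tab-delimited sheet
(`sample_id<TAB>fastq_path`) via `--list`. Library use mirrors the CLI:
`load_catalog`, `detect_adapter`, `simulate_suite`, `score_suite` in
`srnadapt`.

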