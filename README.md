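# fastqdedup

De novo PCR-duplicate removal for single- and paired-end FASTQ/FASTA data,
with a RAM budget that does not grow with input size.

During library amplification, PCR produces copies of the same template
molecule; after sequencing these duplicates can make up tens of percent of a
dataset and bias any quantitative analysis downstream. De novo deduplicators
identify duplicates from sequence content alone, without aligning to a
reference genome — but most of them load the whole dataset into RAM, which
is prohibitive for modern Hi-C, WGS or RNA–chromatin interaction libraries of
hundreds of gigabytes. `fastqdedup` instead external-sorts reads by sequence
under a user-set memory ceiling, trading RAM for roughly 2× the input size in
temporary disk space, then removes duplicates in a single pass over the
sorted stream in *O(N log N)* time.

## Duplicate definitions

The sequence-based engine supports three definitions of "duplicate":

- **tight** (default) — exact full-length sequence equality; reads of
  different lengths are never duplicates.
- **loose** — FastUniq-style prefix matching: the shorter read is a duplicate
  when it equals the prefix of the longer. On paired-end data the result
  depends on the order of the two input files, an inherent ambiguity of
  prefix-based duplicate identity.
- **tail-hamming** — two reads are duplicates when they are *adjacent in the
  sorted stream*, have equal length, and their Hamming distance is ≤ a user
  threshold *k*. Motivated by sequencing errors concentrating at read 3'
  ends. Because "within distance k" is not transitive, any mismatch-tolerant
  deduplication is algorithm-defined; this one compares each read to its
  immediate predecessor.

For paired-end data a pair is removed only when **both** its mates are
duplicates of the corresponding mates of the retained pair. Read IDs,
sequences and qualities pass through unchanged; the survivor of each
duplicate group is its first occurrence in the input.

A fourth mode, **fast**, deduplicates exact copies in memory using sequences
packed 16 bases per 64-bit word (4-bit codes, so `N`/IUPAC letters stay
distinct). It preserves input order, keeps exactly the same read IDs as tight
mode, and cannot be memory-limited.

## Worked example

Generate a synthetic amplified library — 1000 templates × 5 reads, with
3'-biased substitution errors on some copies and 3'-truncated copies on
others — then deduplicate it in each mode:

```sh
fastqdedup synth --templates 1000 --copies 5 --error-rate 0.1 \
    --truncation-fraction 0.2 --seed 42 --out lib
fastqdedup dedup -i lib_1.fastq -o tight.fastq
fastqdedup dedup -i lib_1.fastq -o loose.fastq --compare loose
fastqdedup dedup -i lib_1.fastq -o th.fastq --compare tail-hamming --hamming 2
fastqdedup dedup -i lib_1.fastq -o fast.fastq --mode fast
```

The runs print (to stderr):

| mode | reads in | kept | removed | % removed |
|---|---|---|---|---|
| tight | 5000 | 3870 | 1130 | 22.60% |
| loose | 5000 | 2758 | 2242 | 44.84% |
| tail-hamming k=2 | 5000 | 2510 | 2490 | 49.80% |
| fast | 5000 | 3870 | 1130 | 22.60% |

Tight removes only the error-free exact copies. Loose additionally removes
the truncated copies (prefix duplicates). Tail-hamming k=2 additionally
removes copies whose substitution errors stayed within two mismatches.
Fast agrees with tight read-for-read. The `lib.manifest.tsv` ground-truth
file records each read's template and class, so these counts can be checked
against what the generator actually emitted.

Paired-end data uses two synchronized files: `-i`/`-u` in, `-o`/`-p` out.
Gzip-compressed input is detected automatically; a `.gz` output path
produces gzip output. `--mem-limit MIB` caps the sort buffer (default
2048 MiB, floor 16 MiB).

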