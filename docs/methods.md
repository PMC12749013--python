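# Methods

## The deduplication model

`fastqdedup` treats a sequencing library as a stream of units — a read
(single-end) or an ordered read pair (paired-end) — and asks, for each unit,
whether it is a PCR duplicate of a unit already seen. No reference genome is
used: duplicate identity is a pure function of the sequence content, so
reads from distinct loci with identical sequences are (unavoidably)
indistinguishable from true PCR duplicates.

### Sequence-based engine

1. **Sort.** Units are sorted by their uppercased sequence bytes; paired
   units by `left + 0x00 + right`. The `0x00` sentinel sorts before every
   base letter, so a left mate that is a prefix of another left mate sorts
   ahead of all its extensions. The secondary sort key is always the unit's
   0-based position in the input, which (a) makes the output of every mode a
   deterministic function of the input, and (b) makes the first occurrence
   in the input the retained member of every duplicate group.
2. **Scan.** A single pass over the sorted stream. For **tight** and
   **loose**, each unit is compared against the current *group
   representative* — the first kept unit of the group; a unit that fails the
   comparison is kept and becomes the new representative. Prefix-extensions
   of a representative are contiguous in sorted order, which is what makes
   the representative rule correct for loose. For **tail-hamming**, each
   unit is compared against its *immediate predecessor in the sorted
   stream*, whether or not that predecessor was kept: adjacency in the
   sorted file is the definition, not group membership.
3. **Write.** Kept units are streamed to the output in sorted order, fields
   byte-identical to the input. Paired outputs are written in lockstep and
   therefore stay synchronized.

A pair is a duplicate only if *both* mates satisfy the active comparator
against the corresponding mates of the reference pair.

Comparator details:

- tight: string equality after uppercasing; unequal lengths never match.
- loose: the shorter sequence must equal the longer one's prefix; equal
  lengths degenerate to equality.
- tail-hamming(k): unequal lengths never match (Hamming distance is
  undefined there, mirroring tight's length rule); otherwise positional
  mismatches are counted with early exit once they exceed k.

`N` and the other IUPAC ambiguity letters are ordinary symbols everywhere:
`N` matches `N` and nothing else.

### The transitivity caveat

"Within Hamming distance k" is not an equivalence relation. In a sorted
chain A, B, C with d(A,B) ≤ k, d(B,C) ≤ k but d(A,C) > k, this scan removes
both B and C (each against its predecessor); an algorithm comparing against
the kept representative would keep C. Both are valid resolutions of an
ill-posed problem — there is no ground truth once mismatches are allowed —
so tail-hamming results are comparable only between runs of the same
algorithm. Consequently tail-hamming is *not* idempotent in general
(removing B can separate A from C by more than one sorted position
neighbour relation); a second pass never removes more than the first, which
the test suite asserts, and k = 0 is exactly tight. Tight and loose are
idempotent.

### Fast engine

Exact duplicates only, in memory, preserving input order. Sequences are
packed 16 bases per 64-bit word with a 4-bit code per symbol
(A C G T N R Y S W K M B D H V U → 0…15) plus the explicit base length. The
4-bit width (rather than 2-bit) keeps all 16 supported symbols collision
free; the stored length disambiguates sequences whose packed words tie.
Keys are full packed tuples, not hashes of them, so a false-positive
removal is impossible. Kept read IDs are provably identical to tight
mode's: both keep the first occurrence of each distinct sequence (pair).
Memory cannot be capped in this mode.

## External sort and resource bounds

The sort buffers units until their estimated footprint would exceed the
budget, then spills one sorted run to disk and continues; runs are finally
k-way merged (heap, one head record per run). The footprint of a unit is
the byte length of its text fields plus a fixed 96 bytes per mate — an
approximation of container overhead; the contract is bounded,
parameterizable buffering, not byte-exact RSS. The budget floor is 16 MiB
(guarantees progress); the default is 2048 MiB.

Runs are length-prefixed binary frames in a private subdirectory of the
chosen tmpdir, removed on completion and on every error path. One spill
pass writes approximately one serialized copy of the input, so cumulative
temporary bytes are about 1.1× the input file size for typical read
lengths (framing overhead ≈ 25 bytes/record against the ~6 bytes/record of
FASTQ punctuation), within the documented 2× disk cost. If more than 128
runs exist (a portability bound for default open-file limits), groups of
128 are cascade-merged first, which can add a second ~1× pass in the worst
case while deleted inputs keep live bytes bounded. If the entire input fits
in one buffer, the sort happens in memory and no temporary file is created.
Output is byte-identical for every budget, because `(key, index)` is a
total order.

## Synthetic libraries

The generator emulates a PCR-amplified shotgun library:

- **Templates**: i.i.d. uniform A/C/G/T sequences (default length 100 bp),
  single or paired. At realistic template counts and lengths, accidental
  exact collisions are birthday-bounded to effectively zero, so the
  template count is the exact expected output of tight deduplication on an
  error-free library.
- **Copies** per template, each classed as `exact_pcr_copy`,
  `tail_error_copy` (substitutions drawn from the error profile landed), or
  `truncated_copy` (3' truncation of 1–10 bp by default: a loose-mode
  prefix duplicate). Defaults emit exact copies only
  (`error-rate 0`, `truncation-fraction 0`); the CLI example conditions in
  the README use `--error-rate 0.1 --truncation-fraction 0.2` to exercise
  all three comparators at once.
- **Error profile**: substitution probability 0 over the first 80% of
  positions, rising linearly to the configured maximum at the final base —
  the 3'-end error enrichment that motivates tail-hamming. Substitution
  only: no indels, matching what Hamming comparison can express.
- **Emission**: deterministic shuffle, constant high qualities (`I`,
  Phred 40), optional gzip (written with zeroed mtime so identical seeds
  give identical bytes), plus a TSV truth manifest
  (`read_id  template_id  class`).

What the generator does **not** emulate — quality-score structure, indels,
optical-duplicate geometry, UMIs, non-uniform base composition — bounds
what the tests show: they validate the deduplication *semantics* and
resource contracts exactly, not error-mode coverage on real instruments.
The CLI's `--copies` counts total reads per template; the library-level
`amplify(copies=…)` counts additional copies beyond the original.

## Verification strategy and problem sizes

Every mode is checked against an independently written naive oracle (plain
built-in sort + literal in-memory scan, no shared engine code) on 20 seeded
libraries of ~10⁴ reads — every comparator/pairedness combination twice,
plus two single-end datasets of 10⁵ reads where a 16 MiB budget genuinely
splits the sort into multiple runs — under budgets of 16 MiB, 64 MiB and
1 GiB. Cross-mode identities (fast ≡ tight; tail-hamming k=0 ≡ tight;
loose ≡ tight at uniform read length), budget-invariance of output bytes,
truth-manifest recovery, paired-end synchronization, byte fidelity and
gzip round-trips are asserted end-to-end. The disk-cost measurement uses a
~96.75 MB library (150,000 templates × 3 reads × 100 bp) with a 16 MiB
budget; these sizes keep the whole suite at a few minutes on one CPU while
still exercising the multi-run external path.

## Numerical / procedural choices

- Tie-break and retention: lowest original index wins everywhere (nothing
  in the duplicate definitions prescribes which copy survives; this choice
  makes runs reproducible and modes comparable).
- Unequal lengths under tail-hamming: non-duplicate (distance undefined).
- Empty sequences are legal and compare as length-0 strings.
- FASTQ dialect: strict 4-line records; CRLF tolerated on input, LF
  written; sequence case preserved on output, uppercased for comparison;
  qualities are opaque payload (never interpreted).
- Empty-input percentage convention: 0.00% removed.
- Degenerate inputs: empty files produce empty outputs and exit 0;
  truncated FASTQ blocks and desynchronized pair files abort with distinct
  exit codes and no partial output left in place.

## Known limitations

- Loose mode's paired-end result is order-sensitive by construction (the
  test suite contains a minimal three-pair example where swapping the
  input files changes the kept count from 1 to 2).
- Exact FastUniq output equivalence is not claimed beyond the stated
  prefix rule.
- Single-threaded by design; no UMI handling, no optical-duplicate
  detection, no error correction.
- Fast mode's memory grows with the number of distinct sequences.
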