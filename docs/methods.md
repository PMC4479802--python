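# Methods

## Problem and model

A collection of same-species genomes is redundant twice over: every
sequence is close to the reference, and the sequences are close to each
other. `refcoll` encodes both layers explicitly instead of leaving the
second to a general-purpose compressor.

### First-level factoring

Each sequence is parsed greedily left to right against the reference R.
Matches are seeded by a k-mer hash table over R (open addressing, linear
probing, power-of-two capacity, load factor ≤ 0.7; 64-bit polynomial
hashing over raw ASCII codes so N and degenerate IUPAC letters need no
special case). A hash-seeded match must be at least h1m symbols long.
Every candidate is verified by direct string comparison before extension,
so hash collisions cannot corrupt output; among equal-length longest
matches the smallest reference position wins, making parses deterministic.

Immediately after a match the parser probes, in fixed order, the
continuations left by a substitution, a 1-symbol insertion, a 1-symbol
deletion and (optionally) 2-symbol indels, accepting a resumed match of
length ≥ h1e. The longest accepted probe is compared against the best
hash match at the same position; the longer wins and ties go to the probe,
whose position is predicted exactly by the encoder and therefore costs
almost nothing. Substituted/inserted symbols are emitted as literal tuples
before the short match, keeping the grammar to two tuple kinds. Short
matches re-arm the probe, so runs of nearby variants chain without
touching the hash table.

### Second-level factoring

Tuple streams of genomes sharing variants contain identical runs. For
every position of every *eligible* earlier stream, the index stores the
shortest run starting there whose weight reaches h2 (literal = 1,
first-level match = `match_weight` = 7); the current stream derives its
query key by the same rule, so identical content always meets. Candidate
lists are capped at the 64 most recent entries to bound scans on
pathological repeats. Matches extend forward tuple-by-tuple under
full-field equality (runs are copied verbatim on decode, so positional or
length-only equivalence would break losslessness); the heaviest candidate
wins, ties resolved to the most recent stream (which keeps the position
predictor warm), then the smallest tuple position. The first stream always
passes through unchanged.

### Entropy coding

A 32-bit carry-less range coder (Schindler-style renormalization,
byte-wise output) driven by adaptive frequency models: add-1
initialization, increment 32, halving when a table's total reaches 2^16 —
the total therefore always fits under the coder's bottom threshold.
Per-tuple fields and their contexts:

| field | context |
|---|---|
| tuple flag (4 symbols incl. terminator) | previous two flags |
| literal symbol | previous literal symbol |
| L1 position-delta class (perfect / good / poor) | none |
| L1 length class (≤2^8 / ≤2^16+2^8 / larger) | none |
| L2 sequence-id prefix (radix 256) | none |
| L2 sequence-id suffix | the prefix |
| L2 position-delta class (perfect / good / moderate / poor) | none |
| L2 tuple-count class (bounds 16 / 48 / 176 / 432) | none |
| every payload byte | (class, byte index) |

First-level positions are coded as the residual against
`last_pos + last_len + symbols_since`, where `symbols_since` counts
literal symbols and symbols covered by second-level copies since the last
explicit match; the predictor resets per sequence, with a zero initial
state so a sequence opening with a full-length match also scores a perfect
residual. Good residuals (|δ| ≤ 127) take one zig-zag byte, poor ones
four; the band is chosen so sign and magnitude fit one byte.

Second-level positions use a per-referenced-stream ledger A[u] = (last
copy position in L^u, symbols of the current sequence processed before
that copy). The expectation advances the stored position across L^u,
accumulating per-tuple symbol coverage while it stays within the symbols
processed since — implemented as a binary search over a coverage prefix
array, which is exactly equivalent to the stepwise advance. Cold entries
predict offset 0. Good residuals (|δ| ≤ 16) take one sign+magnitude byte,
moderate (≤ 256) a sign byte plus offset byte, poor four zig-zag bytes.

A fourth flag value terminates each sequence inside the coded stream.
Sequence lengths are also recorded in the metadata stream, so the
terminator is deliberate redundancy used as a corruption check.

### Stream and container format

The collection stream begins with an 8-byte magic, a format version, the
parameters (h1m, h1e, h2; a flags byte packing the 2-bp-indel option and
the eligibility stride) and a little-endian u32 sequence count, followed
by the range-coded payload. The archive is three files: zlib-compressed
JSON metadata (file names, ids, lengths, wrap widths, parameters), the
collection stream, and the reference coded by an order-1 model applied to
symbols gathered in triples (one model per triple slot). The reference
stream makes decompression self-contained but is excluded from reported
ratios, since the reference is not part of the collection.

### Random access

With `ref_fraction` f < 1, only every round(1/f)-th sequence (an even
spread, chosen over a prefix rule for late-sequence locality) may serve as
a second-level reference. Extraction field-decodes every stream up to the
target to keep the coder in sync, but expands to tuple/symbol level only
the eligible references and the target — at most ⌈f·n⌉ + 1 streams.
Processing order is strictly file order then record order, so archives are
byte-reproducible; this replaces a parallel FIFO design in which arrival
order, and hence the exact archive bytes, could vary run to run.

## Parameters

| parameter | default | meaning |
|---|---|---|
| h1m | 15 | seed/minimum length of a hash-found reference match (symbols) |
| h1e | 4 | minimum post-variant short-match length (symbols) |
| h2 | 11 | minimum second-level run weight |
| match_weight | 7 | weight of a first-level match in the run-weight rule |
| indel2 | off | probe 2-symbol indels as well (5 probes instead of 3) |
| ref_fraction | 1.0 | fraction of sequences usable as second-level references |

A toy configuration (h1m = 3, h1e = 2, h2 = 3, match weight 2) is exposed
as `TOY_PARAMS` for hand-checkable factoring examples.

## Synthetic data

`synthetic.py` generates uniform ACGT references (optional N-runs) and
mutated collections. Divergence profiles apply, in order: structural
insertions/deletions, per-base SNPs (always substituting a different
base), short indels (≤ 3 bp), N-runs and lowercase soft-masking. All
randomness derives from `numpy.random.SeedSequence`, so fixtures are
reproducible across platforms.

*Independent* mode mutates each record separately. *Diploid* mode emulates
a resequencing panel with linkage structure: eight founder haplotypes
carry variants at the nominal rates, each individual's ancestor is a
mosaic of founder segments (Poisson switch points at 3·10⁻⁶ per base,
standing in for historical recombination), and each of its two haplotypes
adds a private divergence step at 0.1× the nominal rates. Consequences:
haplotype pairs differ from each other far less than from the reference,
and unrelated individuals share long identical stretches wherever their
mosaics agree — the property that gives the second factoring level
cross-individual runs to copy, as shared population haplotypes do in real
cohorts. The founder count, switch rate and private fraction were fixed as
round, biologically plausible magnitudes. What the generator does *not*
model: mutation-rate heterogeneity, repeat families and segmental
duplications, realistic coalescent genealogies, CNVs and inversions.
Passing tests on this family therefore demonstrate correctness of the
algorithms and the expected qualitative behaviour of the two-level scheme,
not ratio forecasts for any particular real dataset (real repeat content,
for instance, mainly stresses the candidate-list cap).

## Numerical and degenerate-input choices

* Sequences shorter than h1m, all-N and empty sequences parse to literals
  (or nothing) and round-trip losslessly; an empty FASTA body under a
  header is treated as a valid empty record.
* Losslessness is defined over (header, residues, one wrap width per
  record); ragged input line widths are reproduced with uniform wrapping.
* Sequence ids in second-level matches are capped at 2^16 by the radix-256
  prefix/suffix split.
* Class boundaries are closed on the left-hand class (e.g. |δ| = 16 is
  good, 17 moderate; length 256 is short, 257 long).
* Decode verifies per-sequence lengths against the metadata and bounds on
  every copy; violations raise corruption errors naming the sequence or
  stream offset.

## Problem sizes used in the checks

The test suite and the acceptance script run entirely on generated data:
1000 randomized small collections for the round-trip family, 500 random
reference/sequence pairs (references ≤ 2 kb) against a quadratic
scan-based parser oracle, 200 small tuple collections against an
exhaustive maximal-weight oracle, 1000 random model configurations for
coder invertibility, and a 1 Mb × 100-sequence diploid-style panel (0.1%
SNP + 0.01% indel) for the second-level benefit and scaling measurements,
with a 20 kb × 100-sequence panel for the random-access bound. These sizes
were chosen so the full pipeline, including its brute-force oracles, is
exercised at meaningful scale on a single CPU.
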