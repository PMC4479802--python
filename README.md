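# refcoll

Lossless referential compression of collections of same-species genomes,
with random access to individual sequences.

Resequencing projects store thousands of genomes that differ from a
reference — and from each other — only by SNPs, short indels and occasional
structural variants. `refcoll` exploits both layers of redundancy with a
two-level Ziv–Lempel scheme followed by contextual arithmetic coding:

1. **First level (sequence vs reference).** Each collection sequence
   S<sup>k</sup> is LZSS-factored against the reference R into a tuple
   stream L<sup>k</sup> of literals and matches `(pos, len)`, found through
   a k-mer hash table over R (seed length h<sub>1m</sub> = 15). Right after
   any match the parser probes the continuation a variant would leave —
   substitution, 1–2 bp insertion or deletion — and accepts resumed matches
   as short as h<sub>1e</sub> = 4, because their position is exactly
   predictable and near-free to encode.
2. **Second level (tuple stream vs earlier streams).** Genomes that share
   variants produce identical *runs of tuples*. Each L<sup>k</sup> is
   factored against all previously processed streams: a run whose weight
   (literal = 1, match = 7) reaches h<sub>2</sub> = 11 is replaced by a
   single reference `(sequence id, tuple position, tuple count)`.
3. **Entropy coding.** The resulting streams are compressed with an
   adaptive binary range coder. Match positions at both levels are
   predicted from context (previous match end plus symbols coded since; a
   per-referenced-stream position/symbol ledger at level two) and only the
   class of the residual plus a few payload bytes are coded, each field in
   its own context model.

An archive is three files: `<prefix>.gdc2_desc` (zlib-compressed metadata),
`<prefix>.gdc2_rc` (the coded collection) and `<prefix>.gdc2_ref` (the
coded reference). Decompression is self-contained and byte-exact; a
`ref_fraction` < 1 restricts which sequences may serve as second-level
references, bounding how much must be decoded to extract one sequence.

## Worked example

```sh
$ refcoll synth --length 200000 --n 20 --diploid --seed 7 -o demo
$ refcoll compress -r demo/reference.fa -o demo/arch demo/collection.fa
20 sequences, 4066946 raw bytes -> 5076 bytes (ratio 801.2)
$ refcoll info demo/arch
parameters: {'h1m': 15, 'h1e': 4, 'h2': 11, 'indel2': False, 'ref_fraction': 1.0, 'match_weight': 7}
sequences:  20
streams:    desc=236  rc=4840  ref=50438
raw bytes:  4066946
ratio:      801.21  (raw / (desc + rc))
...
$ refcoll extract -s seq_0003_h1 demo/arch | head -2
>seq_0003_h1
TGGTGTTAACCTTACTATACTCCCGCTCCGGGGTTTGGCTCATATGAACAAGTCTTTGCG...
```

The synthetic panel holds 10 diploid individuals (20 haplotypes, 200 kb
each) at 0.1% SNP and 0.01% indel divergence. The 20 sequences (4.1 MB of
FASTA) compress to 5.1 kB of archive payload — a ratio of about 800 —
because later haplotypes are encoded almost entirely as second-level
copies of earlier ones. The ratio counts `desc + rc` only; the coded
reference (50 kB here) is stored for self-containment but is not part of
the collection. `refcoll decompress -o out demo/arch` reproduces
`collection.fa` byte-for-byte.

The same functionality is available as a library:

```python
import refcoll as rc

ref = rc.generate_reference(200_000, seed=7)
profile = rc.DivergenceProfile(snp_rate=0.001, indel_rate=0.0001, seed=8)
records = rc.generate_collection(ref, 20, profile, diploid=True)

idx = rc.ReferenceIndex(ref, k=15)
l1 = rc.factor_sequence(records[0].data, idx, h1e=4)
assert rc.reconstruct_sequence(l1, ref) == records[0].data
```

## Layout

- `src/refcoll/sequence_io.py` — multi-FASTA I/O and collection metadata
- `src/refcoll/reference_index.py` — k-mer hash table over the reference
- `src/refcoll/first_level.py` — LZSS factoring with variant-tolerant
  short-match extension
- `src/refcoll/second_level.py` — weighted tuple-run factoring across
  sequences
- `src/refcoll/rangecoder.py`, `src/refcoll/collection_codec.py` — range
  coder, context models, position predictors, stream format
- `src/refcoll/archive.py` — three-file container, decompression, random
  access
- `src/refcoll/synthetic.py` — synthetic references and collections
- `docs/methods.md` — models, parameters and design notes
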