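# Methods

## Problem and approach

High-throughput sequencing pipelines produce two large artifacts: the
reads themselves and their alignments against a reference genome.  Both
are highly structured — an alignment record is a bundle of small integers,
flags, short strings and cross-references — yet the dominant storage
formats compress them as undifferentiated byte streams.  This package
stores reads and alignments as typed records in a chunked container and
compresses alignment chunks with a schema-aware *hybrid* codec that
exploits four sources of redundancy general-purpose compressors cannot
see:

1. **Separate field encoding.**  A chunk of up to K records is transposed
   into one value list per field before entropy coding.  Successive values
   of one field are far more regular than interleaved records: most lists
   collapse under run-length coding or compress close to their empirical
   entropy under the adaptive arithmetic coder.
2. **Field modeling.**  Where one field is approximately a function of
   others, only the residual is stored: genomic positions as successive
   deltas (small and non-negative in sorted files), the query-aligned
   length against the read length (zero without clipping), the
   target-aligned length against the query-aligned length (zero without
   indels or introns), and a variation's read index against its reference
   offset (constant without upstream indels or clips).
3. **Template compression.**  After setting aside the three fields that
   change with every record — query index, position, and per-base mapped
   qualities — consecutive records are frequently byte-identical
   (duplicate reads, repetitive library structure).  Each run of equal
   *templates* is stored once with its repetition count: run-length
   encoding generalized to whole structured records.  The template state
   resets at chunk boundaries so chunks stay independently decodable.
4. **Domain link modeling.**  Mate-pair and splice links name their target
   by a (position, target, fragment) triple.  Inside a chunk the same
   information fits in a small signed entry offset; the triple is
   reconstructed from the linked entry at decode time.  Links that leave
   the chunk, or whose triple is ambiguous within it, stay explicit —
   losslessness always wins over compression.

The three hybrid configurations are labelled **H** (transposition +
modeling only), **H+T** (plus templates) and **H+T+D** (plus link
modeling).  Whole-chunk gzip and bzip2 codecs provide the general-purpose
baseline and serve read (Tier I) containers, where field structure is
dominated by incompressible base and quality strings.

## Schema evolution

Records use a tag–length–value serialization (docs/FORMAT.md §2): any
field tag a codec version does not recognise is carved verbatim into an
opaque per-record buffer.  The hybrid codec routes those buffers into a
separately gzip-compressed *Left-Over stream*, keyed by chunk ordinal, and
reattaches them on decode.  Data written by newer schema versions
therefore survives a compress/decompress cycle under older software
byte-identically — the property that rigid binary formats lack.  This is
the codec's hard contract and the fidelity suite exercises it directly.

## Coders and numerical choices

* The arithmetic coder is a 32-bit integer interval coder with
  underflow-bit (pending) handling.  The adaptive model starts every
  symbol count at 1, increments after each coded symbol, and halves
  (floored at 1) when the total exceeds max(2^16, 2n).  The 2n term
  matters only for alphabets larger than the base threshold — columns of
  near-unique values such as explicit link positions — where a fixed
  threshold would force a full O(n) rescale on every symbol; with it,
  rescaling stays amortized constant-time.  These constants, the exact
  interval arithmetic and the bit order are normative (docs/FORMAT.md §3)
  because the on-disk format depends on them; a deliberately plain,
  independently written reference coder lives in the test suite and the
  production coder must match it bit for bit.
* Decoding resolves a symbol in O(log n) by Fenwick-tree descent over the
  cumulative counts, so large alphabets (byte columns, n = 256) decode at
  the same asymptotic cost as small ones.
* Integer lists hold arbitrary Python integers; negatives are folded by
  the zigzag bijection (0,−1,1,−2,… → 0,1,2,3,…), which keeps small
  magnitudes small.  Floats are stored as their binary32 bit patterns, so
  the round trip is bit-exact, including signed zeros and infinities.
* The run-length decision is the exact rule "use runs iff the two run
  lists are shorter than the input", applied recursively to the run lists
  themselves; recursion terminates because each level is strictly shorter.
* Query-index columns use minimal binary coding after rebasing by the list
  minimum — the optimal code under the uniform distribution that sorting
  induces on read identities.  Tier III can additionally permute original
  indices to a dense 0..n range in genomic order, shrinking the coded
  width; the `.perm` block map inverts the permutation without touching
  Tier II.
* Empty chunks, empty lists, single-symbol alphabets and chunks of one
  record are all legal and covered by tests; ties in the link-ambiguity
  check fall back to the explicit triple.

## Containers and random access

Chunks are framed with an 8×0xFF delimiter, a codec registration byte, a
length and a CRC-32 (docs/FORMAT.md §1).  Semi-random access scans from
any byte offset to the next verifiable frame; CRC plus decode verification
rejects delimiter look-alikes inside payloads, and the scanner resumes
past false positives.  The default chunk size K = 100,000 records trades
compression (larger chunks amortize model adaptation and symbol tables)
against seek granularity; K is a writer option, not a format constant.

## SAM/FASTQ boundary

Import decomposes each mapped record's CIGAR and MD tag into typed
sequence-variation records (mismatch, insertion, deletion), converts
1-based SAM coordinates to the internal 0-based convention, and optionally
preserves soft clips with their qualities and the full mapped quality
string.  Export reconstructs CIGAR, MD and (given the reference) SEQ.
Read names are deliberately not preserved: identity is the integer query
index, and names are re-synthesized as `q<index>`.  The covered fidelity
surface is: flag strand/pair bits, position, mapping quality, CIGAR, MD,
SEQ/QUAL (per the preservation options), and mate position.  Variation
`read_index` counts 1-based within the read *as aligned* (clips included);
for reverse-strand alignments this indexes the reverse-complemented read —
a documented simplification that keeps import/export exactly involutive.
Unmapped reads live only in Tier I; reads exceeding a caller-supplied
ambiguity threshold are listed in `.tmh` and excluded from entries.

## Synthetic fixtures

The generators emulate the record-level statistics of four assay
families, with class presets chosen to mirror their qualitative character:

| class | paired | spliced | per-base substitution | duplicates |
|---|---|---|---|---|
| rnaseq | yes | 15% of reads | 1% | 25% |
| exome | yes | no | 0.5% | 15% |
| wgs | yes | no | 0.2% | 5% |
| rrbs | no | no | 12% (bisulfite conversion) | 35% |

Read length is 100, four reference targets of 1 Mb (i.i.d. bases —
adequate because the codecs see record structure, never reference
biology), insert sizes ~N(200, 30), indel rate 0.05–0.1% and soft-clip
rate 2–5% by class.  Duplicate runs are geometric with mean ≈ 3.  All
randomness flows from a single seeded generator over integer-valued paths,
so a spec plus seed reproduces byte-identical collections on any platform.

What the fixtures do **not** model: realistic quality-score correlation
(qualities are i.i.d. over a 21-symbol range), coverage hot-spots, strand
bias, reference repeats, or aligner-specific tag inventories.  Passing the
fidelity suite therefore demonstrates lossless handling of the record
*structure* real data exercises — including links, clips, indels and
schema-evolution payloads — but measured compression ratios are
fixture-relative: they stand in for, and do not reproduce, ratios on the
published benchmark datasets, which would require downloading those
accessions.

## Problem sizes and thresholds

The fidelity regression runs every codec over 100,000-entry collections of
each class; the ratio regression asserts, on the default sorted paired
spliced fixture at the same size, that H+T+D ≤ 60% of the bzip2 chunk
codec with the ordering H+T+D ≤ H+T ≤ H.  The 60% bound deliberately
relaxes the roughly 45% average the method family achieves on real data,
allowing for implementation and fixture variance while still catching any
regression that erodes the hybrid codec's advantage.  The acceptance
script uses 20,000–30,000-entry collections per class for its secondary
probes and the full 100,000 for the headline ratio.

## Known limitations

* The container framing is self-defined; it does not read or write the
  file format of the original Java implementation of this compression
  scheme, nor CRAM/BAM containers (SAM text is the interchange boundary).
* The hybrid codec is implemented for the alignment schema only; read
  chunks use the general codecs.
* Spliced reads are represented as linked fragments natively, but the SAM
  exporter emits one record per fragment without an N-op CIGAR merge.
* `score` export to SAM's integer `AS` tag truncates non-integral scores;
  the native container preserves the full binary32 value.
* The `.perm` map loads block-structured JSON; lookups touch one block but
  the file is read whole — adequate at desk scale, not for billion-read
  archives.
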