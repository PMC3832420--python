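# actpack

Schema-aware lossless compression of high-throughput sequencing reads and
alignments, for people who build or operate sequencing pipelines and need
alignment storage that is both much smaller than general-purpose
compression and safely extensible as data schemas evolve.

Alignment records are typed structures — positions, lengths, flags,
sequence variations, mate and splice links — stored here in chunked
containers (up to K = 100,000 records per chunk) behind pluggable codecs.
Besides whole-chunk gzip/bzip2, the package provides a hybrid codec whose
ACT stream (**A**rithmetic **C**oding and **T**emplate) compresses each
chunk by:

* transposing records into per-field value lists and entropy-coding each
  list with run-length coding plus an adaptive arithmetic coder
  (uniformly distributed query indices get minimal binary coding instead);
* storing modeled fields as residuals (position deltas, aligned-length
  differences);
* run-length encoding whole record *templates* — records identical after
  removing the fast-changing fields (query index, position, mapped
  qualities) — as template + repeat count (**+T**);
* replacing intra-chunk mate/splice link triples (position, target,
  fragment) by a small signed entry offset (**+D**).

Fields a codec version does not recognise travel through a separately
compressed Left-Over stream byte-verbatim, so files written by newer
schema versions survive older software — the schema-evolution guarantee
that rigid binary formats lack.  Round-trip fidelity is the contract:
decompressed entries are field-identical to the input, unknown fields
included, under every codec.

Data is organized in tiers: reads (`.compact-reads`, Tier I), stand-alone
alignments (`.entries`/`.header`/`.index`/`.tmh`, Tier II), and the
query-index permutation linking alignments back to reads (`.perm`,
Tier III).  SAM and FASTQ are the interchange boundary: import decomposes
CIGAR/MD strings into typed sequence-variation records; export
reconstructs them.  Byte layouts are specified in
[docs/FORMAT.md](docs/FORMAT.md), the scientific background and design
choices in [docs/methods.md](docs/methods.md).

## Worked example

Generate a deterministic synthetic RNA-Seq-like SAM file, import it, and
compare codecs:

```sh
$ actpack fixtures /tmp/fx --fixture-class rnaseq --n-entries 10000 \
      --seed 7 --format sam
INFO wrote /tmp/fx.sam and /tmp/fx.fa

$ actpack sam-to-compact /tmp/fx.sam /tmp/fx --codec gzip
INFO imported 10000 entries (4 targets) -> /tmp/fx.entries, /tmp/fx.header

$ actpack recompress /tmp/fx /tmp/fx_htd --codec hybrid-1
INFO recompressed 10000 entries with hybrid-1 -> /tmp/fx_htd.entries

$ actpack --quiet benchmark --fixture-class rnaseq --n-entries 10000 --seed 7
{
  "fixture": "rnaseq",
  "n_entries": 10000,
  "seed": 7,
  "results": {
    "bzip2": { "bytes": 104151, "ratio_vs_bzip2": 100.0 },
    "H":     { "bytes": 88848,  "ratio_vs_bzip2": 85.31 },
    "H+T":   { "bytes": 86559,  "ratio_vs_bzip2": 83.11 },
    "H+T+D": { "bytes": 58759,  "ratio_vs_bzip2": 56.42 }
  }
}
```

The ratio column is size(method)/size(bzip2) as a percentage, so H+T+D
stores this fixture in about 56% of the space the bzip2 chunk codec
needs.  `actpack stats /tmp/fx_htd` decodes every chunk and
reports entry counts and per-field presence — the same full-decode pass
doubles as the fidelity check.

Library use mirrors the CLI:

```python
from actpack.storage_protocol import default_registry, write_collection, read_collection
from actpack.synthetic_fixtures import fixture_spec, generate_alignment_fixture

entries, reference, header = generate_alignment_fixture(
    fixture_spec("exome", 50_000, seed=1))
codec = default_registry().create_by_name("hybrid-1", template=True, domain=True)
container = write_collection(entries, codec)
assert read_collection(container) == entries  # lossless, field for field
```

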