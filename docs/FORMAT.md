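# Container and codec format specification

This file is normative: two independent implementations following it must
produce byte-identical containers.  All multi-byte integers are big-endian
unless stated otherwise.  Bit streams are written most-significant-bit
first within each byte and flushed with zero padding to a byte boundary.

## 1. Container framing

A container is a sequence of *frames* followed by a *termination chunk*:

```
frame        := delimiter code-byte payload-length payload crc32
delimiter    := 0xFF x 8
code-byte    := registration code + 1          (one byte; 0 is reserved)
payload-length := 4-byte big-endian byte count of payload
crc32        := CRC-32 of payload, 4-byte big-endian
termination  := delimiter 0x00 x 4             (immediately before EOF)
```

The code byte stores the codec registration code **plus one** so a frame
header can never begin with the four zero bytes that mark termination.
Registration codes: `0` gzip, `1` bzip2, `2` hybrid-1; codes 3–127 are
reserved for future standard codecs, 128–253 for private use.

Payloads may contain bytes that mimic the delimiter.  A reader entering at
an arbitrary offset scans for the delimiter and verifies each candidate
frame (length in range, CRC match, payload decodes under the registered
codec); any failure marks a false positive and scanning resumes one byte
past the candidate delimiter.  A structurally valid frame whose code is
unregistered is a hard error, never silently skipped.

Concatenating the frame regions of two containers (dropping the first
termination) yields a valid container holding both collections in order.

This framing is self-consistent but **not** interoperable with containers
produced by other tools in this problem domain.

## 2. Record serialization (tag–length–value)

Records are serialized as a sequence of fields.  Each field starts with a
varint key `(tag << 3) | wire_type`.  Varints are unsigned LEB128
(little-endian 7-bit groups, high bit = continuation).  Wire types:

| wire type | payload |
|---|---|
| 0 | varint |
| 2 | varint length, then that many bytes |
| 5 | 4 bytes (IEEE-754 binary32, little-endian) |

Fields at their default value (zero / empty / absent) are omitted.  A
parser must preserve any field whose tag it does not recognise — key bytes
included, order preserved — in the record's *unknown-fields* buffer, and a
writer must re-emit that buffer verbatim after the known fields.  Signed
values are zigzag-folded before varint coding: `0,-1,1,-2,… → 0,1,2,3,…`.

### Alignment entry tags

| tag | field | type |
|---|---|---|
| 1 | query_index | varint |
| 2 | target_index | varint |
| 3 | position (0-based) | varint |
| 4 | fragment_index | varint |
| 5 | matching_reverse_strand | varint 0/1 |
| 6 | query_length | varint |
| 7 | query_aligned_length | varint |
| 8 | target_aligned_length | varint |
| 9 | mapping_quality | varint |
| 10 | score | fixed32 |
| 11 | sequence_variation (repeated) | message |
| 12 | pair_link | message |
| 13 | splice_forward_link | message |
| 14 | splice_backward_link | message |
| 15 | softclip_left bases | bytes |
| 16 | softclip_right bases | bytes |
| 17 | softclip_left qualities | bytes |
| 18 | softclip_right qualities | bytes |
| 19 | to_quality (aligned-base qualities) | bytes |
| 20 | read_origin_index | varint |

Sequence variation: `1` position (offset from entry position, varint),
`2` read_index (1-based within the read as aligned, clips included,
varint), `3` from-bases, `4` to-bases, `5` to-qualities (bytes).  Empty
`from` = insertion, empty `to` = deletion.

Entry link: triple form `1` position, `2` target_index, `3` fragment_index
(varints) — or delta form `4` signed entry offset (zigzag varint).

Read entry tags: `1` query_index, `2` sequence, `3` qualities, `4`
pair_sequence, `5` pair_qualities, `6` identifier, `7` description,
`8` meta_data.

## 3. Coders

**Nibble coding** (natural numbers): pad the binary representation on the
left with zeroes to a multiple of three bits; split into 3-bit blocks; emit
each block prefixed by one flag bit, 0 for every block except the last.

**Minimal binary coding**: values rebased by the list minimum are written
at fixed width `m` = position of the most significant bit of the maximum
rebased value (minimum 1).

**Adaptive arithmetic coding** (normative algorithm):

* Model: one count per symbol, all initialised to 1.  After coding a
  symbol its count is incremented by 1.  When the total exceeds
  `max(2^16, 2n)` every count is halved, floored at 1 (the `2n` term keeps
  rescaling amortized constant-time for alphabets above the threshold).
* Coder: 32-bit integer interval `[low, high]`, initially
  `[0, 2^32 - 1]`.  For a symbol with cumulative range `[c_lo, c_hi)` of
  total `T`: `high = low + span*c_hi//T - 1`, `low = low + span*c_lo//T`
  with `span = high - low + 1`.  Renormalise while the interval lies in
  one half (emit the half bit, then any pending underflow bits inverted)
  or in the middle half (`[1/4, 3/4)`: increment the pending counter);
  after each case shift `low <<= 1`, `high = (high << 1) | 1`.
  Finalisation (only for non-empty symbol lists): increment pending, then
  emit 0 if `low < 1/4·2^32` else 1, followed by the pending inverted bits.
* Decoder: initialise `value` from the first 32 payload bits (zero-padded
  past the end), mirror the interval updates, and recover each symbol as
  the largest `s` with `cum(s) <= ((value-low+1)*T - 1) // span`.
* Framing: each arithmetic payload is preceded by its exact bit length,
  nibble-coded, so consecutive codes can share one bit stream.

## 4. List encodings

**Integer list** — one leading flag bit records the run-length decision.
The run decomposition (`lengths[i]` = run length of `run_values[i]`) is
used iff `len(lengths) + len(run_values) < len(values)`; both lists are
then written recursively in that order.  Otherwise the plain layout
follows: element count (nibble) · **if count > 0**: sign bit (1 iff any
value negative) · distinct-symbol count (nibble) · each distinct value in
first-appearance order (nibble; zigzag-folded when the sign bit is 1) ·
arithmetic-coded symbol indices over the distinct-symbol alphabet.

**Uniform integer list** (query indices): element count (nibble) · **if
count > 0**: minimum value (nibble) · width m (nibble) · each value minus
the minimum at fixed width m.

**Byte-string / string list**: the lengths as one integer list, then for
each column position `c` (up to the maximum length) one integer list with
the byte at position `c` of every string longer than `c` (ragged
transpose).  **Boolean list**: 0/1 integer list.  **Float list**: IEEE-754
binary32 bit patterns as an integer list.

## 5. Hybrid (ACT) chunk payload

```
payload      := flags act-stream
flags        := 1 byte (bit0 = template compression, bit1 = domain opts)
act-stream   := one bit stream holding, in order:
  entry count                        nibble
  query_index column                 uniform integer list
  position column                    integer list of successive deltas
  to_quality presence                boolean list
  to_quality values (present only)   byte-string list
  [if template] run counts           integer list
  template-field columns             over runs (template) or entries
  left-over ordinals                 integer list
  left-over blob length (bytes)      nibble
  left-over blob                     raw bytes (gzip of varint-length-
                                     prefixed unknown-field buffers)
```

Template-field columns, in order: target_index · fragment_index ·
reverse-strand (bool) · query_length · `query_length −
query_aligned_length` residual · `target_aligned_length −
query_aligned_length` residual · mapping_quality · score (float list) ·
variation count · variation position · variation `read_index − position −
1` residual · variation from (string list) · variation to (string list) ·
variation to-qualities (presence bool list + byte-string list) · pair,
splice-forward and splice-backward links · soft-clip left/right bases
(presence + string list) and qualities (presence + byte-string list) ·
read-origin presence (bool list) + values (integer list).

A link column set is: presence (0/1 integer list) · delta-form flags
(boolean list over present links) · deltas (integer list) · positions ·
target indices · fragment indices (integer lists over explicit links).

The field-modeling inventory (position deltas, the two aligned-length
residuals, the variation read-index residual) is part of this format
version; changing it is a format change.

Template identity is byte equality of the serialized record after removing
tags 1, 3 and 19 (query index, position, to_quality) and the unknown-field
buffer; the template run state resets at every chunk boundary.  Link
deltas count entries within the chunk (`delta = j - i`); only links whose
triple matches exactly one entry of the chunk are rewritten.

## 6. Tier files

| extension | content |
|---|---|
| `.compact-reads` | container of read entries (gzip/bzip2 codec) |
| `.entries` | container of alignment entries (any registered codec) |
| `.header` | JSON: target names/lengths, query count, flags, version |
| `.index` | JSON: (target, position) keys + byte offset per chunk, max span |
| `.tmh` | JSON list of query indices with too many hits |
| `.perm` | JSON: block size + blocks of original query indices in small-index order |
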