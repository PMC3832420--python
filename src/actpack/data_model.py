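"""Structured record schema for reads and alignments, with schema evolution.

Records are plain dataclasses serialized with a self-describing
tag-length-value wire format (documented in ``docs/FORMAT.md``): each field
is written as a varint key ``(tag << 3) | wire_type`` followed by a varint
value, a fixed 32-bit word, or a length-prefixed byte string.  A parser
built against this schema version carves any key it does not recognise —
byte-verbatim, key included — into the record's ``unknown_fields`` buffer,
and every codec in the package carries that buffer through compression
untouched.  Newer schema versions can therefore add fields without older
software erasing them.

Coordinates are 0-based half-open throughout; SAM import/export converts
from/to SAM's 1-based convention at the boundary.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

__all__ = [
    "SequenceVariation",
    "EntryLink",
    "AlignmentEntry",
    "ReadEntry",
    "AlignmentHeader",
    "serialize_entry",
    "parse_entry",
    "serialize_read",
    "parse_read",
    "set_unknown_field",
    "make_unknown_payload",
    "validate_entry",
    "zigzag_encode",
    "zigzag_decode",
]

# Wire types
_VARINT = 0
_BYTES = 2
_FIXED32 = 5


def zigzag_encode(v: int) -> int:
    """Bijection folding signed integers onto naturals: 0,-1,1,-2 -> 0,1,2,3."""
    return 2 * v if v >= 0 else -2 * v - 1


def zigzag_decode(z: int) -> int:
    return z // 2 if z % 2 == 0 else -(z + 1) // 2


def _write_varint(buf: bytearray, v: int) -> None:
    while v >= 0x80:
        buf.append((v & 0x7F) | 0x80)
        v >>= 7
    buf.append(v)


def _read_varint(data: bytes, pos: int) -> Tuple[int, int]:
    shift = 0
    value = 0
    while True:
        if pos >= len(data):
            raise ValueError("truncated varint")
        b = data[pos]
        pos += 1
        value |= (b & 0x7F) << shift
        if not b & 0x80:
            return value, pos
        shift += 7


def _write_field_varint(buf: bytearray, tag: int, v: int) -> None:
    _write_varint(buf, (tag << 3) | _VARINT)
    _write_varint(buf, v)


def _write_field_bytes(buf: bytearray, tag: int, payload: bytes) -> None:
    _write_varint(buf, (tag << 3) | _BYTES)
    _write_varint(buf, len(payload))
    buf += payload


def _write_field_fixed32(buf: bytearray, tag: int, word: bytes) -> None:
    _write_varint(buf, (tag << 3) | _FIXED32)
    buf += word


def _iter_fields(data: bytes):
    """Yield (tag, wire_type, payload, raw_span) for each field."""
    pos = 0
    n = len(data)
    while pos < n:
        start = pos
        key, pos = _read_varint(data, pos)
        tag, wt = key >> 3, key & 0x7
        if wt == _VARINT:
            value, pos = _read_varint(data, pos)
            yield tag, wt, value, data[start:pos]
        elif wt == _BYTES:
            length, pos = _read_varint(data, pos)
            if pos + length > n:
                raise ValueError("truncated length-delimited field")
            yield tag, wt, data[pos : pos + length], data[start : pos + length]
            pos += length
        elif wt == _FIXED32:
            if pos + 4 > n:
                raise ValueError("truncated fixed32 field")
            yield tag, wt, data[pos : pos + 4], data[start : pos + 4]
            pos += 4
        else:
            raise ValueError(f"unsupported wire type {wt}")


# ---------------------------------------------------------------------------
# Records


@dataclass(eq=True)
class SequenceVariation:
    """One difference between the read and the reference.

    ``position`` is reference-relative within the alignment (0-based offset
    from the entry position); ``read_index`` is the 1-based position within
    the read as aligned (reference orientation, clipped bases included).
    ``from_bases`` empty means an insertion into the read; ``to_bases``
    empty means a deletion.
    """

    position: int = 0
    read_index: int = 0
    from_bases: str = ""
    to_bases: str = ""
    to_qualities: Optional[bytes] = None


@dataclass(eq=True)
class EntryLink:
    """Reference to another alignment entry (mate or splice neighbour).

    Exactly one representation is active: the explicit ``(position,
    target_index, fragment_index)`` triple, or — inside a chunk, after link
    optimization — a signed ``delta`` counting how many entries up- or
    downstream the linked entry sits.
    """

    position: Optional[int] = None
    target_index: Optional[int] = None
    fragment_index: Optional[int] = None
    delta: Optional[int] = None

    @property
    def is_delta(self) -> bool:
        return self.delta is not None

    def triple(self) -> Tuple[int, int, int]:
        if self.is_delta:
            raise ValueError("link is in delta form")
        return (self.position, self.target_index, self.fragment_index)


@dataclass(eq=True)
class AlignmentEntry:
    """How one segment of a read aligns against the reference genome."""

    query_index: int = 0
    target_index: int = 0
    position: int = 0
    fragment_index: int = 0
    matching_reverse_strand: bool = False
    query_length: int = 0
    query_aligned_length: int = 0
    target_aligned_length: int = 0
    mapping_quality: int = 0
    score: float = 0.0
    sequence_variations: List[SequenceVariation] = field(default_factory=list)
    pair_link: Optional[EntryLink] = None
    splice_forward_link: Optional[EntryLink] = None
    splice_backward_link: Optional[EntryLink] = None
    softclip_left: Optional[str] = None
    softclip_right: Optional[str] = None
    softclip_left_quals: Optional[bytes] = None
    softclip_right_quals: Optional[bytes] = None
    to_quality: Optional[bytes] = None
    read_origin_index: Optional[int] = None
    unknown_fields: bytes = b""


@dataclass(eq=True)
class ReadEntry:
    """One sequenced read (Tier I), identified by its query index."""

    query_index: int = 0
    sequence: str = ""
    qualities: Optional[bytes] = None
    pair_sequence: Optional[str] = None
    pair_qualities: Optional[bytes] = None
    identifier: Optional[str] = None
    description: Optional[str] = None
    meta_data: Optional[str] = None
    unknown_fields: bytes = b""


@dataclass(eq=True)
class AlignmentHeader:
    """Global information about an alignment collection (.header file)."""

    target_names: List[str] = field(default_factory=list)
    target_lengths: List[int] = field(default_factory=list)
    n_queries: int = 0
    sorted: bool = False
    query_indices_permuted: bool = False
    read_origin_infos: List[dict] = field(default_factory=list)
    version: int = 1

    @property
    def n_targets(self) -> int:
        return len(self.target_names)


# ---------------------------------------------------------------------------
# Field tags (the documented contract; see docs/FORMAT.md)

_SV_POSITION = 1
_SV_READ_INDEX = 2
_SV_FROM = 3
_SV_TO = 4
_SV_TO_QUALS = 5

_LINK_POSITION = 1
_LINK_TARGET = 2
_LINK_FRAGMENT = 3
_LINK_DELTA = 4

_AE_QUERY_INDEX = 1
_AE_TARGET_INDEX = 2
_AE_POSITION = 3
_AE_FRAGMENT_INDEX = 4
_AE_REVERSE = 5
_AE_QUERY_LENGTH = 6
_AE_QUERY_ALIGNED = 7
_AE_TARGET_ALIGNED = 8
_AE_MAPQ = 9
_AE_SCORE = 10
_AE_VARIATION = 11
_AE_PAIR_LINK = 12
_AE_SPLICE_FWD = 13
_AE_SPLICE_BWD = 14
_AE_CLIP_LEFT = 15
_AE_CLIP_RIGHT = 16
_AE_CLIP_LEFT_Q = 17
_AE_CLIP_RIGHT_Q = 18
_AE_TO_QUALITY = 19
_AE_READ_ORIGIN = 20

_ENTRY_KNOWN_TAGS = frozenset(range(1, 21))

_RE_QUERY_INDEX = 1
_RE_SEQUENCE = 2
_RE_QUALITIES = 3
_RE_PAIR_SEQUENCE = 4
_RE_PAIR_QUALITIES = 5
_RE_IDENTIFIER = 6
_RE_DESCRIPTION = 7
_RE_META = 8

_READ_KNOWN_TAGS = frozenset(range(1, 9))


def _ser_variation(v: SequenceVariation) -> bytes:
    buf = bytearray()
    if v.position:
        _write_field_varint(buf, _SV_POSITION, v.position)
    if v.read_index:
        _write_field_varint(buf, _SV_READ_INDEX, v.read_index)
    if v.from_bases:
        _write_field_bytes(buf, _SV_FROM, v.from_bases.encode("ascii"))
    if v.to_bases:
        _write_field_bytes(buf, _SV_TO, v.to_bases.encode("ascii"))
    if v.to_qualities is not None:
        _write_field_bytes(buf, _SV_TO_QUALS, v.to_qualities)
    return bytes(buf)


def _parse_variation(data: bytes) -> SequenceVariation:
    v = SequenceVariation()
    for tag, wt, payload, _raw in _iter_fields(data):
        if tag == _SV_POSITION:
            v.position = payload
        elif tag == _SV_READ_INDEX:
            v.read_index = payload
        elif tag == _SV_FROM:
            v.from_bases = payload.decode("ascii")
        elif tag == _SV_TO:
            v.to_bases = payload.decode("ascii")
        elif tag == _SV_TO_QUALS:
            v.to_qualities = bytes(payload)
    return v


def _ser_link(link: EntryLink) -> bytes:
    buf = bytearray()
    if link.is_delta:
        _write_field_varint(buf, _LINK_DELTA, zigzag_encode(link.delta))
    else:
        if link.position:
            _write_field_varint(buf, _LINK_POSITION, link.position)
        if link.target_index:
            _write_field_varint(buf, _LINK_TARGET, link.target_index)
        if link.fragment_index:
            _write_field_varint(buf, _LINK_FRAGMENT, link.fragment_index)
    return bytes(buf)


def _parse_link(data: bytes) -> EntryLink:
    fields = {tag: payload for tag, _wt, payload, _raw in _iter_fields(data)}
    if _LINK_DELTA in fields:
        return EntryLink(delta=zigzag_decode(fields[_LINK_DELTA]))
    return EntryLink(
        position=fields.get(_LINK_POSITION, 0),
        target_index=fields.get(_LINK_TARGET, 0),
        fragment_index=fields.get(_LINK_FRAGMENT, 0),
    )


def serialize_entry(e: AlignmentEntry, *, skip: frozenset = frozenset()) -> bytes:
    """Serialize an alignment entry; ``skip`` drops field tags (template use)."""
    buf = bytearray()
    if e.query_index and _AE_QUERY_INDEX not in skip:
        _write_field_varint(buf, _AE_QUERY_INDEX, e.query_index)
    if e.target_index and _AE_TARGET_INDEX not in skip:
        _write_field_varint(buf, _AE_TARGET_INDEX, e.target_index)
    if e.position and _AE_POSITION not in skip:
        _write_field_varint(buf, _AE_POSITION, e.position)
    if e.fragment_index:
        _write_field_varint(buf, _AE_FRAGMENT_INDEX, e.fragment_index)
    if e.matching_reverse_strand:
        _write_field_varint(buf, _AE_REVERSE, 1)
    if e.query_length:
        _write_field_varint(buf, _AE_QUERY_LENGTH, e.query_length)
    if e.query_aligned_length:
        _write_field_varint(buf, _AE_QUERY_ALIGNED, e.query_aligned_length)
    if e.target_aligned_length:
        _write_field_varint(buf, _AE_TARGET_ALIGNED, e.target_aligned_length)
    if e.mapping_quality:
        _write_field_varint(buf, _AE_MAPQ, e.mapping_quality)
    if e.score != 0.0:
        _write_field_fixed32(buf, _AE_SCORE, struct.pack("<f", e.score))
    for v in e.sequence_variations:
        _write_field_bytes(buf, _AE_VARIATION, _ser_variation(v))
    if e.pair_link is not None:
        _write_field_bytes(buf, _AE_PAIR_LINK, _ser_link(e.pair_link))
    if e.splice_forward_link is not None:
        _write_field_bytes(buf, _AE_SPLICE_FWD, _ser_link(e.splice_forward_link))
    if e.splice_backward_link is not None:
        _write_field_bytes(buf, _AE_SPLICE_BWD, _ser_link(e.splice_backward_link))
    if e.softclip_left is not None:
        _write_field_bytes(buf, _AE_CLIP_LEFT, e.softclip_left.encode("ascii"))
    if e.softclip_right is not None:
        _write_field_bytes(buf, _AE_CLIP_RIGHT, e.softclip_right.encode("ascii"))
    if e.softclip_left_quals is not None:
        _write_field_bytes(buf, _AE_CLIP_LEFT_Q, e.softclip_left_quals)
    if e.softclip_right_quals is not None:
        _write_field_bytes(buf, _AE_CLIP_RIGHT_Q, e.softclip_right_quals)
    if e.to_quality is not None and _AE_TO_QUALITY not in skip:
        _write_field_bytes(buf, _AE_TO_QUALITY, e.to_quality)
    if e.read_origin_index is not None:
        _write_field_varint(buf, _AE_READ_ORIGIN, e.read_origin_index)
    buf += e.unknown_fields
    return bytes(buf)


def parse_entry(data: bytes) -> AlignmentEntry:
    e = AlignmentEntry()
    unknown = bytearray()
    for tag, wt, payload, raw in _iter_fields(data):
        if tag not in _ENTRY_KNOWN_TAGS:
            unknown += raw
            continue
        if tag == _AE_QUERY_INDEX:
            e.query_index = payload
        elif tag == _AE_TARGET_INDEX:
            e.target_index = payload
        elif tag == _AE_POSITION:
            e.position = payload
        elif tag == _AE_FRAGMENT_INDEX:
            e.fragment_index = payload
        elif tag == _AE_REVERSE:
            e.matching_reverse_strand = bool(payload)
        elif tag == _AE_QUERY_LENGTH:
            e.query_length = payload
        elif tag == _AE_QUERY_ALIGNED:
            e.query_aligned_length = payload
        elif tag == _AE_TARGET_ALIGNED:
            e.target_aligned_length = payload
        elif tag == _AE_MAPQ:
            e.mapping_quality = payload
        elif tag == _AE_SCORE:
            e.score = struct.unpack("<f", payload)[0]
        elif tag == _AE_VARIATION:
            e.sequence_variations.append(_parse_variation(payload))
        elif tag == _AE_PAIR_LINK:
            e.pair_link = _parse_link(payload)
        elif tag == _AE_SPLICE_FWD:
            e.splice_forward_link = _parse_link(payload)
        elif tag == _AE_SPLICE_BWD:
            e.splice_backward_link = _parse_link(payload)
        elif tag == _AE_CLIP_LEFT:
            e.softclip_left = payload.decode("ascii")
        elif tag == _AE_CLIP_RIGHT:
            e.softclip_right = payload.decode("ascii")
        elif tag == _AE_CLIP_LEFT_Q:
            e.softclip_left_quals = bytes(payload)
        elif tag == _AE_CLIP_RIGHT_Q:
            e.softclip_right_quals = bytes(payload)
        elif tag == _AE_TO_QUALITY:
            e.to_quality = bytes(payload)
        elif tag == _AE_READ_ORIGIN:
            e.read_origin_index = payload
    e.unknown_fields = bytes(unknown)
    return e


def serialize_read(r: ReadEntry) -> bytes:
    buf = bytearray()
    if r.query_index:
        _write_field_varint(buf, _RE_QUERY_INDEX, r.query_index)
    if r.sequence:
        _write_field_bytes(buf, _RE_SEQUENCE, r.sequence.encode("ascii"))
    if r.qualities is not None:
        _write_field_bytes(buf, _RE_QUALITIES, r.qualities)
    if r.pair_sequence is not None:
        _write_field_bytes(buf, _RE_PAIR_SEQUENCE, r.pair_sequence.encode("ascii"))
    if r.pair_qualities is not None:
        _write_field_bytes(buf, _RE_PAIR_QUALITIES, r.pair_qualities)
    if r.identifier is not None:
        _write_field_bytes(buf, _RE_IDENTIFIER, r.identifier.encode("ascii"))
    if r.description is not None:
        _write_field_bytes(buf, _RE_DESCRIPTION, r.description.encode("ascii"))
    if r.meta_data is not None:
        _write_field_bytes(buf, _RE_META, r.meta_data.encode("ascii"))
    buf += r.unknown_fields
    return bytes(buf)


def parse_read(data: bytes) -> ReadEntry:
    r = ReadEntry()
    unknown = bytearray()
    for tag, wt, payload, raw in _iter_fields(data):
        if tag not in _READ_KNOWN_TAGS:
            unknown += raw
            continue
        if tag == _RE_QUERY_INDEX:
            r.query_index = payload
        elif tag == _RE_SEQUENCE:
            r.sequence = payload.decode("ascii")
        elif tag == _RE_QUALITIES:
            r.qualities = bytes(payload)
        elif tag == _RE_PAIR_SEQUENCE:
            r.pair_sequence = payload.decode("ascii")
        elif tag == _RE_PAIR_QUALITIES:
            r.pair_qualities = bytes(payload)
        elif tag == _RE_IDENTIFIER:
            r.identifier = payload.decode("ascii")
        elif tag == _RE_DESCRIPTION:
            r.description = payload.decode("ascii")
        elif tag == _RE_META:
            r.meta_data = payload.decode("ascii")
    r.unknown_fields = bytes(unknown)
    return r


# ---------------------------------------------------------------------------
# Schema evolution and validation


def make_unknown_payload(tag: int, payload: bytes) -> bytes:
    """Build a well-formed length-delimited field with an unrecognised tag.

    Writers targeting a newer schema use this to attach data this codec
    version cannot interpret; the bytes survive every round trip verbatim.
    """
    if tag in _ENTRY_KNOWN_TAGS:
        raise ValueError(f"tag {tag} is a known field of this schema version")
    buf = bytearray()
    _write_field_bytes(buf, tag, payload)
    return bytes(buf)


def set_unknown_field(entry: AlignmentEntry, payload: bytes) -> AlignmentEntry:
    """Return a copy of ``entry`` carrying ``payload`` as opaque field data."""
    return replace(entry, unknown_fields=entry.unknown_fields + payload)


def validate_entry(entry: AlignmentEntry, header: AlignmentHeader) -> List[str]:
    """Check type invariants; returns human-readable violations (empty = ok)."""
    out: List[str] = []
    if header.n_targets and entry.target_index >= header.n_targets:
        out.append(
            f"target_index {entry.target_index} >= target count {header.n_targets}"
        )
    if entry.position < 0:
        out.append("negative position")
    for i, v in enumerate(entry.sequence_variations):
        if not v.from_bases and not v.to_bases:
            out.append(f"variation {i}: from and to both empty")
        if v.read_index > entry.query_length:
            out.append(
                f"variation {i}: read_index {v.read_index} exceeds "
                f"query_length {entry.query_length}"
            )
        if entry.target_aligned_length and v.position > entry.target_aligned_length:
            out.append(f"variation {i}: position outside aligned span")
    for name, link in (
        ("pair_link", entry.pair_link),
        ("splice_forward_link", entry.splice_forward_link),
        ("splice_backward_link", entry.splice_backward_link),
    ):
        if link is not None and not link.is_delta:
            if link.target_index is None or link.position is None:
                out.append(f"{name}: incomplete triple")
            elif header.n_targets and link.target_index >= header.n_targets:
                out.append(f"{name}: target_index out of range")
    if entry.softclip_left is not None and entry.softclip_left_quals is not None:
        if len(entry.softclip_left) != len(entry.softclip_left_quals):
            out.append("left soft-clip bases and qualities differ in length")
    if entry.softclip_right is not None and entry.softclip_right_quals is not None:
        if len(entry.softclip_right) != len(entry.softclip_right_quals):
            out.append("right soft-clip bases and qualities differ in length")
    return out
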