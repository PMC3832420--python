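"""Chunked container framing with codec registration and semi-random access.

A container is a sequence of frames followed by a termination chunk.  Each
frame is::

    delimiter (8 x 0xFF) | code byte | payload length (4 B big-endian)
    | payload | CRC-32 of payload (4 B big-endian)

The code byte stores the codec registration code **plus one** (0 is
reserved so that the termination chunk — the delimiter followed by four
0x00 bytes, written immediately before end of file — can never collide
with a real frame header).  Registered built-ins: 0 = gzip, 1 = bzip2,
2 = hybrid-1.

Because payloads may contain bytes that mimic the delimiter, a reader
positioned at an arbitrary offset scans forward for the delimiter and
verifies each candidate frame (structure, CRC, and decompressibility);
a candidate that fails verification is a false positive and scanning
resumes just past it.  This yields semi-random access: every chunk that
starts at or after the seek point is recovered.
"""

from __future__ import annotations

import bz2
import gzip
import zlib
from typing import Callable, Dict, Iterable, Iterator, List, Optional, Tuple

from actpack.act_codec import compress_chunk, decompress_chunk
from actpack.data_model import (
    AlignmentEntry,
    parse_entry,
    parse_read,
    serialize_entry,
    serialize_read,
)

__all__ = [
    "DELIMITER",
    "TERMINATION",
    "UnknownCodecError",
    "ContainerError",
    "Codec",
    "GzipCodec",
    "Bzip2Codec",
    "HybridCodec",
    "CodecRegistry",
    "default_registry",
    "compress_payload_general",
    "decompress_payload_general",
    "serialize_records",
    "parse_records",
    "write_collection",
    "read_collection",
    "scan_next_chunk",
    "iter_chunks_from",
]

DELIMITER = b"\xff" * 8
TERMINATION = DELIMITER + b"\x00" * 4


class ContainerError(Exception):
    """Malformed container (truncation, bad frame, failed decode)."""


class UnknownCodecError(ContainerError):
    """A frame names a registration code with no registered codec."""

    def __init__(self, code: int):
        super().__init__(f"no codec registered for code {code}")
        self.code = code


# ---------------------------------------------------------------------------
# Record-block serialization shared by the general codecs


def serialize_records(records: Iterable, serializer: Callable) -> bytes:
    """Concatenate varint-length-prefixed record serializations."""
    out = bytearray()
    for rec in records:
        payload = serializer(rec)
        n = len(payload)
        while n >= 0x80:
            out.append((n & 0x7F) | 0x80)
            n >>= 7
        out.append(n)
        out += payload
    return bytes(out)


def parse_records(data: bytes, parser: Callable) -> List:
    records = []
    pos = 0
    end = len(data)
    while pos < end:
        length = 0
        shift = 0
        while True:
            if pos >= end:
                raise ContainerError("truncated record block")
            b = data[pos]
            pos += 1
            length |= (b & 0x7F) << shift
            if not b & 0x80:
                break
            shift += 7
        if pos + length > end:
            raise ContainerError("truncated record in block")
        records.append(parser(data[pos : pos + length]))
        pos += length
    return records


def compress_payload_general(serialized: bytes, scheme: str) -> bytes:
    """Whole-chunk general compression of a serialized record block."""
    if scheme == "gzip":
        return gzip.compress(serialized, mtime=0)
    if scheme == "bzip2":
        return bz2.compress(serialized)
    raise ValueError(f"unknown compression scheme {scheme!r}")


def decompress_payload_general(payload: bytes, scheme: str) -> bytes:
    try:
        if scheme == "gzip":
            return gzip.decompress(payload)
        if scheme == "bzip2":
            return bz2.decompress(payload)
    except (OSError, ValueError) as exc:
        raise ContainerError(f"{scheme} payload failed to decompress") from exc
    raise ValueError(f"unknown compression scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Codecs


class Codec:
    """Pluggable chunk codec identified by a stable registration code."""

    code: int
    name: str

    def compress(self, records: List) -> bytes:
        raise NotImplementedError

    def decompress(self, payload: bytes) -> List:
        raise NotImplementedError


class _GeneralCodec(Codec):
    scheme: str

    def __init__(self, record_kind: str = "alignment"):
        if record_kind == "alignment":
            self._ser, self._par = serialize_entry, parse_entry
        elif record_kind == "read":
            self._ser, self._par = serialize_read, parse_read
        else:
            raise ValueError(f"unknown record kind {record_kind!r}")
        self.record_kind = record_kind

    def compress(self, records: List) -> bytes:
        return compress_payload_general(
            serialize_records(records, self._ser), self.scheme
        )

    def decompress(self, payload: bytes) -> List:
        return parse_records(
            decompress_payload_general(payload, self.scheme), self._par
        )


class GzipCodec(_GeneralCodec):
    code = 0
    name = "gzip"
    scheme = "gzip"


class Bzip2Codec(_GeneralCodec):
    code = 1
    name = "bzip2"
    scheme = "bzip2"


class HybridCodec(Codec):
    """Schema-aware codec for alignment chunks (H / H+T / H+T+D)."""

    code = 2
    name = "hybrid-1"

    def __init__(self, template: bool = True, domain: bool = True):
        self.template = template
        self.domain = domain

    def compress(self, records: List[AlignmentEntry]) -> bytes:
        return compress_chunk(
            records, template=self.template, domain=self.domain
        ).data

    def decompress(self, payload: bytes) -> List[AlignmentEntry]:
        # options are authoritative from the payload header
        return decompress_chunk(payload)


class CodecRegistry:
    """code -> codec-factory mapping; codes are stable across versions."""

    def __init__(self) -> None:
        self._factories: Dict[int, Callable[..., Codec]] = {}
        self._by_name: Dict[str, int] = {}

    def register(self, code: int, name: str, factory: Callable[..., Codec]) -> None:
        self._factories[code] = factory
        self._by_name[name] = code

    def create(self, code: int, **kwargs) -> Codec:
        if code not in self._factories:
            raise UnknownCodecError(code)
        return self._factories[code](**kwargs)

    def create_by_name(self, name: str, **kwargs) -> Codec:
        if name not in self._by_name:
            raise ValueError(
                f"unknown codec {name!r}; registered: {sorted(self._by_name)}"
            )
        return self.create(self._by_name[name], **kwargs)

    @property
    def names(self) -> List[str]:
        return sorted(self._by_name)


def default_registry() -> CodecRegistry:
    reg = CodecRegistry()
    reg.register(GzipCodec.code, GzipCodec.name, GzipCodec)
    reg.register(Bzip2Codec.code, Bzip2Codec.name, Bzip2Codec)
    reg.register(HybridCodec.code, HybridCodec.name, HybridCodec)
    return reg


# ---------------------------------------------------------------------------
# Container writing


def _frame(code: int, payload: bytes) -> bytes:
    if not 0 <= code <= 0xFE:
        raise ValueError("registration code out of range")
    return (
        DELIMITER
        + bytes([code + 1])
        + len(payload).to_bytes(4, "big")
        + payload
        + (zlib.crc32(payload) & 0xFFFFFFFF).to_bytes(4, "big")
    )


def write_collection(
    records: Iterable,
    codec: Codec,
    chunk_size: int = 100_000,
    sink=None,
) -> Optional[bytes]:
    """Write records as ceil(N/K) frames plus the termination chunk.

    With ``sink=None`` the container is returned as bytes; otherwise frames
    are written to the binary stream ``sink``.
    """
    if chunk_size < 1:
        raise ValueError("chunk size must be >= 1")
    own = sink is None
    chunks: List[bytes] = []

    def emit(data: bytes) -> None:
        if own:
            chunks.append(data)
        else:
            sink.write(data)

    buf: List = []
    for rec in records:
        buf.append(rec)
        if len(buf) == chunk_size:
            emit(_frame(codec.code, codec.compress(buf)))
            buf = []
    if buf:
        emit(_frame(codec.code, codec.compress(buf)))
    emit(TERMINATION)
    if own:
        return b"".join(chunks)
    return None


# ---------------------------------------------------------------------------
# Container reading / scanning


def _try_parse_frame(
    data: bytes, at: int, registry: CodecRegistry, **codec_kwargs
) -> Tuple[Optional[List], int, bool]:
    """Attempt to parse the frame whose delimiter starts at ``at``.

    Returns ``(records, next_offset, is_termination)``; ``records`` is None
    when the candidate is a false positive.  Raises
    :class:`UnknownCodecError` for a structurally valid frame whose code is
    unregistered (never skips data silently).
    """
    body = at + len(DELIMITER)
    if data[body : body + 4] == b"\x00\x00\x00\x00":
        return None, body + 4, True
    if body + 5 > len(data):
        return None, len(data), False
    disk_code = data[body]
    if disk_code == 0:
        return None, at + 1, False  # truncated termination lookalike
    code = disk_code - 1
    length = int.from_bytes(data[body + 1 : body + 5], "big")
    payload_start = body + 5
    payload_end = payload_start + length
    if payload_end + 4 > len(data):
        return None, at + 1, False
    payload = data[payload_start:payload_end]
    crc = int.from_bytes(data[payload_end : payload_end + 4], "big")
    if (zlib.crc32(payload) & 0xFFFFFFFF) != crc:
        return None, at + 1, False
    codec = registry.create(code, **codec_kwargs)
    try:
        records = codec.decompress(payload)
    except Exception:
        # a frame with a valid CRC that fails to decode: false positive
        return None, at + 1, False
    return records, payload_end + 4, False


def scan_next_chunk(
    data: bytes,
    start_offset: int,
    registry: Optional[CodecRegistry] = None,
    **codec_kwargs,
) -> Tuple[Optional[List], int]:
    """Find and decode the first verifiable chunk at or after an offset.

    Returns ``(records, next_offset)``; ``records`` is ``None`` when only
    the termination chunk (or end of data) remains.  False-positive
    delimiters inside payloads are detected by frame verification and
    skipped.
    """
    registry = registry or default_registry()
    pos = start_offset
    while True:
        at = data.find(DELIMITER, pos)
        if at < 0:
            return None, len(data)
        records, nxt, is_term = _try_parse_frame(data, at, registry, **codec_kwargs)
        if is_term:
            return None, nxt
        if records is not None:
            return records, nxt
        pos = nxt if nxt > at else at + 1


def iter_chunks_from(
    data: bytes,
    start_offset: int = 0,
    registry: Optional[CodecRegistry] = None,
    **codec_kwargs,
) -> Iterator[List]:
    """Yield every decodable chunk from ``start_offset`` to termination."""
    pos = start_offset
    while True:
        records, pos = scan_next_chunk(data, pos, registry, **codec_kwargs)
        if records is None:
            return
        yield records


def read_collection(
    data: bytes,
    registry: Optional[CodecRegistry] = None,
    **codec_kwargs,
) -> List:
    """Decode a whole container into its record list."""
    out: List = []
    for chunk in iter_chunks_from(data, 0, registry, **codec_kwargs):
        out.extend(chunk)
    return out
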