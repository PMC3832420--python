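"""Homogeneous-list codecs: integers, booleans, strings, 32-bit floats.

Every list kind reduces to integer lists.  An integer list is first
inspected for run-length encoding: when the ``lengths`` plus ``values``
lists of its run decomposition hold fewer elements than the input, both are
written (recursively) instead.  A plain integer list is written as:

    element count (nibble) · sign bit · distinct-symbol count (nibble) ·
    each distinct value (nibble, zigzag-folded when the sign bit is 1) ·
    arithmetic-coded symbol indices

One leading flag bit per list records the RLE decision.  Strings are
transposed into per-position character columns (ragged: column ``c`` holds
bytes only from strings longer than ``c``) plus a lengths list; floats are
reinterpreted as their IEEE-754 32-bit patterns.

A second integer-list layout, :func:`write_uniform_int_list`, stores values
rebased to the list minimum at fixed width — minimal binary coding, the
optimal code for uniformly distributed values such as query indices.
"""

from __future__ import annotations

import struct
from typing import List, Sequence, Tuple

from actpack.coding_primitives import (
    BitSink,
    BitSource,
    DecodeError,
    arithmetic_decode,
    arithmetic_encode,
    minimal_binary_decode,
    minimal_binary_encode,
    minimal_width,
    nibble_decode,
    nibble_encode,
)
from actpack.data_model import zigzag_decode, zigzag_encode

__all__ = [
    "rle_decide",
    "write_int_list",
    "read_int_list",
    "write_uniform_int_list",
    "read_uniform_int_list",
    "write_string_list",
    "read_string_list",
    "write_bytes_list",
    "read_bytes_list",
    "write_float_list",
    "read_float_list",
    "write_bool_list",
    "read_bool_list",
    "encode_int_list",
    "decode_int_list",
    "encode_string_list",
    "decode_string_list",
    "encode_float_list",
    "decode_float_list",
    "encode_bool_list",
    "decode_bool_list",
]


def rle_decide(values: Sequence[int]) -> Tuple[bool, List[int], List[int]]:
    """Run decomposition and the decision whether it pays off.

    Returns ``(use_rle, lengths, run_values)`` where ``lengths[i]`` is the
    run length of ``run_values[i]``; RLE is used iff the two lists together
    hold strictly fewer elements than the input.
    """
    lengths: List[int] = []
    run_values: List[int] = []
    for v in values:
        if run_values and run_values[-1] == v:
            lengths[-1] += 1
        else:
            run_values.append(v)
            lengths.append(1)
    use = len(lengths) + len(run_values) < len(values)
    return use, lengths, run_values


def _write_plain_int_list(values: Sequence[int], sink: BitSink) -> None:
    nibble_encode(len(values), sink)
    if not values:
        return
    signed = any(v < 0 for v in values)
    sink.write_bit(1 if signed else 0)
    # symbol table in first-appearance order
    table: dict = {}
    for v in values:
        if v not in table:
            table[v] = len(table)
    symbols = list(table)
    nibble_encode(len(symbols), sink)
    for v in symbols:
        nibble_encode(zigzag_encode(v) if signed else v, sink)
    indices = [table[v] for v in values]
    arithmetic_encode(indices, len(symbols), sink)


def _read_plain_int_list(source: BitSource) -> List[int]:
    count = nibble_decode(source)
    if count == 0:
        return []
    signed = source.read_bit()
    n_symbols = nibble_decode(source)
    if n_symbols == 0:
        raise DecodeError("non-empty list with empty symbol table")
    symbols = []
    for _ in range(n_symbols):
        raw = nibble_decode(source)
        symbols.append(zigzag_decode(raw) if signed else raw)
    indices = arithmetic_decode(source, count, n_symbols)
    return [symbols[i] for i in indices]


def write_int_list(values: Sequence[int], sink: BitSink) -> None:
    use_rle, lengths, run_values = rle_decide(values)
    sink.write_bit(1 if use_rle else 0)
    if use_rle:
        write_int_list(lengths, sink)
        write_int_list(run_values, sink)
    else:
        _write_plain_int_list(values, sink)


def read_int_list(source: BitSource) -> List[int]:
    if source.read_bit():
        lengths = read_int_list(source)
        run_values = read_int_list(source)
        if len(lengths) != len(run_values):
            raise DecodeError("run-length lists disagree in length")
        out: List[int] = []
        for n, v in zip(lengths, run_values):
            out.extend([v] * n)
        return out
    return _read_plain_int_list(source)


def write_uniform_int_list(values: Sequence[int], sink: BitSink) -> None:
    """Fixed-width minimal binary layout: count · min · width · values-min."""
    nibble_encode(len(values), sink)
    if not values:
        return
    lo = min(values)
    if lo < 0:
        raise ValueError("uniform layout holds natural numbers only")
    m = minimal_width(max(values) - lo)
    nibble_encode(lo, sink)
    nibble_encode(m, sink)
    for v in values:
        minimal_binary_encode(v - lo, m, sink)


def read_uniform_int_list(source: BitSource) -> List[int]:
    count = nibble_decode(source)
    if count == 0:
        return []
    lo = nibble_decode(source)
    m = nibble_decode(source)
    return [lo + minimal_binary_decode(source, m) for _ in range(count)]


def write_bytes_list(values: Sequence[bytes], sink: BitSink) -> None:
    """Byte strings via lengths list + ragged positional columns."""
    lengths = [len(v) for v in values]
    write_int_list(lengths, sink)
    if not values:
        return
    for c in range(max(lengths)):
        column = [v[c] for v in values if len(v) > c]
        write_int_list(column, sink)


def read_bytes_list(source: BitSource) -> List[bytes]:
    lengths = read_int_list(source)
    if not lengths:
        return []
    out = [bytearray() for _ in lengths]
    for c in range(max(lengths)):
        column = read_int_list(source)
        it = iter(column)
        for i, n in enumerate(lengths):
            if n > c:
                out[i].append(next(it))
    return [bytes(b) for b in out]


def write_string_list(values: Sequence[str], sink: BitSink) -> None:
    write_bytes_list([v.encode("ascii") for v in values], sink)


def read_string_list(source: BitSource) -> List[str]:
    return [b.decode("ascii") for b in read_bytes_list(source)]


def write_float_list(values: Sequence[float], sink: BitSink) -> None:
    patterns = [struct.unpack("<I", struct.pack("<f", v))[0] for v in values]
    write_int_list(patterns, sink)


def read_float_list(source: BitSource) -> List[float]:
    return [
        struct.unpack("<f", struct.pack("<I", p))[0] for p in read_int_list(source)
    ]


def write_bool_list(values: Sequence[bool], sink: BitSink) -> None:
    write_int_list([1 if v else 0 for v in values], sink)


def read_bool_list(source: BitSource) -> List[bool]:
    return [bool(v) for v in read_int_list(source)]


# ---------------------------------------------------------------------------
# Standalone byte-sequence wrappers


def _to_bytes(writer, values) -> bytes:
    sink = BitSink()
    writer(values, sink)
    return sink.to_bytes()


def encode_int_list(values: Sequence[int]) -> bytes:
    return _to_bytes(write_int_list, values)


def decode_int_list(data: bytes) -> List[int]:
    return read_int_list(BitSource(data))


def encode_string_list(values: Sequence[str]) -> bytes:
    return _to_bytes(write_string_list, values)


def decode_string_list(data: bytes) -> List[str]:
    return read_string_list(BitSource(data))


def encode_float_list(values: Sequence[float]) -> bytes:
    return _to_bytes(write_float_list, values)


def decode_float_list(data: bytes) -> List[float]:
    return read_float_list(BitSource(data))


def encode_bool_list(values: Sequence[bool]) -> bytes:
    return _to_bytes(write_bool_list, values)


def decode_bool_list(data: bytes) -> List[bool]:
    return read_bool_list(BitSource(data))
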