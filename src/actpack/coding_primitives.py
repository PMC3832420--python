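"""Bit-level I/O and the three coders every list codec builds on.

Three coders are provided:

* **Nibble coding** — a variable-length code for natural numbers.  The binary
  representation is zero-padded on the left to a multiple of three bits and
  split into 3-bit blocks; each block is written with a leading flag bit that
  is 0 for every block except the last.  Small values therefore cost 4 bits.
* **Minimal binary coding** — a fixed-width ``m``-bit code, optimal for
  uniformly distributed values once a list has been rebased to ``[0, 2^m)``.
* **Adaptive arithmetic coding** — a 32-bit arithmetic coder over an adaptive
  frequency model, near-optimal for skewed symbol distributions.  Symbol
  lookup during decoding is ``O(log n)`` in the alphabet size via a Fenwick
  tree over the symbol counts.

Bit order is most-significant-bit first within every byte; a flushed stream
is padded with zero bits up to a byte boundary.  The exact arithmetic-coder
algorithm (interval update, renormalisation, adaptive model update rule) is
normative for the container format and is documented in ``docs/FORMAT.md``.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence

__all__ = [
    "BitSink",
    "BitSource",
    "TruncationError",
    "DecodeError",
    "ArithmeticModel",
    "nibble_encode",
    "nibble_decode",
    "minimal_binary_encode",
    "minimal_binary_decode",
    "minimal_width",
    "arithmetic_encode",
    "arithmetic_decode",
]


class TruncationError(Exception):
    """A bit source ran out of bits in the middle of a code word."""


class DecodeError(Exception):
    """A stream could not be decoded (corrupt or mismatched parameters)."""


class BitSink:
    """Append-only bit buffer, MSB-first within each byte."""

    __slots__ = ("_bytes", "_acc", "_nacc")

    def __init__(self) -> None:
        self._bytes = bytearray()
        self._acc = 0  # pending bits, right-aligned
        self._nacc = 0

    @property
    def bit_length(self) -> int:
        return len(self._bytes) * 8 + self._nacc

    def write_bits(self, value: int, nbits: int) -> None:
        """Append the ``nbits`` low-order bits of ``value``, MSB first."""
        if nbits < 0 or value < 0 or value >> nbits:
            raise ValueError(f"value {value} does not fit in {nbits} bits")
        acc = (self._acc << nbits) | value
        nacc = self._nacc + nbits
        out = self._bytes
        while nacc >= 8:
            nacc -= 8
            out.append((acc >> nacc) & 0xFF)
        self._acc = acc & ((1 << nacc) - 1)
        self._nacc = nacc

    def write_bit(self, bit: int) -> None:
        self.write_bits(bit, 1)

    def extend(self, other: "BitSink") -> None:
        """Append another sink's bits without byte-aligning the seam."""
        for b in other._bytes:
            self.write_bits(b, 8)
        if other._nacc:
            self.write_bits(other._acc, other._nacc)

    def to_bytes(self) -> bytes:
        """Flush, zero-padding the final partial byte."""
        if self._nacc:
            pad = 8 - self._nacc
            return bytes(self._bytes) + bytes([(self._acc << pad) & 0xFF])
        return bytes(self._bytes)


class BitSource:
    """Sequential bit reader over a byte buffer, MSB-first.

    ``nbits`` bounds the readable region; reading past it raises
    :class:`TruncationError`.
    """

    __slots__ = ("_data", "_nbits", "_pos")

    def __init__(self, data: bytes, nbits: int | None = None) -> None:
        self._data = data
        self._nbits = len(data) * 8 if nbits is None else nbits
        if self._nbits > len(data) * 8:
            raise ValueError("bit count exceeds buffer")
        self._pos = 0

    @property
    def bits_remaining(self) -> int:
        return self._nbits - self._pos

    @property
    def position(self) -> int:
        return self._pos

    def read_bits(self, nbits: int) -> int:
        if nbits > self._nbits - self._pos:
            raise TruncationError(
                f"requested {nbits} bits, {self._nbits - self._pos} remain"
            )
        pos = self._pos
        data = self._data
        value = 0
        taken = 0
        while taken < nbits:
            byte_idx, bit_off = divmod(pos, 8)
            avail = 8 - bit_off
            take = min(avail, nbits - taken)
            chunk = (data[byte_idx] >> (avail - take)) & ((1 << take) - 1)
            value = (value << take) | chunk
            taken += take
            pos += take
        self._pos = pos
        return value

    def read_bit(self) -> int:
        return self.read_bits(1)


# ---------------------------------------------------------------------------
# Nibble coding


def nibble_encode(value: int, sink: BitSink) -> int:
    """Write a natural number as 4-bit blocks; returns the bit count."""
    if value < 0:
        raise ValueError("nibble coding is defined for natural numbers only")
    nbits = max(1, value.bit_length())
    nblocks = (nbits + 2) // 3
    for i in range(nblocks - 1, -1, -1):
        payload = (value >> (3 * i)) & 0b111
        flag = 1 if i == 0 else 0
        sink.write_bits((flag << 3) | payload, 4)
    return 4 * nblocks


def nibble_decode(source: BitSource) -> int:
    value = 0
    while True:
        block = source.read_bits(4)
        value = (value << 3) | (block & 0b111)
        if block & 0b1000:
            return value


# ---------------------------------------------------------------------------
# Minimal binary coding


def minimal_width(max_rebased: int) -> int:
    """Bit width for rebased values in ``[0, max_rebased]``.

    The width is the position of the most significant bit of the largest
    rebased value (at least 1 so that zero-range lists remain encodable).
    """
    return max(1, max_rebased.bit_length())


def minimal_binary_encode(value: int, m: int, sink: BitSink) -> int:
    if m < 1:
        raise ValueError("width must be >= 1")
    if value < 0 or value >> m:
        raise ValueError(f"value {value} out of range for {m}-bit code")
    sink.write_bits(value, m)
    return m


def minimal_binary_decode(source: BitSource, m: int) -> int:
    return source.read_bits(m)


# ---------------------------------------------------------------------------
# Adaptive arithmetic coding

_RESCALE_THRESHOLD = 1 << 16

_TOP = 1 << 32
_HALF = 1 << 31
_QUARTER = 1 << 30
_MASK = _TOP - 1


class ArithmeticModel:
    """Adaptive frequency model over ``n`` symbols.

    Counts start at 1 for every symbol and the observed symbol's count is
    incremented by 1 after it is coded.  When the total exceeds
    ``max(2^16, 2n)`` all counts are halved (floored at 1); the ``2n`` term
    keeps rescaling amortized O(1) for alphabets larger than the threshold.  Cumulative sums and the inverse lookup
    used by the decoder run in ``O(log n)`` over a Fenwick tree.
    """

    __slots__ = ("n", "_tree", "_total", "_log")

    def __init__(self, n: int) -> None:
        if n < 1:
            raise ValueError("alphabet size must be >= 1")
        self.n = n
        self._log = 1
        while (1 << self._log) < n + 1:
            self._log += 1
        self._build([1] * n)

    def _build(self, counts: Sequence[int]) -> None:
        n = self.n
        tree = [0] * (n + 1)
        for i, c in enumerate(counts):
            tree[i + 1] += c
            j = i + 1 + ((i + 1) & -(i + 1))
            if j <= n:
                tree[j] += tree[i + 1]
        self._tree = tree
        self._total = sum(counts)

    def _counts(self) -> List[int]:
        return [self.cum(i + 1) - self.cum(i) for i in range(self.n)]

    @property
    def total(self) -> int:
        return self._total

    def cum(self, i: int) -> int:
        """Sum of counts of symbols ``< i``."""
        tree = self._tree
        s = 0
        while i > 0:
            s += tree[i]
            i -= i & -i
        return s

    def find(self, target: int) -> int:
        """Largest symbol ``s`` with ``cum(s) <= target``."""
        tree = self._tree
        idx = 0
        bitmask = 1 << (self._log - 1)
        while bitmask:
            nxt = idx + bitmask
            if nxt <= self.n and tree[nxt] <= target:
                idx = nxt
                target -= tree[nxt]
            bitmask >>= 1
        return idx

    def update(self, symbol: int) -> None:
        n = self.n
        tree = self._tree
        i = symbol + 1
        while i <= n:
            tree[i] += 1
            i += i & -i
        self._total += 1
        if self._total > _RESCALE_THRESHOLD and self._total > 2 * n:
            self._build([max(1, c >> 1) for c in self._counts()])


def _fenwick_from_counts(counts: List[int]) -> List[int]:
    n = len(counts)
    tree = [0] * (n + 1)
    for i, c in enumerate(counts):
        tree[i + 1] += c
        j = i + 1 + ((i + 1) & -(i + 1))
        if j <= n:
            tree[j] += tree[i + 1]
    return tree


def arithmetic_encode(symbols: Iterable[int], n: int, sink: BitSink) -> int:
    """Arithmetic-code ``symbols`` from an ``n``-symbol alphabet.

    The payload is prefixed with its own bit length (nibble-coded) so that
    consecutive codes can share one bit stream; returns total bits written.
    The loop below is a flattened, bit-identical form of the documented
    algorithm (:class:`ArithmeticModel` update rule + 32-bit interval
    coder); the class-based form survives as the testable reference surface.
    """
    counts = [1] * n
    tree = _fenwick_from_counts(counts)
    total = n
    low = 0
    high = _MASK
    pending = 0
    out = bytearray()
    acc = 0
    nacc = 0
    three_quarter = 3 * _QUARTER
    wrote_any = False
    for s in symbols:
        if not 0 <= s < n:
            raise ValueError(f"symbol {s} outside alphabet of size {n}")
        wrote_any = True
        lo = 0
        i = s
        while i > 0:
            lo += tree[i]
            i -= i & -i
        hi = lo + counts[s]
        span = high - low + 1
        high = low + span * hi // total - 1
        low = low + span * lo // total
        while True:
            if high < _HALF:
                bit = 0
            elif low >= _HALF:
                bit = 1
                low -= _HALF
                high -= _HALF
            elif low >= _QUARTER and high < three_quarter:
                pending += 1
                low = (low - _QUARTER) << 1
                high = ((high - _QUARTER) << 1) | 1
                continue
            else:
                break
            acc = (acc << 1) | bit
            nacc += 1
            if pending:
                acc <<= pending
                if not bit:
                    acc |= (1 << pending) - 1
                nacc += pending
                pending = 0
            while nacc >= 8:
                nacc -= 8
                out.append((acc >> nacc) & 0xFF)
            acc &= (1 << nacc) - 1
            low <<= 1
            high = (high << 1) | 1
        counts[s] += 1
        i = s + 1
        while i <= n:
            tree[i] += 1
            i += i & -i
        total += 1
        if total > _RESCALE_THRESHOLD and total > 2 * n:
            counts = [max(1, c >> 1) for c in counts]
            tree = _fenwick_from_counts(counts)
            total = sum(counts)
    if wrote_any:
        pending += 1
        bit = 0 if low < _QUARTER else 1
        acc = (acc << 1) | bit
        nacc += 1
        acc <<= pending
        if not bit:
            acc |= (1 << pending) - 1
        nacc += pending
        while nacc >= 8:
            nacc -= 8
            out.append((acc >> nacc) & 0xFF)
        acc &= (1 << nacc) - 1
    nbits = len(out) * 8 + nacc
    header = nibble_encode(nbits, sink)
    for b in out:
        sink.write_bits(b, 8)
    if nacc:
        sink.write_bits(acc, nacc)
    return header + nbits


def arithmetic_decode(source: BitSource, count: int, n: int) -> List[int]:
    """Decode ``count`` symbols written by :func:`arithmetic_encode`."""
    if n < 1:
        raise DecodeError("alphabet size must be >= 1")
    nbits = nibble_decode(source)
    if nbits > source.bits_remaining:
        raise DecodeError("arithmetic payload extends past end of stream")
    if count == 0:
        source.read_bits(nbits)
        return []
    # pull the payload region into 32-bit words for cheap bit serving
    words: List[int] = []
    remaining = nbits
    while remaining >= 32:
        words.append(source.read_bits(32))
        remaining -= 32
    if remaining:
        words.append(source.read_bits(remaining) << (32 - remaining))
    words.append(0)  # zero padding for the decoder's lookahead

    counts = [1] * n
    tree = _fenwick_from_counts(counts)
    total = n
    log = 1
    while (1 << log) < n + 1:
        log += 1
    top_mask = 1 << (log - 1)
    low = 0
    high = _MASK
    pos = 32
    value = words[0]
    three_quarter = 3 * _QUARTER
    nwords = len(words)
    out: List[int] = []
    for _ in range(count):
        span = high - low + 1
        scaled = ((value - low + 1) * total - 1) // span
        if scaled >= total:
            raise DecodeError("corrupt arithmetic stream")
        # Fenwick descent: symbol and its cumulative count in one pass
        idx = 0
        rem = scaled
        bitmask = top_mask
        while bitmask:
            nxt = idx + bitmask
            if nxt <= n and tree[nxt] <= rem:
                idx = nxt
                rem -= tree[nxt]
            bitmask >>= 1
        sym = idx
        lo = scaled - rem
        hi = lo + counts[sym]
        high = low + span * hi // total - 1
        low = low + span * lo // total
        while True:
            if high < _HALF:
                pass
            elif low >= _HALF:
                low -= _HALF
                high -= _HALF
                value -= _HALF
            elif low >= _QUARTER and high < three_quarter:
                low -= _QUARTER
                high -= _QUARTER
                value -= _QUARTER
            else:
                break
            low <<= 1
            high = (high << 1) | 1
            if pos < nbits:
                w = pos >> 5
                bit = (words[w] >> (31 - (pos & 31))) & 1 if w < nwords else 0
            else:
                bit = 0
            pos += 1
            value = (value << 1) | bit
        counts[sym] += 1
        i = sym + 1
        while i <= n:
            tree[i] += 1
            i += i & -i
        total += 1
        if total > _RESCALE_THRESHOLD and total > 2 * n:
            counts = [max(1, c >> 1) for c in counts]
            tree = _fenwick_from_counts(counts)
            total = sum(counts)
        out.append(sym)
    return out
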