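"""Plain, slow reference implementations of the three coders.

Written independently of the production module from the documented coding
rules (docs/FORMAT.md): bits are plain Python lists of 0/1, the adaptive
model is a linear-scan count list, and the arithmetic coder follows the
normative 32-bit interval algorithm step by step.  The production coders
are differentially tested against these, bit for bit.
"""

from typing import List, Sequence, Tuple

HALF = 1 << 31
QUARTER = 1 << 30
MASK = (1 << 32) - 1
RESCALE = 1 << 16


def ref_nibble_encode(value: int) -> List[int]:
    assert value >= 0
    bits = bin(value)[2:]
    while len(bits) % 3 != 0:
        bits = "0" + bits
    blocks = [bits[i : i + 3] for i in range(0, len(bits), 3)]
    out: List[int] = []
    for i, block in enumerate(blocks):
        out.append(1 if i == len(blocks) - 1 else 0)
        out.extend(int(c) for c in block)
    return out


def ref_nibble_decode(bits: Sequence[int], pos: int) -> Tuple[int, int]:
    value = 0
    while True:
        flag = bits[pos]
        value = (value << 3) | (bits[pos + 1] << 2) | (bits[pos + 2] << 1) | bits[pos + 3]
        pos += 4
        if flag:
            return value, pos


def ref_minimal_binary_encode(value: int, m: int) -> List[int]:
    assert 0 <= value < (1 << m)
    return [(value >> (m - 1 - i)) & 1 for i in range(m)]


class _RefModel:
    def __init__(self, n: int):
        self.counts = [1] * n

    @property
    def total(self) -> int:
        return sum(self.counts)

    def cum(self, i: int) -> int:
        return sum(self.counts[:i])

    def update(self, s: int) -> None:
        self.counts[s] += 1
        if sum(self.counts) > max(RESCALE, 2 * len(self.counts)):
            self.counts = [max(1, c // 2) for c in self.counts]


def ref_arithmetic_encode(symbols: Sequence[int], n: int) -> List[int]:
    """Payload bits of the adaptive arithmetic code (no length prefix)."""
    model = _RefModel(n)
    low, high, pending = 0, MASK, 0
    out: List[int] = []

    def emit(bit: int) -> None:
        nonlocal pending
        out.append(bit)
        out.extend([1 - bit] * pending)
        pending = 0

    for s in symbols:
        total = model.total
        span = high - low + 1
        high = low + span * model.cum(s + 1) // total - 1
        low = low + span * model.cum(s) // total
        while True:
            if high < HALF:
                emit(0)
            elif low >= HALF:
                emit(1)
                low -= HALF
                high -= HALF
            elif low >= QUARTER and high < 3 * QUARTER:
                pending += 1
                low -= QUARTER
                high -= QUARTER
            else:
                break
            low = low * 2
            high = high * 2 + 1
        model.update(s)
    if symbols:
        pending += 1
        emit(0 if low < QUARTER else 1)
    return out


def ref_arithmetic_decode(bits: Sequence[int], count: int, n: int) -> List[int]:
    model = _RefModel(n)
    low, high = 0, MASK
    pos = 0

    def next_bit() -> int:
        nonlocal pos
        b = bits[pos] if pos < len(bits) else 0
        pos += 1
        return b

    value = 0
    for _ in range(32):
        value = (value << 1) | next_bit()
    out: List[int] = []
    for _ in range(count):
        total = model.total
        span = high - low + 1
        scaled = ((value - low + 1) * total - 1) // span
        s = 0
        while model.cum(s + 1) <= scaled:
            s += 1
        high = low + span * model.cum(s + 1) // total - 1
        low = low + span * model.cum(s) // total
        while True:
            if high < HALF:
                pass
            elif low >= HALF:
                low -= HALF
                high -= HALF
                value -= HALF
            elif low >= QUARTER and high < 3 * QUARTER:
                low -= QUARTER
                high -= QUARTER
                value -= QUARTER
            else:
                break
            low = low * 2
            high = high * 2 + 1
            value = (value << 1) | next_bit()
        model.update(s)
        out.append(s)
    return out


def ref_arithmetic_encode_framed(symbols: Sequence[int], n: int) -> List[int]:
    """Length-prefixed form matching the production stream layout."""
    payload = ref_arithmetic_encode(symbols, n)
    return ref_nibble_encode(len(payload)) + payload
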