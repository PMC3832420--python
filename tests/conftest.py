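import random

import pytest

from actpack.data_model import AlignmentEntry, EntryLink, SequenceVariation


def sink_bits(sink) -> str:
    """Render a BitSink's exact content (no flush padding) as a 0/1 string."""
    data = sink.to_bytes()
    return "".join(format(b, "08b") for b in data)[: sink.bit_length]


@pytest.fixture
def rng():
    return random.Random(20240915)


def make_entry(
    query_index=0,
    position=0,
    target_index=0,
    fragment_index=0,
    n_variations=0,
    **kwargs,
) -> AlignmentEntry:
    params = dict(
        query_index=query_index,
        target_index=target_index,
        position=position,
        fragment_index=fragment_index,
        query_length=100,
        query_aligned_length=100,
        target_aligned_length=100,
        mapping_quality=60,
    )
    params.update(kwargs)
    e = AlignmentEntry(**params)
    for i in range(n_variations):
        e.sequence_variations.append(
            SequenceVariation(10 * i + 1, 10 * i + 2, "A", "G", bytes([30]))
        )
    return e


def random_entry(rng: random.Random, n_targets=4, span=10**6) -> AlignmentEntry:
    e = AlignmentEntry(
        query_index=rng.randrange(10**6),
        target_index=rng.randrange(n_targets),
        position=rng.randrange(span),
        fragment_index=rng.randrange(2),
        matching_reverse_strand=bool(rng.getrandbits(1)),
        query_length=100,
        query_aligned_length=rng.randint(80, 100),
        target_aligned_length=rng.randint(80, 110),
        mapping_quality=rng.choice((0, 20, 30, 60)),
        score=float(rng.randint(-60, 0)),
    )
    for _ in range(rng.randrange(3)):
        kind = rng.randrange(3)
        if kind == 0:
            v = SequenceVariation(rng.randrange(80), rng.randint(1, 100), "A", "T",
                                  bytes([rng.randrange(41)]))
        elif kind == 1:
            v = SequenceVariation(rng.randrange(80), rng.randint(1, 100), "",
                                  "ACG"[: rng.randint(1, 3)],
                                  bytes([30] * rng.randint(1, 3)))
        else:
            v = SequenceVariation(rng.randrange(80), rng.randint(1, 100),
                                  "CGT"[: rng.randint(1, 3)], "")
        e.sequence_variations.append(v)
    if rng.random() < 0.4:
        e.pair_link = EntryLink(rng.randrange(span), rng.randrange(n_targets),
                                rng.randrange(2))
    if rng.random() < 0.15:
        e.softclip_left = "ACGT"[: rng.randint(1, 4)]
        e.softclip_left_quals = bytes(
            rng.randrange(41) for _ in range(len(e.softclip_left))
        )
    if rng.random() < 0.2:
        e.to_quality = bytes(rng.randrange(41) for _ in range(e.query_aligned_length))
    return e


@pytest.fixture
def random_entries(rng):
    return [random_entry(rng) for _ in range(400)]
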