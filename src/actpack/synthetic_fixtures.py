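"""Deterministic generators of read and alignment collections.

The generators emulate the record-level statistics of common sequencing
assay classes — spliced paired RNA-Seq, exome capture, whole-genome
sequencing (WGS), and reduced-representation bisulfite sequencing (RRBS) —
so the codecs can be exercised and benchmarked without external data.
Reference sequences are i.i.d. nucleotides: the codecs never inspect
reference biology, only record structure.  All randomness flows from the
spec's seed through one named generator, and every byte-affecting path is
integer-valued, so a spec reproduces byte-identical output on any platform.

Statistics modelled per entry: genomic position (sorted or shuffled),
per-base substitution and indel rates, soft-clip rate, paired mates with a
normal-ish insert-size distribution and reciprocal links, spliced fragments
with forward/backward links, runs of entries sharing one template
(duplicate reads), variation qualities, and optionally mapped qualities
over the whole read.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Dict, List, Tuple

from actpack.data_model import (
    AlignmentEntry,
    AlignmentHeader,
    EntryLink,
    ReadEntry,
    SequenceVariation,
)

__all__ = [
    "FixtureSpec",
    "FIXTURE_CLASSES",
    "fixture_spec",
    "generate_alignment_fixture",
    "generate_sam_fixture",
    "generate_reads_fixture",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic alignment collection."""

    n_entries: int = 10_000
    read_length: int = 100
    n_targets: int = 4
    target_length: int = 1_000_000
    paired: bool = False
    insert_mean: int = 200
    insert_sd: int = 30
    spliced: bool = False
    splice_rate: float = 0.0
    intron_mean: int = 1000
    substitution_rate: float = 0.01
    indel_rate: float = 0.001
    softclip_rate: float = 0.05
    sorted: bool = True
    duplicate_rate: float = 0.2
    preserve_all_mapped_qualities: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "splice_rate",
            "substitution_rate",
            "indel_rate",
            "softclip_rate",
            "duplicate_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_entries < 0:
            raise ValueError("n_entries must be >= 0")


#: Assay-class presets emulating the qualitative dataset families of HTS
#: benchmarks: spliced paired RNA-Seq, exome, WGS, and bisulfite (RRBS).
FIXTURE_CLASSES: Dict[str, dict] = {
    "rnaseq": dict(
        paired=True,
        spliced=True,
        splice_rate=0.15,
        substitution_rate=0.01,
        indel_rate=0.001,
        softclip_rate=0.05,
        duplicate_rate=0.25,
        sorted=True,
    ),
    "exome": dict(
        paired=True,
        substitution_rate=0.005,
        indel_rate=0.0005,
        softclip_rate=0.03,
        duplicate_rate=0.15,
        sorted=True,
    ),
    "wgs": dict(
        paired=True,
        substitution_rate=0.002,
        indel_rate=0.0002,
        softclip_rate=0.02,
        duplicate_rate=0.05,
        sorted=True,
    ),
    "rrbs": dict(
        paired=False,
        substitution_rate=0.12,  # bisulfite C->T conversion dominates
        indel_rate=0.0005,
        softclip_rate=0.02,
        duplicate_rate=0.35,
        sorted=True,
    ),
}


def fixture_spec(class_name: str, n_entries: int, seed: int = 0, **overrides) -> FixtureSpec:
    """Build the spec of a named fixture class."""
    if class_name not in FIXTURE_CLASSES:
        raise ValueError(
            f"unknown fixture class {class_name!r}; known: {sorted(FIXTURE_CLASSES)}"
        )
    params = dict(FIXTURE_CLASSES[class_name])
    params.update(overrides)
    return FixtureSpec(n_entries=n_entries, seed=seed, **params)


def _make_reference(rng: random.Random, spec: FixtureSpec) -> Dict[str, str]:
    return {
        f"target{t}": "".join(rng.choices(_BASES, k=spec.target_length))
        for t in range(spec.n_targets)
    }


def _plant_variations(
    rng: random.Random,
    spec: FixtureSpec,
    ref: str,
    position: int,
    read_length: int,
    clip_l: int,
    clip_r: int,
) -> Tuple[List[SequenceVariation], int, int]:
    """Plant substitutions and indels over one aligned segment.

    Returns (variations, query_aligned_length, target_aligned_length).
    """
    q_aligned = read_length - clip_l - clip_r
    variations: List[SequenceVariation] = []
    ref_off = 0
    qpos = clip_l  # full-read index, aligned orientation
    remaining_q = q_aligned
    while remaining_q > 0:
        r = rng.random()
        if r < spec.indel_rate and remaining_q > 4:
            if rng.random() < 0.5:  # insertion
                ilen = rng.randint(1, 3)
                ilen = min(ilen, remaining_q - 1)
                bases = "".join(rng.choice(_BASES) for _ in range(ilen))
                variations.append(
                    SequenceVariation(
                        position=ref_off,
                        read_index=qpos + 1,
                        from_bases="",
                        to_bases=bases,
                        to_qualities=bytes(
                            rng.randint(20, 40) for _ in range(ilen)
                        ),
                    )
                )
                qpos += ilen
                remaining_q -= ilen
            else:  # deletion
                dlen = rng.randint(1, 3)
                from_bases = ref[position + ref_off : position + ref_off + dlen]
                variations.append(
                    SequenceVariation(
                        position=ref_off,
                        read_index=qpos + 1,
                        from_bases=from_bases,
                        to_bases="",
                    )
                )
                ref_off += dlen
            # a matched base must separate events so decomposition is unique
            qpos += 1
            ref_off += 1
            remaining_q -= 1
        elif r < spec.indel_rate + spec.substitution_rate:
            from_base = ref[position + ref_off]
            to_base = rng.choice([b for b in _BASES if b != from_base])
            variations.append(
                SequenceVariation(
                    position=ref_off,
                    read_index=qpos + 1,
                    from_bases=from_base,
                    to_bases=to_base,
                    to_qualities=bytes([rng.randint(20, 40)]),
                )
            )
            qpos += 1
            ref_off += 1
            remaining_q -= 1
        else:
            qpos += 1
            ref_off += 1
            remaining_q -= 1
    return variations, q_aligned, ref_off


def _new_entry(
    rng: random.Random,
    spec: FixtureSpec,
    reference: Dict[str, str],
    target: int,
    position: int,
    query_index: int,
    fragment_index: int,
    allow_decoration: bool = True,
) -> AlignmentEntry:
    ref = reference[f"target{target}"]
    clip_l = clip_r = 0
    if allow_decoration and rng.random() < spec.softclip_rate:
        if rng.random() < 0.5:
            clip_l = rng.randint(1, 8)
        else:
            clip_r = rng.randint(1, 8)
    variations, q_aligned, t_aligned = _plant_variations(
        rng, spec, ref, position, spec.read_length, clip_l, clip_r
    )
    e = AlignmentEntry(
        query_index=query_index,
        target_index=target,
        position=position,
        fragment_index=fragment_index,
        matching_reverse_strand=bool(rng.getrandbits(1)),
        query_length=spec.read_length,
        query_aligned_length=q_aligned,
        target_aligned_length=t_aligned,
        mapping_quality=rng.choice((20, 30, 40, 60)),
        score=float(-2 * len(variations)),
        sequence_variations=variations,
    )
    if clip_l:
        e.softclip_left = "".join(rng.choice(_BASES) for _ in range(clip_l))
        e.softclip_left_quals = bytes(rng.randint(2, 40) for _ in range(clip_l))
    if clip_r:
        e.softclip_right = "".join(rng.choice(_BASES) for _ in range(clip_r))
        e.softclip_right_quals = bytes(rng.randint(2, 40) for _ in range(clip_r))
    if spec.preserve_all_mapped_qualities:
        e.to_quality = bytes(rng.randint(20, 40) for _ in range(q_aligned))
    return e


def generate_alignment_fixture(
    spec: FixtureSpec,
) -> Tuple[List[AlignmentEntry], Dict[str, str], AlignmentHeader]:
    """Generate an alignment collection matching ``spec``.

    Entries come out genomically sorted when ``spec.sorted`` (positions
    monotone within each target), otherwise shuffled.  Paired specs emit
    mate entries with reciprocal position/target/fragment links; spliced
    reads emit two fragments joined by splice links.  Query indices are a
    random permutation, as they would be after sorting a read-order
    alignment.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    reference = _make_reference(rng, spec)
    entries: List[AlignmentEntry] = []
    # generation walks targets in order, advancing position monotonically
    margin = spec.read_length * 4 + spec.insert_mean + 8 * spec.insert_sd
    if spec.spliced:
        margin += 2 * spec.intron_mean + spec.read_length
    span = spec.n_targets * (spec.target_length - margin)
    mean_gap = max(1, span // max(1, spec.n_entries))
    target = 0
    position = 0
    query_counter = 0
    while len(entries) < spec.n_entries:
        position += rng.randint(0, 2 * mean_gap)
        if position >= spec.target_length - margin:
            target = (target + 1) % spec.n_targets
            position = rng.randint(0, mean_gap)
        qi = query_counter
        query_counter += 1
        if spec.duplicate_rate and rng.random() < spec.duplicate_rate:
            # a run of entries sharing one template: no clips, shared
            # variation structure; only query index and position vary
            run = 1 + min(rng.randrange(1, 6), spec.n_entries - len(entries) - 1)
            proto = _new_entry(
                rng, spec, reference, target, position, qi, 0,
                allow_decoration=False,
            )
            proto.sequence_variations = []
            proto.score = 0.0
            proto.query_aligned_length = spec.read_length
            proto.target_aligned_length = spec.read_length
            proto.to_quality = (
                bytes([30] * spec.read_length)
                if spec.preserve_all_mapped_qualities
                else None
            )
            entries.append(proto)
            for _ in range(run - 1):
                dup = replace(
                    proto,
                    query_index=query_counter,
                    position=position,
                    sequence_variations=[],
                )
                query_counter += 1
                entries.append(dup)
            continue
        if spec.spliced and rng.random() < spec.splice_rate:
            # two fragments of one read joined by splice links
            len_a = spec.read_length // 2
            intron = rng.randint(60, 2 * spec.intron_mean)
            pos_b = position + len_a + intron
            half = replace(spec, read_length=len_a)
            other = replace(spec, read_length=spec.read_length - len_a)
            a = _new_entry(rng, half, reference, target, position, qi, 0,
                           allow_decoration=False)
            b = _new_entry(rng, other, reference, target, pos_b, qi, 1,
                           allow_decoration=False)
            a.splice_forward_link = EntryLink(b.position, b.target_index, b.fragment_index)
            b.splice_backward_link = EntryLink(a.position, a.target_index, a.fragment_index)
            entries.append(a)
            entries.append(b)
            continue
        if spec.paired:
            insert = max(
                spec.read_length + 10,
                int(rng.normalvariate(spec.insert_mean, spec.insert_sd)),
            )
            pos_b = position + insert - spec.read_length
            a = _new_entry(rng, spec, reference, target, position, qi, 0)
            b = _new_entry(rng, spec, reference, target, pos_b, qi, 1)
            a.matching_reverse_strand = False
            b.matching_reverse_strand = True
            a.pair_link = EntryLink(b.position, b.target_index, b.fragment_index)
            b.pair_link = EntryLink(a.position, a.target_index, a.fragment_index)
            entries.append(a)
            entries.append(b)
        else:
            entries.append(
                _new_entry(rng, spec, reference, target, position, qi, 0)
            )
    entries = entries[: spec.n_entries]
    # drop links pointing at truncated-away mates
    present = {
        (e.position, e.target_index, e.fragment_index) for e in entries
    }
    for e in entries:
        for attr in ("pair_link", "splice_forward_link", "splice_backward_link"):
            link = getattr(e, attr)
            if link is not None and link.triple() not in present:
                setattr(e, attr, None)
    if spec.sorted:
        entries.sort(key=lambda e: (e.target_index, e.position))
    else:
        rng.shuffle(entries)
    # query indices of a sorted alignment are uniformly scattered
    perm = list(range(query_counter))
    rng.shuffle(perm)
    for e in entries:
        e.query_index = perm[e.query_index]
    header = AlignmentHeader(
        target_names=[f"target{t}" for t in range(spec.n_targets)],
        target_lengths=[spec.target_length] * spec.n_targets,
        n_queries=query_counter,
        sorted=spec.sorted,
    )
    return entries, reference, header


def generate_sam_fixture(spec: FixtureSpec) -> Tuple[str, Dict[str, str]]:
    """Generate SAM text consistent with the alignment fixture.

    Splicing is disabled (a spliced read maps to two entries, which has no
    single-record SAM equivalent here) and mapped qualities are kept so the
    records carry full SEQ/QUAL columns.  The text parses with standard SAM
    tooling; CIGAR and MD are derived from the planted variations.
    """
    from actpack.tiered_io import export_sam

    sam_spec = replace(spec, spliced=False, splice_rate=0.0,
                       preserve_all_mapped_qualities=True)
    entries, reference, header = generate_alignment_fixture(sam_spec)
    return export_sam(entries, header, reference), reference


def generate_reads_fixture(
    n_reads: int, read_length: int = 100, paired: bool = False, seed: int = 0
) -> List[ReadEntry]:
    """Generate a Tier-I read collection with sequential query indices."""
    rng = random.Random(seed)
    reads = []
    for i in range(n_reads):
        r = ReadEntry(
            query_index=i,
            sequence="".join(rng.choice(_BASES) for _ in range(read_length)),
            qualities=bytes(rng.randint(2, 40) for _ in range(read_length)),
        )
        if paired:
            r.pair_sequence = "".join(
                rng.choice(_BASES) for _ in range(read_length)
            )
            r.pair_qualities = bytes(
                rng.randint(2, 40) for _ in range(read_length)
            )
        reads.append(r)
    return reads
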