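"""Multi-tier file organization: SAM and FASTQ interop, genomic sorting and
indexing, and query-index permutation.

Tier I holds reads (``.compact-reads``); Tier II holds alignments
(``.entries`` container, ``.header`` metadata, ``.index`` for random access
by genomic position, optional ``.tmh`` for reads with too many hits);
Tier III holds the ``.perm`` permutation linking small sorted query indices
back to original read identities.  Together Tiers I and II cover the
information a BAM file stores.

SAM records are decomposed on import: the CIGAR/MD encoding of differences
between read and reference becomes a list of sequence-variation records,
soft clips and their qualities are preserved on request, and 1-based SAM
coordinates become the 0-based convention used internally.  Variation
``read_index`` values are 1-based positions within the read *as aligned*
(left to right in reference orientation, clipped bases included); for
reverse-strand alignments this indexes the reverse-complemented read.
Read names are not preserved — read identity is the integer query index.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from actpack.data_model import (
    AlignmentEntry,
    AlignmentHeader,
    EntryLink,
    ReadEntry,
    SequenceVariation,
)
from actpack.storage_protocol import Codec, iter_chunks_from, write_collection

__all__ = [
    "TierSet",
    "PermutationMap",
    "GenomicIndex",
    "SamImportError",
    "import_sam",
    "export_sam",
    "sort_and_index",
    "query_window",
    "permute_query_indices",
    "import_fastq",
    "export_fastq",
    "write_tier_set",
    "read_tier_set",
]


class SamImportError(Exception):
    """A SAM record could not be decomposed into sequence variations."""


@dataclass
class TierSet:
    """In-memory image of one sample's tiered files."""

    entries_data: Optional[bytes] = None  # .entries container
    header: Optional[AlignmentHeader] = None  # .header
    index: Optional["GenomicIndex"] = None  # .index
    tmh: List[int] = field(default_factory=list)  # .tmh
    perm: Optional["PermutationMap"] = None  # .perm
    reads_data: Optional[bytes] = None  # .compact-reads


# ---------------------------------------------------------------------------
# SAM import

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def _parse_md(md: str):
    """MD tag -> sequence of ('match', n) / ('mismatch', ref) / ('del', ref)."""
    out = []
    for m in _MD_TOKEN.finditer(md):
        if m.group(1) is not None:
            n = int(m.group(1))
            if n:
                out.append(("match", n))
        elif m.group(2) is not None:
            out.append(("del", m.group(2)[1:].upper()))
        else:
            out.append(("mismatch", m.group(3).upper()))
    return out

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")


def _parse_cigar(cigar: str) -> List[Tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_TOKEN.findall(cigar)]


def _decompose_record(
    cigar: List[Tuple[int, str]],
    md_ops,
    seq: str,
    qual: Optional[bytes],
) -> Tuple[List[SequenceVariation], int, int, str, str, Optional[bytes], Optional[bytes]]:
    """Walk CIGAR (+MD) over SEQ, yielding variations and clip data.

    Returns (variations, query_aligned_length, target_aligned_length,
    clip_left, clip_right, clip_left_quals, clip_right_quals).
    """
    variations: List[SequenceVariation] = []
    qpos = 0  # index into SEQ (full read, aligned orientation)
    ref_off = 0  # offset from entry position
    clip_left = clip_right = ""
    clip_lq = clip_rq = None
    md = list(md_ops)
    md_i = 0
    md_rem = 0  # remaining matched bases in current MD run

    def md_next():
        nonlocal md_i
        if md_i >= len(md):
            raise SamImportError("MD tag exhausted before CIGAR")
        op = md[md_i]
        md_i += 1
        return op

    for length, op in cigar:
        if op == "S":
            bases = seq[qpos : qpos + length]
            quals = qual[qpos : qpos + length] if qual is not None else None
            if qpos == 0:
                clip_left, clip_lq = bases, quals
            else:
                clip_right, clip_rq = bases, quals
            qpos += length
        elif op in ("M", "=", "X"):
            remaining = length
            while remaining:
                if md_rem == 0:
                    kind, val = md_next()
                    if kind == "match":
                        md_rem = val
                        continue
                    if kind == "mismatch":
                        to_base = seq[qpos] if seq else "N"
                        variations.append(
                            SequenceVariation(
                                position=ref_off,
                                read_index=qpos + 1,
                                from_bases=val,
                                to_bases=to_base,
                                to_qualities=bytes([qual[qpos]])
                                if qual is not None
                                else None,
                            )
                        )
                        qpos += 1
                        ref_off += 1
                        remaining -= 1
                        continue
                    raise SamImportError("MD deletion inside CIGAR match")
                take = min(md_rem, remaining)
                md_rem -= take
                remaining -= take
                qpos += take
                ref_off += take
        elif op == "I":
            variations.append(
                SequenceVariation(
                    position=ref_off,
                    read_index=qpos + 1,
                    from_bases="",
                    to_bases=seq[qpos : qpos + length],
                    to_qualities=bytes(qual[qpos : qpos + length])
                    if qual is not None
                    else None,
                )
            )
            qpos += length
        elif op == "D":
            kind, val = md_next()
            if kind != "del" or len(val) != length:
                raise SamImportError("CIGAR deletion disagrees with MD tag")
            variations.append(
                SequenceVariation(
                    position=ref_off,
                    read_index=qpos + 1,
                    from_bases=val,
                    to_bases="",
                    to_qualities=None,
                )
            )
            ref_off += length
        elif op == "N":
            ref_off += length
        elif op in ("H", "P"):
            continue
        else:
            raise SamImportError(f"unsupported CIGAR op {op}")
    q_aligned = qpos - len(clip_left) - len(clip_right)
    return variations, q_aligned, ref_off, clip_left, clip_right, clip_lq, clip_rq


def import_sam(
    sam_text: str | Iterable[str],
    *,
    preserve_soft_clips: bool = True,
    preserve_all_mapped_qualities: bool = False,
    ambiguity_threshold: Optional[int] = None,
) -> Tuple[List[AlignmentEntry], AlignmentHeader, List[int]]:
    """Decompose SAM records into alignment entries.

    Each mapped record's CIGAR/MD pair is replaced by a list of sequence
    variations (the MD tag is required: without it the read-vs-reference
    differences cannot be derived).  Read names map to query indices in
    first-appearance order.  When ``ambiguity_threshold`` is given, reads
    with more than that many records are listed in the returned tmh set
    and their entries dropped.  Returns (entries, header, tmh).
    """
    if isinstance(sam_text, str):
        lines = sam_text.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in sam_text]
    target_names: List[str] = []
    target_lengths: List[int] = []
    records = []
    for ln in lines:
        if not ln:
            continue
        if ln.startswith("@"):
            if ln.startswith("@SQ"):
                fields = dict(
                    f.split(":", 1) for f in ln.split("\t")[1:] if ":" in f
                )
                target_names.append(fields["SN"])
                target_lengths.append(int(fields.get("LN", 0)))
            continue
        records.append(ln.split("\t"))
    tid_of = {name: i for i, name in enumerate(target_names)}
    name_to_qi: Dict[str, int] = {}
    hits: Dict[str, int] = {}
    for f in records:
        name = f[0]
        if name not in name_to_qi:
            name_to_qi[name] = len(name_to_qi)
        hits[name] = hits.get(name, 0) + 1
    tmh: List[int] = []
    if ambiguity_threshold is not None:
        tmh = sorted(
            name_to_qi[n] for n, c in hits.items() if c > ambiguity_threshold
        )
    tmh_set = set(tmh)
    entries: List[AlignmentEntry] = []
    for f in records:
        name, flag, rname = f[0], int(f[1]), f[2]
        if flag & 0x4 or rname == "*":
            continue  # unmapped reads live in Tier I only
        qi = name_to_qi[name]
        if qi in tmh_set:
            continue
        opt = {}
        for tagfield in f[11:]:
            tag, typ, val = tagfield.split(":", 2)
            opt[tag] = val
        if "MD" not in opt:
            raise SamImportError(
                f"record {name!r} lacks an MD tag; variations cannot be derived"
            )
        seq = f[9] if f[9] != "*" else ""
        qual = (
            bytes(ord(c) - 33 for c in f[10]) if f[10] != "*" else None
        )
        cigar = _parse_cigar(f[5])
        (
            variations,
            q_aligned,
            t_aligned,
            clip_l,
            clip_r,
            clip_lq,
            clip_rq,
        ) = _decompose_record(cigar, _parse_md(opt["MD"]), seq, qual)
        e = AlignmentEntry(
            query_index=qi,
            target_index=tid_of[rname],
            position=int(f[3]) - 1,
            fragment_index=1 if flag & 0x80 else 0,
            matching_reverse_strand=bool(flag & 0x10),
            query_length=len(seq) if seq else q_aligned + len(clip_l) + len(clip_r),
            query_aligned_length=q_aligned,
            target_aligned_length=t_aligned,
            mapping_quality=int(f[4]),
            score=float(opt.get("AS", 0.0)),
            sequence_variations=variations,
        )
        if preserve_soft_clips and (clip_l or clip_r):
            if clip_l:
                e.softclip_left = clip_l
                e.softclip_left_quals = clip_lq
            if clip_r:
                e.softclip_right = clip_r
                e.softclip_right_quals = clip_rq
        if preserve_all_mapped_qualities and qual is not None:
            lo = len(clip_l)
            hi = len(seq) - len(clip_r)
            e.to_quality = qual[lo:hi]
        if flag & 0x1 and f[6] != "*":
            mate_t = tid_of[rname] if f[6] == "=" else tid_of[f[6]]
            e.pair_link = EntryLink(
                position=int(f[7]) - 1,
                target_index=mate_t,
                fragment_index=0 if flag & 0x80 else 1,
            )
        entries.append(e)
    header = AlignmentHeader(
        target_names=target_names,
        target_lengths=target_lengths,
        n_queries=len(name_to_qi),
    )
    return entries, header, tmh


# ---------------------------------------------------------------------------
# SAM export


def _rebuild_cigar_md(e: AlignmentEntry) -> Tuple[str, str, List[SequenceVariation]]:
    """CIGAR and MD from an entry's variation list (N not reconstructed:
    any skipped reference span is folded into deletions by construction)."""
    cigar: List[str] = []
    if e.softclip_left:
        cigar.append(f"{len(e.softclip_left)}S")
    md: List[str] = []
    events = sorted(
        e.sequence_variations, key=lambda v: (v.position, v.from_bases != "")
    )
    ref_off = 0
    match_run = 0  # aligned (M) bases since last emitted cigar op
    md_run = 0  # matched bases since last MD event
    for v in events:
        gap = v.position - ref_off
        match_run += gap
        md_run += gap
        ref_off = v.position
        if not v.from_bases:  # insertion
            if match_run:
                cigar.append(f"{match_run}M")
                match_run = 0
            cigar.append(f"{len(v.to_bases)}I")
        elif not v.to_bases:  # deletion
            if match_run:
                cigar.append(f"{match_run}M")
                match_run = 0
            cigar.append(f"{len(v.from_bases)}D")
            md.append(str(md_run))
            md.append("^" + v.from_bases)
            md_run = 0
            ref_off += len(v.from_bases)
        else:  # mismatch(es)
            match_run += len(v.from_bases)
            for base in v.from_bases:
                md.append(str(md_run))
                md_run = 0
                md.append(base)
            ref_off += len(v.from_bases)
    tail = e.target_aligned_length - ref_off
    match_run += tail
    md_run += tail
    if match_run:
        cigar.append(f"{match_run}M")
    md.append(str(md_run))
    if e.softclip_right:
        cigar.append(f"{len(e.softclip_right)}S")
    return "".join(cigar), "".join(md), events


def _rebuild_seq_qual(
    e: AlignmentEntry, reference: Optional[Dict[str, str]], target_name: str
) -> Tuple[str, str]:
    """Reconstruct SEQ/QUAL from reference plus variations and clips."""
    if reference is None:
        return "*", "*"
    ref = reference[target_name]
    aligned = []
    events = sorted(
        e.sequence_variations, key=lambda v: (v.position, v.from_bases != "")
    )
    ref_off = 0
    for v in events:
        aligned.append(ref[e.position + ref_off : e.position + v.position])
        ref_off = v.position
        if not v.from_bases:
            aligned.append(v.to_bases)
        elif not v.to_bases:
            ref_off += len(v.from_bases)
        else:
            aligned.append(v.to_bases)
            ref_off += len(v.from_bases)
    aligned.append(ref[e.position + ref_off : e.position + e.target_aligned_length])
    seq = (e.softclip_left or "") + "".join(aligned) + (e.softclip_right or "")
    qual = "*"
    if e.to_quality is not None:
        q = (
            (e.softclip_left_quals or b"\x00" * len(e.softclip_left or ""))
            + e.to_quality
            + (e.softclip_right_quals or b"\x00" * len(e.softclip_right or ""))
        )
        qual = "".join(chr(c + 33) for c in q)
    return seq, qual


def export_sam(
    entries: Sequence[AlignmentEntry],
    header: AlignmentHeader,
    reference: Optional[Dict[str, str]] = None,
) -> str:
    """Render entries back to SAM text.

    Read names are synthesized as ``q<query_index>`` (identity lives in the
    query index).  SEQ/QUAL require the reference (and stored qualities);
    without them the columns are ``*``.
    """
    lines = ["@HD\tVN:1.6"]
    for name, length in zip(header.target_names, header.target_lengths):
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    for e in entries:
        for attr in ("pair_link", "splice_forward_link", "splice_backward_link"):
            link = getattr(e, attr)
            if link is not None and link.is_delta:
                raise ValueError(
                    "entry links must be in triple form for export "
                    "(decode the container first)"
                )
        flag = 0
        if e.matching_reverse_strand:
            flag |= 0x10
        rnext, pnext = "*", 0
        if e.pair_link is not None:
            flag |= 0x1
            flag |= 0x80 if e.fragment_index else 0x40
            mate_name = header.target_names[e.pair_link.target_index]
            rnext = "=" if e.pair_link.target_index == e.target_index else mate_name
            pnext = e.pair_link.position + 1
        target_name = header.target_names[e.target_index]
        cigar, md, _ = _rebuild_cigar_md(e)
        seq, qual = _rebuild_seq_qual(e, reference, target_name)
        lines.append(
            "\t".join(
                [
                    f"q{e.query_index}",
                    str(flag),
                    target_name,
                    str(e.position + 1),
                    str(e.mapping_quality),
                    cigar or "*",
                    rnext,
                    str(pnext),
                    "0",
                    seq,
                    qual,
                    f"MD:Z:{md}",
                    f"AS:i:{int(e.score)}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Sorting, indexing, window queries


@dataclass
class GenomicIndex:
    """Maps chunk starts to byte offsets for random access by position."""

    chunk_keys: List[Tuple[int, int]] = field(default_factory=list)
    chunk_offsets: List[int] = field(default_factory=list)
    max_span: int = 0  # largest target_aligned_length seen (query slack)

    def to_json(self) -> str:
        return json.dumps(
            {
                "chunk_keys": self.chunk_keys,
                "chunk_offsets": self.chunk_offsets,
                "max_span": self.max_span,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GenomicIndex":
        d = json.loads(text)
        return cls(
            [tuple(k) for k in d["chunk_keys"]], d["chunk_offsets"], d["max_span"]
        )


def sort_and_index(
    entries: Sequence[AlignmentEntry],
    codec: Codec,
    chunk_size: int = 100_000,
) -> Tuple[List[AlignmentEntry], bytes, GenomicIndex]:
    """Sort by (target, position), write a container and its genomic index."""
    ordered = sorted(entries, key=lambda e: (e.target_index, e.position))
    index = GenomicIndex()
    offset = 0
    frames: List[bytes] = []
    for start in range(0, len(ordered), chunk_size):
        chunk = ordered[start : start + chunk_size]
        data = write_collection(chunk, codec, chunk_size=chunk_size)
        frame = data[: -12]  # drop the termination chunk of the sub-container
        index.chunk_keys.append((chunk[0].target_index, chunk[0].position))
        index.chunk_offsets.append(offset)
        frames.append(frame)
        offset += len(frame)
        span = max((e.target_aligned_length for e in chunk), default=0)
        index.max_span = max(index.max_span, span)
    from actpack.storage_protocol import TERMINATION

    container = b"".join(frames) + TERMINATION
    return ordered, container, index


def query_window(
    container: bytes,
    index: GenomicIndex,
    target_index: int,
    start: int,
    end: int,
) -> List[AlignmentEntry]:
    """Entries overlapping [start, end) on a target, via the index."""
    import bisect

    key = (target_index, max(0, start - index.max_span))
    i = bisect.bisect_right(index.chunk_keys, key) - 1
    if i < 0:
        i = 0
    offset = index.chunk_offsets[i] if index.chunk_offsets else 0
    out: List[AlignmentEntry] = []
    for chunk in iter_chunks_from(container, offset):
        first = (chunk[0].target_index, chunk[0].position)
        if first > (target_index, end):
            break
        for e in chunk:
            if e.target_index != target_index:
                continue
            if e.position < end and e.position + e.target_aligned_length > start:
                out.append(e)
    return out


# ---------------------------------------------------------------------------
# Query-index permutation (Tier III)


@dataclass
class PermutationMap:
    """Blocks mapping small sorted indices back to original query indices."""

    block_size: int = 1024
    blocks: List[List[int]] = field(default_factory=list)
    min_q: int = 0
    max_q: int = 0

    def original_of(self, small: int) -> int:
        b, r = divmod(small, self.block_size)
        return self.blocks[b][r]

    def __len__(self) -> int:
        return sum(len(b) for b in self.blocks)

    def to_json(self) -> str:
        return json.dumps(
            {
                "block_size": self.block_size,
                "blocks": self.blocks,
                "min_q": self.min_q,
                "max_q": self.max_q,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PermutationMap":
        d = json.loads(text)
        return cls(d["block_size"], d["blocks"], d["min_q"], d["max_q"])


def permute_query_indices(
    sorted_entries: Sequence[AlignmentEntry], block_size: int = 1024
) -> Tuple[List[AlignmentEntry], PermutationMap]:
    """Replace original query indices by small genomic-order indices.

    Small indices are assigned 0, 1, 2, … in first-occurrence order over the
    genomically sorted entries; every fragment of one read receives the same
    small index.  The returned map retrieves the original index for any
    small index without touching the entries.
    """
    mapping: Dict[int, int] = {}
    out: List[AlignmentEntry] = []
    from actpack.act_codec import _clone_entry

    originals: List[int] = []
    for e in sorted_entries:
        if e.query_index not in mapping:
            mapping[e.query_index] = len(mapping)
            originals.append(e.query_index)
        c = _clone_entry(e)
        c.query_index = mapping[e.query_index]
        out.append(c)
    pm = PermutationMap(
        block_size=block_size,
        blocks=[
            originals[i : i + block_size]
            for i in range(0, len(originals), block_size)
        ],
        min_q=min(originals) if originals else 0,
        max_q=max(originals) if originals else 0,
    )
    return out, pm


# ---------------------------------------------------------------------------
# FASTQ (Tier I)


def _fastq_records(lines: Iterable[str]):
    buf = []
    for ln in lines:
        ln = ln.rstrip("\n")
        if not ln and not buf:
            continue
        buf.append(ln)
        if len(buf) == 4:
            name = buf[0][1:].split()[0]
            if buf[2] and not buf[2].startswith("+"):
                raise ValueError(f"malformed FASTQ record {name!r}")
            yield name, buf[1], buf[3]
            buf = []
    if buf:
        raise ValueError("truncated FASTQ input")


def import_fastq(
    fastq: str | Iterable[str],
    pair_fastq: Optional[str | Iterable[str]] = None,
    keep_identifiers: bool = False,
) -> List[ReadEntry]:
    """FASTQ (optionally paired) to read entries with sequential indices."""
    first = list(_fastq_records(
        fastq.splitlines() if isinstance(fastq, str) else fastq
    ))
    second = None
    if pair_fastq is not None:
        second = list(_fastq_records(
            pair_fastq.splitlines() if isinstance(pair_fastq, str) else pair_fastq
        ))
        if len(second) != len(first):
            raise ValueError(
                f"paired files differ in record count "
                f"({len(first)} vs {len(second)})"
            )
    reads = []
    for i, (name, seq, qual) in enumerate(first):
        r = ReadEntry(
            query_index=i,
            sequence=seq,
            qualities=bytes(ord(c) - 33 for c in qual),
        )
        if keep_identifiers:
            r.identifier = name
        if second is not None:
            _, pseq, pqual = second[i]
            r.pair_sequence = pseq
            r.pair_qualities = bytes(ord(c) - 33 for c in pqual)
        reads.append(r)
    return reads


def export_fastq(reads: Sequence[ReadEntry]) -> Tuple[str, Optional[str]]:
    """Read entries back to FASTQ text (and mate FASTQ when paired)."""
    out1, out2 = [], []
    paired = any(r.pair_sequence is not None for r in reads)
    for r in reads:
        name = r.identifier or f"q{r.query_index}"
        qual = "".join(chr(c + 33) for c in (r.qualities or b""))
        out1.append(f"@{name}\n{r.sequence}\n+\n{qual}\n")
        if paired:
            pq = "".join(chr(c + 33) for c in (r.pair_qualities or b""))
            out2.append(f"@{name}\n{r.pair_sequence or ''}\n+\n{pq}\n")
    return "".join(out1), "".join(out2) if paired else None


# ---------------------------------------------------------------------------
# Tier file I/O


def write_tier_set(base_path: str, tiers: TierSet) -> List[str]:
    """Write the populated members of a tier set next to ``base_path``."""
    written = []
    if tiers.entries_data is not None:
        p = base_path + ".entries"
        with open(p, "wb") as fh:
            fh.write(tiers.entries_data)
        written.append(p)
    if tiers.header is not None:
        p = base_path + ".header"
        with open(p, "w") as fh:
            json.dump(asdict(tiers.header), fh)
        written.append(p)
    if tiers.index is not None:
        p = base_path + ".index"
        with open(p, "w") as fh:
            fh.write(tiers.index.to_json())
        written.append(p)
    if tiers.tmh:
        p = base_path + ".tmh"
        with open(p, "w") as fh:
            json.dump(tiers.tmh, fh)
        written.append(p)
    if tiers.perm is not None:
        p = base_path + ".perm"
        with open(p, "w") as fh:
            fh.write(tiers.perm.to_json())
        written.append(p)
    if tiers.reads_data is not None:
        p = base_path + ".compact-reads"
        with open(p, "wb") as fh:
            fh.write(tiers.reads_data)
        written.append(p)
    return written


def read_tier_set(base_path: str) -> TierSet:
    import os

    tiers = TierSet()
    if os.path.exists(base_path + ".entries"):
        with open(base_path + ".entries", "rb") as fh:
            tiers.entries_data = fh.read()
    if os.path.exists(base_path + ".header"):
        with open(base_path + ".header") as fh:
            tiers.header = AlignmentHeader(**json.load(fh))
    if os.path.exists(base_path + ".index"):
        with open(base_path + ".index") as fh:
            tiers.index = GenomicIndex.from_json(fh.read())
    if os.path.exists(base_path + ".tmh"):
        with open(base_path + ".tmh") as fh:
            tiers.tmh = json.load(fh)
    if os.path.exists(base_path + ".perm"):
        with open(base_path + ".perm") as fh:
            tiers.perm = PermutationMap.from_json(fh.read())
    if os.path.exists(base_path + ".compact-reads"):
        with open(base_path + ".compact-reads", "rb") as fh:
            tiers.reads_data = fh.read()
    return tiers
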