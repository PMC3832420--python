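"""Hybrid chunk codec: template algorithm traces, link optimization,
field modeling, column laws and full round trips."""

import copy

import pytest

from actpack.act_codec import (
    compress_chunk,
    decompose_chunk,
    decompress_chunk,
    model_fields,
    optimize_links,
    recompose_chunk,
    restore_links,
    template_compress,
    template_expand,
    unmodel_fields,
)
from actpack.coding_primitives import DecodeError
from actpack.data_model import (
    AlignmentEntry,
    EntryLink,
    SequenceVariation,
    make_unknown_payload,
    set_unknown_field,
)

from .conftest import make_entry

ALL_OPTIONS = [(False, False), (True, False), (False, True), (True, True)]


class TestTemplateAlgorithm:
    """Hand-traced chunks for the run-length-over-templates algorithm."""

    def test_identical_run_emits_one_template(self):
        run = []
        for i in range(5):
            e = make_entry(query_index=i, position=100 + i)
            run.append(e)
        counts, reps = template_compress(run)
        assert counts == [5]
        assert len(reps) == 1

    def test_alternating_templates_never_merge(self):
        # runs must be consecutive; the count resets on every change
        a = make_entry(mapping_quality=60)
        b = make_entry(mapping_quality=9)
        chunk = [copy.deepcopy(x) for x in (a, b, a, b)]
        for i, e in enumerate(chunk):
            e.query_index = i
        counts, reps = template_compress(chunk)
        assert counts == [1, 1, 1, 1]
        assert [r.mapping_quality for r in reps] == [60, 9, 60, 9]

    def test_single_entry(self):
        counts, reps = template_compress([make_entry()])
        assert counts == [1] and len(reps) == 1

    def test_nontemplate_fields_do_not_split_runs(self):
        # query index, position and mapped qualities vary freely inside a run
        chunk = []
        for i in range(4):
            e = make_entry(query_index=1000 - i, position=7 * i)
            e.to_quality = bytes([i] * 10)
            chunk.append(e)
        counts, _ = template_compress(chunk)
        assert counts == [4]

    def test_variation_differences_split_runs(self):
        a = make_entry(n_variations=1)
        b = make_entry(n_variations=2)
        counts, _ = template_compress(
            [copy.deepcopy(a), copy.deepcopy(a), copy.deepcopy(b)]
        )
        assert counts == [2, 1]

    def test_expansion_law(self, random_entries):
        counts, reps = template_compress(random_entries)
        assert sum(counts) == len(random_entries)
        expanded = template_expand(counts, reps)
        # templates equal within runs; non-template fields come from columns
        assert len(expanded) == len(random_entries)

    def test_empty_chunk(self):
        assert template_compress([]) == ([], [])
        assert template_expand([], []) == []


class TestLinkOptimization:
    def _chunk(self):
        entries = [
            make_entry(query_index=i, position=100 + 10 * i) for i in range(10)
        ]
        return entries

    def test_mates_become_signed_offsets(self):
        entries = self._chunk()
        entries[4].pair_link = EntryLink(160, 0, 0)  # entry 6
        entries[6].pair_link = EntryLink(140, 0, 0)  # entry 4
        out = optimize_links(entries)
        assert out[4].pair_link.delta == 2
        assert out[6].pair_link.delta == -2

    def test_cross_chunk_link_kept_explicit(self):
        entries = self._chunk()
        entries[0].pair_link = EntryLink(99_999, 2, 1)  # not in this chunk
        out = optimize_links(entries)
        assert out[0].pair_link == EntryLink(99_999, 2, 1)

    def test_ambiguous_triple_kept_explicit(self):
        entries = self._chunk()
        entries[2].position = entries[3].position = 500
        entries[0].pair_link = EntryLink(500, 0, 0)
        out = optimize_links(entries)
        assert not out[0].pair_link.is_delta

    def test_entry_without_links_unchanged(self):
        entries = self._chunk()
        assert optimize_links(entries) == entries

    def test_optimize_then_restore_is_identity(self, random_entries):
        # involution safety on triples that resolve in-chunk and ones that don't
        entries = list(random_entries)
        for i in range(0, 100, 2):
            entries[i].pair_link = EntryLink(
                entries[i + 1].position,
                entries[i + 1].target_index,
                entries[i + 1].fragment_index,
            )
        restored = restore_links(optimize_links(entries))
        assert restored == entries


class TestFieldModeling:
    def test_position_deltas(self):
        cols = model_fields({"position": [100, 100, 105, 230]})
        assert cols["position"] == [100, 0, 5, 125]
        assert unmodel_fields(cols)["position"] == [100, 100, 105, 230]

    def test_perfect_alignment_residual_is_zero(self):
        cols = model_fields(
            {"query_length": [100, 100], "query_aligned_length": [100, 95]}
        )
        assert cols["query_aligned_length"] == [0, 5]
        assert unmodel_fields(cols)["query_aligned_length"] == [100, 95]

    def test_unsorted_positions_yield_negative_deltas(self):
        cols = model_fields({"position": [500, 100]})
        assert cols["position"] == [500, -400]
        assert unmodel_fields(cols)["position"] == [500, 100]


class TestDecompose:
    def test_no_unknown_fields_no_leftovers(self):
        entries = [make_entry(query_index=i) for i in range(3)]
        _, leftovers = decompose_chunk(entries)
        assert leftovers == []

    def test_residual_keeps_ordinal(self):
        entries = [make_entry(query_index=i) for i in range(3)]
        payload = make_unknown_payload(50, b"xyz")
        entries[1] = set_unknown_field(entries[1], payload)
        _, leftovers = decompose_chunk(entries)
        assert leftovers == [(1, payload)]

    def test_nested_count_column_law(self):
        entries = [
            make_entry(n_variations=2),
            make_entry(n_variations=0),
            make_entry(n_variations=1),
        ]
        cols, _ = decompose_chunk(entries)
        by_id = {c.field_id: c.values for c in cols}
        assert by_id["variation_count"] == [2, 0, 1]
        assert len(by_id["variation_position"]) == 3
        assert len(by_id["query_index"]) == 3

    def test_recomposition_exact(self):
        entries = [make_entry(query_index=i, n_variations=i % 3) for i in range(20)]
        cols, leftovers = decompose_chunk(entries)
        assert recompose_chunk(cols, leftovers) == entries


class TestChunkRoundTrip:
    @pytest.mark.parametrize("template,domain", ALL_OPTIONS)
    def test_random_chunk_roundtrip(self, random_entries, template, domain):
        payload = compress_chunk(random_entries, template=template, domain=domain)
        assert decompress_chunk(payload) == random_entries

    @pytest.mark.parametrize("template,domain", ALL_OPTIONS)
    def test_empty_chunk(self, template, domain):
        payload = compress_chunk([], template=template, domain=domain)
        assert decompress_chunk(payload) == []

    def test_unknown_fields_attached_to_right_entries(self, random_entries):
        entries = list(random_entries)
        entries[3] = set_unknown_field(entries[3], make_unknown_payload(60, b"A3"))
        entries[7] = set_unknown_field(entries[7], make_unknown_payload(60, b"B7"))
        back = decompress_chunk(compress_chunk(entries, template=True, domain=True))
        assert back == entries
        assert back[3].unknown_fields != back[7].unknown_fields

    def test_options_flag_mismatch_detected(self, random_entries):
        payload = compress_chunk(random_entries, template=True, domain=False)
        with pytest.raises(DecodeError):
            decompress_chunk(payload, template=False)
        with pytest.raises(DecodeError):
            decompress_chunk(payload, domain=True)
        assert decompress_chunk(payload, template=True, domain=False) == random_entries

    def test_corrupt_payload_raises(self, random_entries):
        payload = bytearray(compress_chunk(random_entries).data)
        payload[5] ^= 0xFF
        with pytest.raises(Exception):
            got = decompress_chunk(bytes(payload))
            if got == random_entries:  # corruption must not go unnoticed
                raise AssertionError("corruption silently ignored")

    def test_intra_chunk_mates_roundtrip_under_domain(self):
        entries = [make_entry(query_index=i, position=50 * i) for i in range(40)]
        for i in range(0, 40, 2):
            entries[i].pair_link = EntryLink(50 * (i + 1), 0, 0)
            entries[i + 1].pair_link = EntryLink(50 * i, 0, 0)
        payload = compress_chunk(entries, template=True, domain=True)
        assert decompress_chunk(payload) == entries


class TestSizeOrdering:
    def test_template_shrinks_duplicate_rich_chunks(self):
        # consecutive identical templates: T must strictly help
        entries = []
        for i in range(2000):
            entries.append(make_entry(query_index=i, position=10 * i))
        h = len(compress_chunk(entries, template=False, domain=False).data)
        ht = len(compress_chunk(entries, template=True, domain=False).data)
        assert ht < h

    def test_domain_shrinks_link_rich_chunks(self):
        entries = [make_entry(query_index=i, position=50 * i) for i in range(2000)]
        for i in range(0, 2000, 2):
            entries[i].pair_link = EntryLink(50 * (i + 1), 0, 0)
            entries[i + 1].pair_link = EntryLink(50 * i, 0, 0)
        ht = len(compress_chunk(entries, template=True, domain=False).data)
        htd = len(compress_chunk(entries, template=True, domain=True).data)
        assert htd < ht
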