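"""Corpus I/O: normalization, BIO conversion, slicing, splitting, formats."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import random_document
from ohcner.corpus_io import (
    AnnotatedDocument,
    EntitySpan,
    SplitSpec,
    TaggedSequence,
    ValidationError,
    bio_to_spans,
    normalize_text,
    normalize_with_offsets,
    read_conll,
    read_jsonl,
    slice_document,
    spans_to_bio,
    split_dataset,
    write_conll,
    write_jsonl,
)


class TestNormalize:
    @pytest.mark.parametrize("raw,expected", [
        ("血糖高\U0001F600", "血糖高:grinning_face:"),
        ("", ""),
        ("空腹血糖7.8", "空腹血糖7.8"),           # no emoji/control: identity
        ("你好​世界", "你好世界"),            # zero-width mark removed
        ("a\x00b\x07c", "abc"),                  # control chars removed
        ("测\U0001F9EA试", "测:emoji:试"),        # unknown emoji -> generic code
    ])
    def test_replacement_policy(self, raw, expected):
        assert normalize_text(raw) == expected

    def test_chinese_punctuation_preserved(self):
        s = "血糖高，去医院；复查。！？"
        assert normalize_text(s) == s

    @settings(max_examples=200, derandomize=True)
    @given(st.text(max_size=40))
    def test_idempotent_on_arbitrary_unicode(self, raw):
        once = normalize_text(raw)
        assert normalize_text(once) == once

    def test_offset_map_points_into_source(self):
        raw = "高\U0001F600糖"
        out, src = normalize_with_offsets(raw)
        assert out == "高:grinning_face:糖"
        assert len(src) == len(out)
        assert src[0] == 0 and src[-1] == 2
        # every shortcode character maps back to the emoji position
        assert set(src[1:-1]) == {1}


class TestBioConversion:
    def test_span_becomes_b_then_i(self):
        doc = AnnotatedDocument("d", "abcde", [EntitySpan(0, 2, "drug")])
        seq = spans_to_bio(doc)
        assert seq.tags == ["B-drug", "I-drug", "O", "O", "O"]

    def test_no_spans_all_outside(self):
        seq = spans_to_bio(AnnotatedDocument("d", "abc", []))
        assert seq.tags == ["O", "O", "O"]

    def test_overlap_rejected_naming_spans(self):
        doc = AnnotatedDocument("d", "abcde", [EntitySpan(0, 2, "drug"),
                                               EntitySpan(1, 3, "check")])
        with pytest.raises(ValidationError, match="overlap"):
            spans_to_bio(doc)

    def test_keep_longest_repair(self):
        doc = AnnotatedDocument("d", "abcde", [EntitySpan(0, 2, "drug"),
                                               EntitySpan(1, 5, "check")])
        repaired = doc.validate(keep_longest=True)
        assert repaired.spans == [EntitySpan(1, 5, "check")]

    def test_decode_definition_and_repair(self):
        assert bio_to_spans(["B-drug", "I-drug", "O"]) == [EntitySpan(0, 2, "drug")]
        assert bio_to_spans(["I-drug", "I-drug"]) == [EntitySpan(0, 2, "drug")]

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValidationError, match="unknown tag"):
            bio_to_spans(["B-drug", "X-drug"])

    def test_strict_mode_rejects_ill_formed(self):
        with pytest.raises(ValidationError, match="ill-formed"):
            bio_to_spans(["O", "I-drug"], strict=True)

    def test_round_trip_on_random_documents(self, rng):
        for i in range(300):
            doc = random_document(rng, f"d{i}").validate()
            seq = spans_to_bio(doc)
            assert bio_to_spans(seq.tags) == doc.spans


class TestSlicing:
    def test_short_document_single_slice(self, rng):
        doc = random_document(rng, "d", min_len=40, max_len=50).validate()
        slices = slice_document(doc, 128)
        assert len(slices) == 1
        assert slices[0].text == doc.text

    def test_cut_moved_before_straddling_entity(self):
        # entity straddles the naive cut at max_len=10
        text = "a" * 9 + "bb" + "c" * 5
        doc = AnnotatedDocument("d", text, [EntitySpan(9, 11, "drug")])
        slices = slice_document(doc, 10)
        assert all(len(s) <= 10 for s in slices)
        mentions = [m for s in slices for m in
                    [(sp.start + s.offset, sp.end + s.offset, sp.label)
                     for sp in bio_to_spans(s.tags)]]
        assert mentions == [(9, 11, "drug")]

    def test_oversized_entity_rejected(self):
        doc = AnnotatedDocument("d", "abcdefgh", [EntitySpan(0, 8, "drug")])
        with pytest.raises(ValidationError, match="longer than max_len"):
            slice_document(doc, 5)

    def test_conservation_over_random_documents(self, rng):
        """Characters and (surface, label) mention multisets are preserved."""
        for i in range(150):
            doc = random_document(rng, f"d{i}", min_len=20, max_len=300).validate()
            slices = slice_document(doc, 64)
            assert "".join(s.text for s in slices) == doc.text
            assert all(len(s) <= 64 for s in slices)
            before = sorted(doc.mentions())
            after = sorted(
                (s.text[sp.start:sp.end], sp.label)
                for s in slices for sp in bio_to_spans(s.tags))
            assert before == after

    def test_slices_prefer_sentence_breaks(self):
        text = ("ab" * 10 + "。") * 5  # sentence breaks every 21 chars
        doc = AnnotatedDocument("d", text, [])
        slices = slice_document(doc, 50)
        for s in slices[:-1]:
            assert s.text.endswith("。")


def _dummy_slices(n):
    return [TaggedSequence(["a"], ["O"], doc_id=str(i)) for i in range(n)]


class TestSplit:
    def test_five_to_one_ratio(self):
        train, val, test = split_dataset(_dummy_slices(600),
                                         SplitSpec(test_count=0))
        assert (len(train), len(val), len(test)) == (500, 100, 0)

    def test_fixed_test_count(self):
        train, val, test = split_dataset(_dummy_slices(6669),
                                         SplitSpec(test_count=650))
        assert len(test) == 650
        assert len(train) + len(val) == 6019

    def test_seed_determinism_and_partition(self):
        slices = _dummy_slices(100)
        a = split_dataset(slices, SplitSpec(test_fraction=0.1, seed=3))
        b = split_dataset(slices, SplitSpec(test_fraction=0.1, seed=3))
        ids = lambda parts: [[s.doc_id for s in p] for p in parts]
        assert ids(a) == ids(b)
        all_ids = sorted(i for p in ids(a) for i in p)
        assert all_ids == sorted(s.doc_id for s in slices)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            SplitSpec(test_fraction=1.5)
        with pytest.raises(ValidationError):
            split_dataset(_dummy_slices(2), SplitSpec())


class TestFormats:
    def test_jsonl_round_trip(self, tmp_path, rng):
        docs = [random_document(rng, f"d{i}").validate() for i in range(20)]
        path = tmp_path / "corpus.jsonl"
        write_jsonl(docs, path)
        back = read_jsonl(path)
        assert [(d.doc_id, d.text, d.spans) for d in back] == \
               [(d.doc_id, d.text, sorted(d.spans)) for d in docs]

    def test_jsonl_is_doccano_shaped(self, tmp_path):
        doc = AnnotatedDocument("1", "abc", [EntitySpan(0, 1, "drug")])
        path = tmp_path / "c.jsonl"
        write_jsonl([doc], path)
        rec = json.loads(path.read_text().strip())
        assert rec == {"id": "1", "text": "abc", "label": [[0, 1, "drug"]]}

    def test_conll_round_trip(self, tmp_path, small_slices):
        path = tmp_path / "out.conll"
        write_conll(small_slices, path)
        back = read_conll(path)
        assert [(s.tokens, s.tags) for s in back] == \
               [(s.tokens, s.tags) for s in small_slices]

    def test_malformed_jsonl_rejected(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"text": "ab", "label": [[0, 5, "drug"]]}\n')
        with pytest.raises(ValidationError, match="out of bounds"):
            read_jsonl(path)
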