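"""Annotated-corpus I/O: Doccano JSONL ingestion, text normalization,
span<->BIO conversion, document slicing and dataset splitting.

The unit of annotation is an :class:`AnnotatedDocument` (unicode text plus
character-offset entity spans); the unit of model I/O is a
:class:`TaggedSequence` (aligned character tokens and BIO tags).  Offsets are
0-based half-open ``[start, end)``; tokenization is per Unicode character,
the standard choice for Chinese clinical NER.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .emoji_codes import is_emoji, shortcode
from .labels import DEFAULT_SCHEME, LabelScheme

# sentence-ending punctuation preferred as slice cut points
SENTENCE_BREAKS = "。！？；.!?;\n"


class ValidationError(ValueError):
    """Raised when annotations violate the corpus contracts."""


@dataclass(frozen=True, order=True)
class EntitySpan:
    """Character-offset entity annotation: ``text[start:end]`` has `label`."""

    start: int
    end: int
    label: str

    def shifted(self, delta: int) -> "EntitySpan":
        return EntitySpan(self.start + delta, self.end + delta, self.label)


@dataclass
class AnnotatedDocument:
    """A consultation text with its validated entity spans."""

    doc_id: str
    text: str
    spans: list[EntitySpan] = field(default_factory=list)

    def validate(self, scheme: LabelScheme = DEFAULT_SCHEME,
                 keep_longest: bool = False) -> "AnnotatedDocument":
        """Check bounds, labels and overlaps; returns a document with spans
        sorted by start offset.

        With ``keep_longest`` an overlapping pair is repaired by dropping the
        shorter span instead of raising.
        """
        n = len(self.text)
        for s in self.spans:
            if not (0 <= s.start < s.end <= n):
                raise ValidationError(
                    f"doc {self.doc_id}: span {s} out of bounds for text of length {n}")
            scheme.validate_label(s.label)
        spans = sorted(self.spans)
        kept: list[EntitySpan] = []
        for s in spans:
            if kept and s.start < kept[-1].end:
                if keep_longest:
                    if (s.end - s.start) > (kept[-1].end - kept[-1].start):
                        kept[-1] = s
                    continue
                raise ValidationError(
                    f"doc {self.doc_id}: overlapping spans {kept[-1]} and {s}")
            kept.append(s)
        return AnnotatedDocument(self.doc_id, self.text, kept)

    def mentions(self) -> list[tuple[str, str]]:
        """(surface, label) pairs, in offset order."""
        return [(self.text[s.start:s.end], s.label) for s in sorted(self.spans)]


@dataclass
class TaggedSequence:
    """Aligned character tokens and BIO tags, with slice provenance."""

    tokens: list[str]
    tags: list[str]
    doc_id: str = ""
    offset: int = 0  # character offset of this slice in the source document

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise ValidationError(
                f"tokens/tags length mismatch: {len(self.tokens)} vs {len(self.tags)}")

    @property
    def text(self) -> str:
        return "".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class SplitSpec:
    """Test-first split: hold out the test set by fraction or fixed count,
    then divide the remainder train:val (floor rounding on the validation
    side)."""

    test_fraction: float | None = 0.1
    test_count: int | None = None
    train_val_ratio: tuple[int, int] = (5, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.test_count is None:
            if self.test_fraction is None or not (0.0 < self.test_fraction < 1.0):
                raise ValidationError("test_fraction must lie in (0, 1)")
        elif self.test_count < 0:
            raise ValidationError("test_count must be non-negative")
        if min(self.train_val_ratio) <= 0:
            raise ValidationError("train:val ratio parts must be positive")


# ---------------------------------------------------------------------------
# normalization


def normalize_with_offsets(raw: str) -> tuple[str, list[int]]:
    """Normalize text and return, per output character, its source index.

    Emoji are replaced by colon-delimited ASCII shortcodes (every shortcode
    character maps back to the emoji's index); control characters and
    zero-width/format marks are dropped.  All other characters, including
    Chinese punctuation, pass through unchanged.
    """
    out: list[str] = []
    src: list[int] = []
    for i, ch in enumerate(raw):
        if ord(ch) == 0xFE0F:  # variation selector riding on an emoji: drop
            continue
        if is_emoji(ch):
            code = shortcode(ch)
            out.append(code)
            src.extend([i] * len(code))
        elif unicodedata.category(ch) in ("Cc", "Cf"):
            continue
        else:
            out.append(ch)
            src.append(i)
    return "".join(out), src


def normalize_text(raw: str) -> str:
    """Total normalization function; see :func:`normalize_with_offsets`."""
    return normalize_with_offsets(raw)[0]


# ---------------------------------------------------------------------------
# BIO conversion


def spans_to_bio(doc: AnnotatedDocument,
                 scheme: LabelScheme = DEFAULT_SCHEME) -> TaggedSequence:
    """Convert validated spans to character-level BIO tags.

    The span's first character gets ``B-label``, the rest ``I-label``,
    everything else ``O``.
    """
    doc = doc.validate(scheme)
    tags = ["O"] * len(doc.text)
    for s in doc.spans:
        tags[s.start] = f"B-{s.label}"
        for i in range(s.start + 1, s.end):
            tags[i] = f"I-{s.label}"
    return TaggedSequence(list(doc.text), tags, doc_id=doc.doc_id, offset=0)


def bio_to_spans(tags: Sequence[str], scheme: LabelScheme = DEFAULT_SCHEME,
                 strict: bool = False) -> list[EntitySpan]:
    """Decode BIO tags to spans (inverse of :func:`spans_to_bio`).

    An I-x opening a run (sequence start, after O, or after a different
    category) is repaired to B-x; with ``strict`` such ill-formed input
    raises instead — used to verify that hard CRF transition constraints
    produce repair-free output.
    """
    valid = set(scheme.tags)
    spans: list[EntitySpan] = []
    cur_start: int | None = None
    cur_label: str | None = None

    def close(end: int) -> None:
        nonlocal cur_start, cur_label
        if cur_label is not None:
            spans.append(EntitySpan(cur_start, end, cur_label))
        cur_start = cur_label = None

    for i, tag in enumerate(tags):
        if tag not in valid:
            raise ValidationError(f"unknown tag {tag!r} at position {i}")
        if tag == "O":
            close(i)
            continue
        prefix, label = tag.split("-", 1)
        if prefix == "B":
            close(i)
            cur_start, cur_label = i, label
        else:  # I-
            if cur_label == label:
                continue
            if strict:
                raise ValidationError(
                    f"ill-formed BIO: {tag} opens a run at position {i}")
            close(i)  # repair: treat as B-
            cur_start, cur_label = i, label
    close(len(tags))
    return spans


# ---------------------------------------------------------------------------
# slicing


def _find_cut(doc: AnnotatedDocument, start: int, limit: int) -> int:
    """Best cut position in (start, limit]: after sentence punctuation when
    possible, otherwise the last position not inside an entity."""
    blocked = np.zeros(len(doc.text) + 1, dtype=bool)
    for s in doc.spans:
        blocked[s.start + 1:s.end] = True  # cutting here would split the span
    for pos in range(limit, start, -1):
        if blocked[pos]:
            continue
        if doc.text[pos - 1] in SENTENCE_BREAKS:
            return pos
    for pos in range(limit, start, -1):
        if not blocked[pos]:
            return pos
    raise ValidationError(
        f"doc {doc.doc_id}: an entity spanning positions {start}..{limit} "
        f"exceeds the slice budget")


def slice_document(doc: AnnotatedDocument, max_len: int,
                   scheme: LabelScheme = DEFAULT_SCHEME) -> list[TaggedSequence]:
    """Slice a document into BIO sequences of at most ``max_len`` characters.

    Cut points prefer sentence-ending punctuation; an entity span is never
    split across slices; concatenating the slices reproduces the text.
    Raises if any entity is longer than ``max_len``.
    """
    if max_len <= 0:
        raise ValidationError("max_len must be positive")
    doc = doc.validate(scheme)
    for s in doc.spans:
        if s.end - s.start > max_len:
            raise ValidationError(
                f"doc {doc.doc_id}: entity {s} longer than max_len={max_len}")
    slices: list[TaggedSequence] = []
    pos = 0
    n = len(doc.text)
    while pos < n:
        if n - pos <= max_len:
            cut = n
        else:
            cut = _find_cut(doc, pos, pos + max_len)
        piece_spans = [s.shifted(-pos) for s in doc.spans
                       if s.start >= pos and s.end <= cut]
        piece = AnnotatedDocument(doc.doc_id, doc.text[pos:cut], piece_spans)
        seq = spans_to_bio(piece, scheme)
        seq.offset = pos
        slices.append(seq)
        pos = cut
    return slices


# ---------------------------------------------------------------------------
# splitting


def split_dataset(slices: Sequence[TaggedSequence], spec: SplitSpec
                  ) -> tuple[list[TaggedSequence], list[TaggedSequence], list[TaggedSequence]]:
    """Shuffle deterministically, hold out the test set, then divide the
    remainder train:val with floor rounding on the validation side."""
    n = len(slices)
    if n < 3:
        raise ValidationError("need at least 3 sequences to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    if spec.test_count is not None:
        n_test = spec.test_count
    else:
        n_test = int(round(n * spec.test_fraction))
    if n_test >= n:
        raise ValidationError("test split would consume the whole dataset")
    test = [slices[i] for i in order[:n_test]]
    rest = order[n_test:]
    a, b = spec.train_val_ratio
    n_val = (len(rest) * b) // (a + b)
    val = [slices[i] for i in rest[:n_val]]
    train = [slices[i] for i in rest[n_val:]]
    return train, val, test


# ---------------------------------------------------------------------------
# file formats


def read_jsonl(path: str | Path,
               scheme: LabelScheme = DEFAULT_SCHEME,
               keep_longest: bool = False) -> list[AnnotatedDocument]:
    """Read Doccano-style JSONL: one ``{"id", "text", "label": [[s,e,cat]...]}``
    object per line."""
    docs: list[AnnotatedDocument] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            spans = [EntitySpan(int(s), int(e), str(lab))
                     for s, e, lab in rec.get("label", [])]
            doc = AnnotatedDocument(str(rec.get("id", lineno)), rec["text"], spans)
            docs.append(doc.validate(scheme, keep_longest=keep_longest))
    return docs


def write_jsonl(docs: Iterable[AnnotatedDocument], path: str | Path,
                split_names: dict[str, str] | None = None) -> None:
    """Write Doccano-style JSONL; ``split_names`` adds a split-assignment
    field per document id."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            rec = {"id": doc.doc_id, "text": doc.text,
                   "label": [[s.start, s.end, s.label] for s in sorted(doc.spans)]}
            if split_names is not None:
                rec["split"] = split_names.get(doc.doc_id, "")
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def write_conll(sequences: Iterable[TaggedSequence], path: str | Path) -> None:
    """Two-column CoNLL-style BIO: character TAB tag, blank line between
    sequences."""
    with open(path, "w", encoding="utf-8") as fh:
        for seq in sequences:
            for tok, tag in zip(seq.tokens, seq.tags):
                fh.write(f"{tok}\t{tag}\n")
            fh.write("\n")


def read_conll(path: str | Path) -> list[TaggedSequence]:
    sequences: list[TaggedSequence] = []
    tokens: list[str] = []
    tags: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                if tokens:
                    sequences.append(TaggedSequence(tokens, tags))
                    tokens, tags = [], []
                continue
            tok, _, tag = line.partition("\t")
            tokens.append(tok)
            tags.append(tag)
    if tokens:
        sequences.append(TaggedSequence(tokens, tags))
    return sequences
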