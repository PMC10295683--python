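"""Entity-level and token-level evaluation, model comparison and corpus
frequency statistics.

A predicted mention counts as correct only under exact match: identical
document, span boundaries and category (set intersection of gold and
predicted mention arrays).  Precision, recall and F1 follow the usual
definitions with the zero-denominator -> 0 convention; "accuracy" is
token-level tag accuracy, since true negatives are undefined for open
entity sets.  The headline aggregate is the macro average over categories;
micro (pooled) counts are reported alongside.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import AnnotatedDocument, TaggedSequence, bio_to_spans
from .labels import DEFAULT_SCHEME, LabelScheme


@dataclass(frozen=True, order=True)
class EntityMention:
    """The unit of entity-level evaluation; identity is exact span+category."""

    doc_id: str
    start: int
    end: int
    category: str
    surface: str = field(default="", compare=False)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class MetricsReport:
    """Per-category and aggregate precision/recall/F1 (+ optional accuracy)."""

    per_category: dict[str, dict[str, float]]
    macro: dict[str, float]
    micro: dict[str, float]
    accuracy: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = dict(self.per_category)
        rows["macro"] = self.macro
        rows["micro"] = self.micro
        frame = pd.DataFrame(rows).T[["precision", "recall", "f1"]]
        if self.accuracy is not None:
            frame.loc["micro", "accuracy"] = self.accuracy
        return frame


def mentions_from_documents(docs: Iterable[AnnotatedDocument]) -> set[EntityMention]:
    out = set()
    for doc in docs:
        for s in doc.spans:
            out.add(EntityMention(doc.doc_id, s.start, s.end, s.label,
                                  doc.text[s.start:s.end]))
    return out


def mentions_from_tags(sequences: Sequence[TaggedSequence],
                       tag_lists: Sequence[Sequence[str]],
                       scheme: LabelScheme = DEFAULT_SCHEME) -> set[EntityMention]:
    """Decode BIO tag lists (aligned with their source slices) to mentions in
    source-document coordinates."""
    out = set()
    for seq, tags in zip(sequences, tag_lists):
        for s in bio_to_spans(tags, scheme):
            start = s.start + seq.offset
            out.add(EntityMention(seq.doc_id, start, s.end + seq.offset,
                                  s.label, seq.text[s.start:s.end]))
    return out


def entity_confusion(gold: set[EntityMention], pred: set[EntityMention]
                     ) -> dict[str, ConfusionCounts]:
    """Exact-match TP/FP/FN per category plus a pooled 'micro' entry."""
    cats = sorted({m.category for m in gold} | {m.category for m in pred})
    out: dict[str, ConfusionCounts] = {}
    inter = gold & pred
    for cat in cats:
        g = {m for m in gold if m.category == cat}
        p = {m for m in pred if m.category == cat}
        i = {m for m in inter if m.category == cat}
        out[cat] = ConfusionCounts(tp=len(i), fp=len(p) - len(i), fn=len(g) - len(i))
    out["micro"] = ConfusionCounts(tp=len(inter), fp=len(pred) - len(inter),
                                   fn=len(gold) - len(inter))
    return out


def prf_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Precision, recall and F1 with zero denominators mapping to 0."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    pre = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    return {"precision": pre, "recall": rec, "f1": f1}


def metrics_report(gold: set[EntityMention], pred: set[EntityMention],
                   categories: Sequence[str] | None = None,
                   accuracy: float | None = None) -> MetricsReport:
    counts = entity_confusion(gold, pred)
    if categories is None:
        categories = [c for c in counts if c != "micro"]
    per_cat = {}
    for cat in categories:
        per_cat[cat] = prf_metrics(counts.get(cat, ConfusionCounts()))
    macro = {m: float(np.mean([per_cat[c][m] for c in per_cat])) if per_cat else 0.0
             for m in ("precision", "recall", "f1")}
    micro = prf_metrics(counts["micro"])
    return MetricsReport(per_cat, macro, micro, accuracy=accuracy)


def token_accuracy(gold_tags: Sequence[Sequence[str]],
                   pred_tags: Sequence[Sequence[str]]) -> float:
    """Fraction of positions with the correct tag (padding excluded by
    construction: only real tokens appear in the lists)."""
    correct = total = 0
    for g, p in zip(gold_tags, pred_tags):
        if len(g) != len(p):
            raise ValueError("gold/predicted tag sequences differ in length")
        correct += sum(1 for a, b in zip(g, p) if a == b)
        total += len(g)
    if len(gold_tags) != len(pred_tags):
        raise ValueError("gold/predicted sequence counts differ")
    return correct / total if total else 0.0


def compare_models(rows: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Pairwise metric differences between named models, in percentage points.

    Input metrics are on the [0, 1] scale (as printed in results tables);
    the output delta for (a, b) is ``100 * (metric_a - metric_b)``.
    """
    names = list(rows)
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    cols = list(rows[names[0]])
    for n in names[1:]:
        if list(rows[n]) != cols:
            raise ValueError(f"metric columns of {n!r} do not match {names[0]!r}")
    out = {}
    for a in names:
        for b in names:
            if a == b:
                continue
            out[f"{a}-{b}"] = {m: round(100.0 * (rows[a][m] - rows[b][m]), 10)
                               for m in cols}
    return pd.DataFrame(out).T[cols]


def percentage(numerator: float, denominator: float) -> float:
    """Share as a percentage, rounded half-up to 2 decimals (report style)."""
    if denominator == 0:
        return 0.0
    val = Decimal(numerator) / Decimal(denominator) * 100
    return float(val.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CategoryFrequency:
    records_with_mention: int
    total_records: int
    record_rate_pct: float
    mention_count: int
    top_surfaces: list[tuple[str, int]]
    top_share_pct: float


@dataclass
class FrequencyReport:
    total_records: int
    per_category: dict[str, CategoryFrequency]

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for cat, f in self.per_category.items():
            rows[cat] = {
                "records": f"{f.records_with_mention}/{f.total_records}",
                "record_rate_pct": f.record_rate_pct,
                "mentions": f.mention_count,
                "top_mentions": sum(c for _, c in f.top_surfaces),
                "top_share_pct": f.top_share_pct,
            }
        return pd.DataFrame(rows).T


def corpus_statistics(docs: Sequence[AnnotatedDocument], k: int = 10,
                      scheme: LabelScheme = DEFAULT_SCHEME) -> FrequencyReport:
    """Per-category record frequency, mention totals and top-k surface share.

    Mirrors the corpus summary tables of consultation-text studies: for each
    category, how many records mention it at least once, how often it is
    mentioned in total, and what share of mentions the k most frequent
    surface strings account for.
    """
    if not docs:
        raise ValueError("empty corpus")
    n = len(docs)
    per_cat: dict[str, CategoryFrequency] = {}
    for cat in scheme.categories:
        with_mention = 0
        surfaces: Counter[str] = Counter()
        for doc in docs:
            cat_spans = [s for s in doc.spans if s.label == cat]
            if cat_spans:
                with_mention += 1
            for s in cat_spans:
                surfaces[doc.text[s.start:s.end]] += 1
        total_mentions = sum(surfaces.values())
        top = surfaces.most_common(k)
        top_count = sum(c for _, c in top)
        per_cat[cat] = CategoryFrequency(
            records_with_mention=with_mention,
            total_records=n,
            record_rate_pct=percentage(with_mention, n),
            mention_count=total_mentions,
            top_surfaces=top,
            top_share_pct=percentage(top_count, total_mentions),
        )
    return FrequencyReport(total_records=n, per_category=per_cat)


def confusion_matrix(gold_tags: Sequence[Sequence[str]],
                     pred_tags: Sequence[Sequence[str]],
                     scheme: LabelScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Token-level category confusion counts with B-/I- pooled per category.

    Rows are gold categories (plus O), columns predictions; row sums equal
    the gold per-category token counts.
    """
    labels = list(scheme.categories) + ["O"]
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)

    def pool(tag: str) -> str:
        return "O" if tag == "O" else tag.split("-", 1)[1]

    for g_seq, p_seq in zip(gold_tags, pred_tags):
        if len(g_seq) != len(p_seq):
            raise ValueError("gold/predicted tag sequences differ in length")
        for g, p in zip(g_seq, p_seq):
            mat.loc[pool(g), pool(p)] += 1
    return mat


def plot_confusion(matrix: pd.DataFrame, path: str) -> None:
    """Render the confusion matrix as a heatmap (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.to_numpy(), cmap="Blues")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=45)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    ax.set_xlabel("predicted")
    ax.set_ylabel("gold")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
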