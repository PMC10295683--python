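"""Entity-level metrics, model comparison deltas, corpus statistics."""

import numpy as np
import pytest
from sklearn.metrics import accuracy_score

from _oracles import entity_prf_oracle, random_bio_tags
from ohcner.corpus_io import AnnotatedDocument, EntitySpan, TaggedSequence
from ohcner.evaluation import (
    ConfusionCounts,
    EntityMention,
    compare_models,
    confusion_matrix,
    corpus_statistics,
    entity_confusion,
    metrics_report,
    percentage,
    prf_metrics,
    token_accuracy,
)
from ohcner.labels import DEFAULT_SCHEME


def m(doc, start, end, cat):
    return EntityMention(doc, start, end, cat)


class TestEntityConfusion:
    def test_identical_sets(self):
        gold = {m("d1", 0, 2, "drug"), m("d1", 3, 5, "check")}
        counts = entity_confusion(gold, set(gold))["micro"]
        assert (counts.tp, counts.fp, counts.fn) == (2, 0, 0)

    def test_category_mismatch_is_both_fp_and_fn(self):
        gold = {m("d1", 0, 2, "drug"), m("d1", 3, 5, "check")}
        pred = {m("d1", 0, 2, "drug"), m("d1", 3, 5, "disease")}
        counts = entity_confusion(gold, pred)["micro"]
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 1)

    def test_matches_double_loop_matcher(self, rng):
        for _ in range(30):
            def random_set():
                return {m(f"d{rng.integers(3)}", int(s := rng.integers(20)),
                          int(s + rng.integers(1, 5)),
                          str(rng.choice(["drug", "check"])))
                        for _ in range(rng.integers(0, 15))}
            gold, pred = random_set(), random_set()
            counts = entity_confusion(gold, pred)["micro"]
            tp = sum(1 for p in pred for g in gold if p == g)
            assert counts.tp == tp
            assert counts.fp == len(pred) - tp
            assert counts.fn == len(gold) - tp

    def test_totals_invariant(self, rng):
        gold = {m("d", i, i + 1, "drug") for i in range(10)}
        pred = {m("d", i, i + 1, "drug") for i in range(5, 12)}
        for counts in entity_confusion(gold, pred).values():
            assert counts.tp >= 0
        micro = entity_confusion(gold, pred)["micro"]
        assert micro.tp + micro.fn == len(gold)
        assert micro.tp + micro.fp == len(pred)


class TestPrfMetrics:
    def test_balanced_half(self):
        out = prf_metrics(ConfusionCounts(tp=1, fp=1, fn=1))
        assert out == {"precision": 0.5, "recall": 0.5, "f1": 0.5}

    def test_zero_denominator_convention(self):
        out = prf_metrics(ConfusionCounts(tp=0, fp=0, fn=5))
        assert out == {"precision": 0.0, "recall": 0.0, "f1": 0.0}

    def test_f1_is_harmonic_mean(self, rng):
        for _ in range(50):
            c = ConfusionCounts(*(int(x) for x in rng.integers(0, 30, size=3)))
            out = prf_metrics(c)
            if out["precision"] + out["recall"] > 0:
                hm = (2 * out["precision"] * out["recall"]
                      / (out["precision"] + out["recall"]))
                assert abs(out["f1"] - hm) < 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0)


class TestTokenAccuracy:
    def test_identical_and_disjoint(self):
        assert token_accuracy([["O", "B-drug"]], [["O", "B-drug"]]) == 1.0
        assert token_accuracy([["O", "B-drug"]], [["B-drug", "O"]]) == 0.0

    def test_matches_sklearn_on_random_pairs(self, rng):
        gold = [random_bio_tags(rng, int(rng.integers(1, 30))) for _ in range(20)]
        pred = [random_bio_tags(rng, len(g)) for g in gold]
        ours = token_accuracy(gold, pred)
        flat_g = [t for seq in gold for t in seq]
        flat_p = [t for seq in pred for t in seq]
        assert abs(ours - accuracy_score(flat_g, flat_p)) < 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            token_accuracy([["O", "O"]], [["O"]])


class TestCompareModels:
    # test-set rows of the combined tagger (RBC) and the BiLSTM-CRF
    # baseline (BC) from the reference comparison table
    RBC = {"precision": 0.786, "recall": 0.829, "f1": 0.807, "accuracy": 0.812}
    BC = {"precision": 0.743, "recall": 0.759, "f1": 0.751, "accuracy": 0.754}

    def test_baseline_deltas_in_percentage_points(self):
        table = compare_models({"RBC": self.RBC, "BC": self.BC})
        row = table.loc["RBC-BC"]
        assert row["precision"] == pytest.approx(4.3, abs=1e-9)
        assert row["recall"] == pytest.approx(7.0, abs=1e-9)
        assert row["f1"] == pytest.approx(5.6, abs=1e-9)
        assert row["accuracy"] == pytest.approx(5.8, abs=1e-9)

    def test_identical_rows_zero_delta(self):
        table = compare_models({"a": self.RBC, "b": self.RBC})
        assert (table.loc["a-b"] == 0.0).all()

    def test_antisymmetry(self, rng):
        a = {k: float(v) for k, v in zip("prfa", rng.random(4))}
        b = {k: float(v) for k, v in zip("prfa", rng.random(4))}
        table = compare_models({"a": a, "b": b})
        assert np.allclose(table.loc["a-b"], -table.loc["b-a"])

    def test_column_mismatch_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            compare_models({"a": {"f1": 0.5}, "b": {"precision": 0.4}})


class TestCorpusStatistics:
    def test_percentage_formula_on_printed_counts(self):
        # top-10 share: 1790 of 2447 disease mentions
        assert percentage(1790, 2447) == 73.15

    def test_every_record_mentioning_gives_hundred(self):
        docs = [AnnotatedDocument(str(i), "血糖高", [EntitySpan(0, 2, "check")])
                for i in range(7)]
        report = corpus_statistics(docs)
        assert report.per_category["check"].record_rate_pct == 100.0

    def test_matches_generator_bookkeeping(self, small_corpus):
        docs, books = small_corpus
        report = corpus_statistics(docs)
        for cat in DEFAULT_SCHEME.categories:
            f = report.per_category[cat]
            assert f.records_with_mention == books.records_with_mention[cat]
            assert f.mention_count == books.mention_counts[cat]
            top = dict(f.top_surfaces)
            for surface, count in top.items():
                assert books.surface_counts[cat][surface] == count

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            corpus_statistics([])


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        tags = [["O", "B-drug", "I-drug", "B-check"]]
        mat = confusion_matrix(tags, tags)
        assert mat.loc["drug", "drug"] == 2
        assert mat.loc["check", "check"] == 1
        assert mat.loc["O", "O"] == 1
        off = mat.to_numpy().sum() - np.trace(mat.to_numpy())
        assert off == 0

    def test_all_outside_prediction_single_column(self):
        gold = [["B-drug", "I-drug", "O"]]
        pred = [["O", "O", "O"]]
        mat = confusion_matrix(gold, pred)
        assert mat["O"].sum() == 3
        assert mat.drop(columns="O").to_numpy().sum() == 0

    def test_row_sums_equal_gold_counts(self, rng):
        gold = [random_bio_tags(rng, 40) for _ in range(5)]
        pred = [random_bio_tags(rng, 40) for _ in range(5)]
        mat = confusion_matrix(gold, pred)

        def pool(t):
            return "O" if t == "O" else t[2:]

        for cat in mat.index:
            expected = sum(1 for seq in gold for t in seq if pool(t) == cat)
            assert mat.loc[cat].sum() == expected


class TestEntityLevelCrossCheck:
    def test_micro_prf_agrees_with_independent_scorer(self, rng):
        """Entity P/R/F1 equal an independently coded run matcher on random
        (often ill-formed) BIO prediction/gold pairs."""
        gold_seqs, pred_seqs, sequences = [], [], []
        for i in range(40):
            n = int(rng.integers(1, 40))
            gold_seqs.append(random_bio_tags(rng, n))
            pred_seqs.append(random_bio_tags(rng, n))
            sequences.append(TaggedSequence(["x"] * n, gold_seqs[-1],
                                            doc_id=f"d{i}"))
        from ohcner.evaluation import mentions_from_tags

        gold = mentions_from_tags(sequences, gold_seqs)
        pred = mentions_from_tags(sequences, pred_seqs)
        report = metrics_report(gold, pred)
        oracle = entity_prf_oracle(gold_seqs, pred_seqs)
        for metric in ("precision", "recall", "f1"):
            assert report.micro[metric] == pytest.approx(oracle[metric], abs=1e-12)
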