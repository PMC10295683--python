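"""Independent brute-force oracles and random-instance generators shared by
the unit and acceptance tests.

Everything here is deliberately written the slow, obvious way (explicit
loops, full path enumeration, set arithmetic over decoded runs) and never
calls the implementation paths it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np

from ohcner.corpus_io import AnnotatedDocument, EntitySpan
from ohcner.labels import DEFAULT_SCHEME

ALPHABET = "血糖高空腹餐后化验本人父亲运动手术担心头晕二甲双胍abcdef。！？"


# ---------------------------------------------------------------------------
# random annotated documents


def random_document(rng: np.random.Generator, doc_id: str,
                    min_len: int = 5, max_len: int = 120,
                    categories=DEFAULT_SCHEME.categories) -> AnnotatedDocument:
    """Random text with random valid non-overlapping spans."""
    n = int(rng.integers(min_len, max_len + 1))
    text = "".join(rng.choice(list(ALPHABET), size=n))
    spans = []
    pos = 0
    while pos < n - 1:
        if rng.random() < 0.4:
            length = int(rng.integers(1, min(8, n - pos) + 1))
            label = str(rng.choice(categories))
            spans.append(EntitySpan(pos, pos + length, label))
            pos += length + int(rng.integers(1, 4))
        else:
            pos += int(rng.integers(1, 5))
    return AnnotatedDocument(doc_id, text, spans)


# ---------------------------------------------------------------------------
# CRF enumeration


def enumerate_path_scores(P: np.ndarray, A: np.ndarray) -> dict[tuple, float]:
    """Score of every one of the k^n paths, term by term."""
    n, k = P.shape
    start, end = k, k + 1
    out = {}
    for path in itertools.product(range(k), repeat=n):
        s = A[start, path[0]]
        for t in range(n - 1):
            s += A[path[t], path[t + 1]]
        s += A[path[-1], end]
        for t in range(n):
            s += P[t, path[t]]
        out[path] = float(s)
    return out


def brute_log_partition(P: np.ndarray, A: np.ndarray) -> float:
    scores = np.array(list(enumerate_path_scores(P, A).values()))
    m = scores.max()
    return float(m + np.log(np.exp(scores - m).sum()))


def brute_viterbi_score(P: np.ndarray, A: np.ndarray) -> float:
    return max(enumerate_path_scores(P, A).values())


# ---------------------------------------------------------------------------
# attention / LSTM formula oracles


def attention_oracle(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Per-position softmax(QK^T/sqrt(d_k))V computed with explicit loops."""
    n, d_k = Q.shape
    out = np.zeros((n, V.shape[1]))
    for i in range(n):
        scores = np.array([Q[i] @ K[j] / np.sqrt(d_k) for j in range(n)])
        e = np.exp(scores - scores.max())
        w = e / e.sum()
        for j in range(n):
            out[i] += w[j] * V[j]
    return out


def ffn_oracle(Z, W1, b1, W2, b2) -> np.ndarray:
    out = np.zeros((Z.shape[0], W2.shape[1]))
    for i in range(Z.shape[0]):
        hidden = np.maximum(0.0, Z[i] @ W1 + b1)
        out[i] = hidden @ W2 + b2
    return out


def lstm_step_oracle(x, h_prev, c_prev, w_xh, w_hh, b_h):
    """Direct element-wise evaluation of the gate equations."""
    def sig(z):
        return 1.0 / (1.0 + np.exp(-z))

    i = sig(x @ w_xh["i"] + h_prev @ w_hh["i"] + b_h["i"])
    f = sig(x @ w_xh["f"] + h_prev @ w_hh["f"] + b_h["f"])
    o = sig(x @ w_xh["o"] + h_prev @ w_hh["o"] + b_h["o"])
    cand = np.tanh(x @ w_xh["c"] + h_prev @ w_hh["c"] + b_h["c"])
    c = i * cand + f * c_prev
    h = o * np.tanh(c)
    return h, c


# ---------------------------------------------------------------------------
# independent entity-level scorer


def decode_bio_runs(tags: list[str]) -> set[tuple[int, int, str]]:
    """Extract (start, end, category) runs from BIO tags, repairing a
    run-opening I- to B- — coded independently of the package decoder."""
    runs = set()
    i = 0
    n = len(tags)
    while i < n:
        if tags[i] == "O":
            i += 1
            continue
        cat = tags[i][2:]
        j = i + 1
        while j < n and tags[j] == f"I-{cat}":
            j += 1
        runs.add((i, j, cat))
        i = j
    return runs


def entity_prf_oracle(gold_seqs: list[list[str]], pred_seqs: list[list[str]]
                      ) -> dict[str, float]:
    """Micro precision/recall/F1 by double-loop exact matching of runs."""
    tp = fp = fn = 0
    for si, (g, p) in enumerate(zip(gold_seqs, pred_seqs)):
        gold_runs = {(si,) + r for r in decode_bio_runs(g)}
        pred_runs = {(si,) + r for r in decode_bio_runs(p)}
        for r in pred_runs:
            if r in gold_runs:
                tp += 1
            else:
                fp += 1
        for r in gold_runs:
            if r not in pred_runs:
                fn += 1
    pre = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    return {"precision": pre, "recall": rec, "f1": f1}


def random_bio_tags(rng: np.random.Generator, n: int,
                    categories=DEFAULT_SCHEME.categories) -> list[str]:
    """A random (possibly ill-formed) sequence from the 17-tag space."""
    tags = []
    for _ in range(n):
        r = rng.random()
        if r < 0.5:
            tags.append("O")
        else:
            cat = str(rng.choice(categories))
            tags.append(("B-" if r < 0.8 else "I-") + cat)
    return tags
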