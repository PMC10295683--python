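"""Linear-chain conditional random field over BIO tag sequences.

Given per-position emission scores ``P`` (n x k, from the BiLSTM head) and a
transition matrix ``A`` ((k+2) x (k+2), augmented with synthetic START and
END states at indices k and k+1), a path ``y`` scores

    s(X, y) = A[START, y_1] + sum_i A[y_i, y_{i+1}] + A[y_n, END]
            + sum_i P[i, y_i]

The path distribution is the Gibbs measure ``p(y|X) = exp s / Z`` with the
partition ``Z`` summed over all k^n paths by the forward algorithm in log
space; training minimises the negative log-likelihood ``log Z - s`` and
decoding maximises ``s`` by the Viterbi recursion.  Ties in Viterbi break
toward the lowest tag index.  An optional hard BIO mask forbids transitions
that would produce ill-formed tag runs (O -> I-x, B-x -> I-y, ...).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, no_grad, parameter
from .labels import DEFAULT_SCHEME, LabelScheme

IMPOSSIBLE = -1.0e4  # finite stand-in for -inf; keeps arithmetic NaN-free


class CRFError(ValueError):
    pass


def _check(P: np.ndarray, A: np.ndarray) -> tuple[int, int]:
    P = np.asarray(P)
    A = np.asarray(A)
    if P.ndim != 2 or P.shape[0] < 1:
        raise CRFError("emission matrix must be (n, k) with n >= 1")
    n, k = P.shape
    if A.shape != (k + 2, k + 2):
        raise CRFError(f"transition matrix must be ({k + 2}, {k + 2}), got {A.shape}")
    return n, k


def start_end(k: int) -> tuple[int, int]:
    """Indices of the synthetic START and END states in A."""
    return k, k + 1


def sequence_score(P: np.ndarray, y, A: np.ndarray) -> float:
    """Path score: transition terms (including START/END) plus emissions."""
    n, k = _check(P, A)
    y = np.asarray(y, dtype=np.int64)
    if y.shape != (n,):
        raise CRFError(f"path length {y.shape} does not match n={n}")
    if y.min() < 0 or y.max() >= k:
        raise CRFError("tag index out of range")
    start, end = start_end(k)
    score = A[start, y[0]] + A[y[-1], end]
    score += np.sum(A[y[:-1], y[1:]])
    score += np.sum(P[np.arange(n), y])
    return float(score)


def log_partition(P: np.ndarray, A: np.ndarray,
                  mask: np.ndarray | None = None) -> float:
    """log-sum-exp over all k^n path scores via the forward algorithm."""
    n, k = _check(P, A)
    P, A = np.asarray(P, float), np.asarray(A, float)
    if mask is not None:
        keep = np.asarray(mask, bool)
        if keep.shape != (n,):
            raise CRFError("mask length mismatch")
        if not keep.any():
            raise CRFError("empty (all-masked) sequence")
        P = P[keep]
        n = P.shape[0]
    start, end = start_end(k)
    alpha = A[start, :k] + P[0]
    for t in range(1, n):
        scores = alpha[:, None] + A[:k, :k] + P[t][None, :]
        m = scores.max(axis=0)
        alpha = m + np.log(np.exp(scores - m[None, :]).sum(axis=0))
    final = alpha + A[:k, end]
    m = final.max()
    return float(m + np.log(np.exp(final - m).sum()))


def crf_nll(P: np.ndarray, y, A: np.ndarray,
            mask: np.ndarray | None = None) -> float:
    """Negative log-likelihood of a gold path; non-negative."""
    P = np.asarray(P)
    if mask is not None:
        keep = np.asarray(mask, bool)
        P = P[keep]
        y = np.asarray(y)[keep]
    return log_partition(P, A) - sequence_score(P, y, A)


def viterbi_decode(P: np.ndarray, A: np.ndarray,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Maximum-scoring tag path; ties break toward the lowest tag index."""
    n, k = _check(P, A)
    P, A = np.asarray(P, float), np.asarray(A, float)
    if mask is not None:
        keep = np.asarray(mask, bool)
        if not keep.any():
            raise CRFError("empty (all-masked) sequence")
        P = P[keep]
        n = P.shape[0]
    start, end = start_end(k)
    delta = A[start, :k] + P[0]
    back = np.zeros((n, k), dtype=np.int64)
    for t in range(1, n):
        scores = delta[:, None] + A[:k, :k]  # (from, to)
        best_from = scores.argmax(axis=0)    # argmax returns lowest index on ties
        back[t] = best_from
        delta = scores[best_from, np.arange(k)] + P[t]
    final = delta + A[:k, end]
    path = np.zeros(n, dtype=np.int64)
    path[-1] = int(final.argmax())
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def bio_transition_mask(scheme: LabelScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Boolean (k+2)x(k+2) matrix of allowed transitions under BIO rules.

    Forbidden: any entry into START or out of END; START -> I-x; O -> I-x;
    B-x/I-x -> I-y for y != x.  Everything else is allowed.
    """
    tags = scheme.tags
    k = len(tags)
    start, end = start_end(k)
    allowed = np.ones((k + 2, k + 2), dtype=bool)
    allowed[:, start] = False
    allowed[end, :] = False
    allowed[start, end] = True  # empty-path degenerate transition
    for j, to_tag in enumerate(tags):
        if not to_tag.startswith("I-"):
            continue
        cat = to_tag[2:]
        allowed[start, j] = False
        for i, from_tag in enumerate(tags):
            if from_tag == f"B-{cat}" or from_tag == f"I-{cat}":
                continue
            allowed[i, j] = False
    return allowed


class LinearChainCRF:
    """Trainable CRF layer: learned transitions, batched NLL, decoding."""

    def __init__(self, num_tags: int, seed: int = 0,
                 constrain_bio: bool = False,
                 scheme: LabelScheme = DEFAULT_SCHEME):
        rng = np.random.default_rng(seed)
        self.k = num_tags
        self.A = parameter(rng.normal(0.0, 0.01, size=(num_tags + 2, num_tags + 2)))
        structural = np.ones((num_tags + 2, num_tags + 2), dtype=bool)
        start, end = start_end(num_tags)
        structural[:, start] = False   # nothing enters START
        structural[end, :] = False     # nothing leaves END
        if constrain_bio:
            if scheme.num_tags != num_tags:
                raise CRFError("BIO constraint scheme does not match tag count")
            structural &= bio_transition_mask(scheme)
        self.allowed = structural

    @property
    def params(self) -> dict[str, Tensor]:
        return {"crf.A": self.A}

    def effective_A(self) -> Tensor:
        """Learned transitions with structurally forbidden entries pinned."""
        keep = Tensor(self.allowed.astype(np.float64))
        return self.A * keep + Tensor((~self.allowed) * IMPOSSIBLE)

    def nll(self, emissions: Tensor, paths: np.ndarray,
            mask: np.ndarray) -> Tensor:
        """Mean negative log-likelihood over a padded batch.

        ``emissions`` is (B, n, k); ``paths`` integer (B, n); ``mask``
        boolean (B, n) with contiguous True prefixes (right padding).
        """
        B, n, k = emissions.shape
        if k != self.k:
            raise CRFError("emission tag dimension mismatch")
        paths = np.asarray(paths, dtype=np.int64)
        mask = np.asarray(mask, dtype=bool)
        lengths = mask.sum(axis=1)
        if (lengths < 1).any():
            raise CRFError("empty sequence in batch")
        A = self.effective_A()
        start, end = start_end(k)
        fmask = mask.astype(np.float64)

        # gold-path score -------------------------------------------------
        flat_emit = np.ravel_multi_index(
            (np.repeat(np.arange(B), n), np.tile(np.arange(n), B),
             paths.reshape(-1)), (B, n, k))
        emit_terms = emissions.take_flat(flat_emit).reshape(B, n)
        emit_score = (emit_terms * Tensor(fmask)).sum(axis=1)

        prev = paths[:, :-1].copy()
        nxt = paths[:, 1:].copy()
        pair_mask = (mask[:, :-1] & mask[:, 1:]).astype(np.float64)
        flat_trans = np.ravel_multi_index(
            (prev.reshape(-1), nxt.reshape(-1)), (k + 2, k + 2))
        trans_terms = A.take_flat(flat_trans).reshape(B, n - 1) if n > 1 \
            else Tensor(np.zeros((B, 0)))
        trans_score = (trans_terms * Tensor(pair_mask)).sum(axis=1) \
            if n > 1 else Tensor(np.zeros(B))

        first = paths[:, 0]
        last = paths[np.arange(B), lengths - 1]
        start_terms = A.take_flat(np.ravel_multi_index(
            (np.full(B, start), first), (k + 2, k + 2)))
        end_terms = A.take_flat(np.ravel_multi_index(
            (last, np.full(B, end)), (k + 2, k + 2)))
        gold = emit_score + trans_score + start_terms + end_terms

        # forward algorithm ----------------------------------------------
        alpha = A[start, :k].reshape(1, k) + emissions[:, 0, :]
        for t in range(1, n):
            scores = alpha.reshape(B, k, 1) + A[:k, :k].reshape(1, k, k) \
                + emissions[:, t, :].reshape(B, 1, k)
            new_alpha = scores.logsumexp(axis=1)
            m_t = Tensor(fmask[:, t:t + 1])
            alpha = m_t * new_alpha + (1.0 - m_t) * alpha
        logz = (alpha + A[:k, end].reshape(1, k)).logsumexp(axis=1)

        return (logz - gold).mean()

    def decode(self, emissions: np.ndarray,
               mask: np.ndarray | None = None) -> list[np.ndarray]:
        """Viterbi paths for a batch of emission matrices."""
        with no_grad():
            A = self.effective_A().data
        emissions = np.asarray(emissions)
        if emissions.ndim == 2:
            emissions = emissions[None]
            mask = None if mask is None else np.asarray(mask)[None]
        out = []
        for b in range(emissions.shape[0]):
            m = None if mask is None else mask[b]
            out.append(viterbi_decode(emissions[b], A, mask=m))
        return out
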