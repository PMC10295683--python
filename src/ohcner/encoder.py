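"""Contextual character embeddings from a compact self-attention encoder.

The encoder is a standard transformer stack: scaled dot-product attention,
multi-head projection, position-wise feed-forward, with residual connections
and layer normalization around each sub-layer and learned absolute position
embeddings (zero-initialised, so a zero-layer encoder reduces to the
character embedding lookup).  A small adapter contract lets an externally
pretrained encoder of matching dimension stand in for the bundled one; the
rest of the tagging stack is agnostic to which encoder produced the vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .autodiff import Tensor, concat, glorot, no_grad, parameter

NEG_INF = -1.0e9  # additive attention mask value; exp underflows to exactly 0


class ShapeError(ValueError):
    pass


def _lift(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


# ---------------------------------------------------------------------------
# functional building blocks


def scaled_dot_attention(Q, K, V, mask: np.ndarray | None = None,
                         return_weights: bool = False):
    """Scaled dot-product attention over one sequence (or a batch).

    Weights are ``softmax(Q K^T / sqrt(d_k))`` with masked key positions
    forced to zero weight; each unmasked row sums to 1.  Shapes: Q, K, V are
    ``(..., n, d_k)``; ``mask`` is a boolean vector of length n (True =
    real position).
    """
    Qt, was_tensor = _lift(Q)
    Kt, wk = _lift(K)
    Vt, wv = _lift(V)
    was_tensor = was_tensor or wk or wv
    if Qt.shape[-1] != Kt.shape[-1] or Kt.shape[-2] != Vt.shape[-2]:
        raise ShapeError(f"incompatible attention shapes {Qt.shape}/{Kt.shape}/{Vt.shape}")
    d_k = Qt.shape[-1]
    scores = (Qt @ Kt.T) * (1.0 / np.sqrt(d_k))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[-1] != Kt.shape[-2]:
            raise ShapeError("mask length does not match key count")
        if not mask.any(axis=-1, keepdims=False).all():
            raise ShapeError("attention over an all-masked sequence is undefined")
        scores = scores + np.where(mask, 0.0, NEG_INF)
    weights = scores.softmax(axis=-1)
    out = weights @ Vt
    if not was_tensor:
        out = out.data
        weights = weights.data
    if return_weights:
        return out, weights
    return out


def position_wise_ffn(Z, W1, b1, W2, b2):
    """Row-wise feed-forward ``max(0, Z W1 + b1) W2 + b2``."""
    Zt, was_tensor = _lift(Z)
    W1t, _ = _lift(W1)
    b1t, _ = _lift(b1)
    W2t, _ = _lift(W2)
    b2t, _ = _lift(b2)
    if Zt.shape[-1] != W1t.shape[0] or W1t.shape[1] != W2t.shape[0]:
        raise ShapeError("feed-forward weight shapes do not conform")
    out = (Zt @ W1t + b1t).relu() @ W2t + b2t
    return out if was_tensor else out.data


def multi_head_attention(X, Wq, Wk, Wv, Wo, h: int,
                         mask: np.ndarray | None = None):
    """Multi-head attention: per-head scaled dot-product attention on
    ``d/h``-dimensional projections, concatenated and projected by ``Wo``."""
    Xt, was_tensor = _lift(X)
    d = Xt.shape[-1]
    if d % h:
        raise ShapeError(f"model dimension {d} not divisible by head count {h}")
    d_k = d // h
    Q = Xt @ _lift(Wq)[0]
    K = Xt @ _lift(Wk)[0]
    V = Xt @ _lift(Wv)[0]
    heads = []
    for i in range(h):
        sl = slice(i * d_k, (i + 1) * d_k)
        idx = (Ellipsis, sl)
        heads.append(scaled_dot_attention(Q[idx], K[idx], V[idx], mask=mask))
    out = concat(heads, axis=-1) @ _lift(Wo)[0]
    return out if was_tensor else out.data


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=-1, keepdims=True)
    return gain * (centred * (var + eps) ** -0.5) + bias


# ---------------------------------------------------------------------------
# encoder stack


@dataclass
class EncoderConfig:
    vocab_size: int
    d: int = 64
    heads: int = 4
    layers: int = 2
    ffn_dim: int | None = None  # defaults to 4*d
    max_len: int = 512
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.d % self.heads:
            raise ShapeError("d must be divisible by the head count")
        if self.ffn_dim is None:
            self.ffn_dim = 4 * self.d


class ContextualEmbeddings:
    """Per-position contextual vectors plus per-layer attention weights."""

    def __init__(self, embeddings: np.ndarray, attention: list[np.ndarray]):
        self.embeddings = embeddings      # (n, d)
        self.attention = attention        # one (h, n, n) array per layer


class MiniEncoder:
    """A from-scratch transformer encoder over character ids.

    Intended for training the tagging stack end-to-end on corpora of this
    package's scale; the ``d=768``-class pretrained encoders plug in through
    :func:`pretrained_adapter` instead.
    """

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.params: dict[str, Tensor] = {
            "emb": parameter(rng.normal(0.0, 0.02, size=(c.vocab_size, c.d))),
            "pos": parameter(np.zeros((c.max_len, c.d))),
        }
        for l in range(c.layers):
            p = self.params
            p[f"L{l}.Wq"] = glorot(rng, c.d, c.d)
            p[f"L{l}.Wk"] = glorot(rng, c.d, c.d)
            p[f"L{l}.Wv"] = glorot(rng, c.d, c.d)
            p[f"L{l}.Wo"] = glorot(rng, c.d, c.d)
            p[f"L{l}.ln1_g"] = parameter(np.ones(c.d))
            p[f"L{l}.ln1_b"] = parameter(np.zeros(c.d))
            p[f"L{l}.W1"] = glorot(rng, c.d, c.ffn_dim)
            p[f"L{l}.b1"] = parameter(np.zeros(c.ffn_dim))
            p[f"L{l}.W2"] = glorot(rng, c.ffn_dim, c.d)
            p[f"L{l}.b2"] = parameter(np.zeros(c.d))
            p[f"L{l}.ln2_g"] = parameter(np.ones(c.d))
            p[f"L{l}.ln2_b"] = parameter(np.zeros(c.d))

    @property
    def d(self) -> int:
        return self.config.d

    def forward(self, token_ids: np.ndarray, mask: np.ndarray | None = None,
                train: bool = False, rng: np.random.Generator | None = None,
                collect_attention: list | None = None) -> Tensor:
        """Contextual embeddings for one sequence of character ids.

        ``mask`` marks real positions (True); padded positions neither
        attend nor are attended to, so their values never influence real
        outputs.
        """
        ids = np.asarray(token_ids, dtype=np.int64)
        if ids.ndim != 1:
            raise ShapeError("forward expects a single id sequence")
        if ids.size == 0:
            raise ShapeError("empty sequence")
        if ids.min() < 0 or ids.max() >= self.config.vocab_size:
            raise ValueError("token id out of vocabulary range")
        if ids.size > self.config.max_len:
            raise ShapeError(f"sequence longer than max_len={self.config.max_len}")
        n = ids.size
        x = self.params["emb"][ids] + self.params["pos"][np.arange(n)]
        x = self._dropout(x, train, rng)
        for l in range(self.config.layers):
            p = self.params
            if collect_attention is not None:
                att = self._attention_weights(x, l, mask)
                collect_attention.append(att)
            a = multi_head_attention(x, p[f"L{l}.Wq"], p[f"L{l}.Wk"],
                                     p[f"L{l}.Wv"], p[f"L{l}.Wo"],
                                     self.config.heads, mask=mask)
            x = layer_norm(x + self._dropout(a, train, rng),
                           p[f"L{l}.ln1_g"], p[f"L{l}.ln1_b"])
            f = position_wise_ffn(x, p[f"L{l}.W1"], p[f"L{l}.b1"],
                                  p[f"L{l}.W2"], p[f"L{l}.b2"])
            x = layer_norm(x + self._dropout(f, train, rng),
                           p[f"L{l}.ln2_g"], p[f"L{l}.ln2_b"])
        return x

    def _attention_weights(self, x: Tensor, layer: int,
                           mask: np.ndarray | None) -> np.ndarray:
        c = self.config
        p = self.params
        d_k = c.d // c.heads
        with no_grad():
            Q = (x @ p[f"L{layer}.Wq"]).data
            K = (x @ p[f"L{layer}.Wk"]).data
        weights = []
        for i in range(c.heads):
            sl = slice(i * d_k, (i + 1) * d_k)
            scores = Q[:, sl] @ K[:, sl].T / np.sqrt(d_k)
            if mask is not None:
                scores = scores + np.where(np.asarray(mask, bool), 0.0, NEG_INF)
            scores -= scores.max(axis=-1, keepdims=True)
            e = np.exp(scores)
            weights.append(e / e.sum(axis=-1, keepdims=True))
        return np.stack(weights)

    def _dropout(self, x: Tensor, train: bool,
                 rng: np.random.Generator | None) -> Tensor:
        rate = self.config.dropout
        if not train or rate <= 0.0 or rng is None:
            return x
        keep = (rng.random(x.shape) >= rate).astype(np.float64) / (1.0 - rate)
        return x * Tensor(keep)

    def encode(self, token_ids: Sequence[int],
               mask: np.ndarray | None = None) -> ContextualEmbeddings:
        """Inference-mode contract: vectors plus attention maps as arrays."""
        attention: list[np.ndarray] = []
        with no_grad():
            out = self.forward(np.asarray(token_ids), mask=mask,
                               collect_attention=attention)
        return ContextualEmbeddings(out.data, attention)

    # adapter-protocol surface: callable returning plain arrays
    def __call__(self, token_ids: Sequence[int],
                 mask: np.ndarray | None = None) -> np.ndarray:
        return self.encode(token_ids, mask=mask).embeddings

    @property
    def dim(self) -> int:
        return self.config.d


class EncoderAdapter:
    """Wrap an external per-character encoder behind the encode contract.

    The handle must expose ``dim`` and be callable as
    ``handle(token_ids, mask) -> (n, dim) array``.  Wrapped outputs enter
    the tagging stack as constants (the external encoder is not fine-tuned
    through this adapter).
    """

    def __init__(self, handle, expected_dim: int):
        if getattr(handle, "dim", None) != expected_dim:
            raise ShapeError(
                f"adapter dimension {getattr(handle, 'dim', None)} does not "
                f"match configured d={expected_dim}")
        self._handle = handle
        self.dim = expected_dim
        self.params: dict[str, Tensor] = {}

    @property
    def d(self) -> int:
        return self.dim

    def forward(self, token_ids, mask=None, train=False, rng=None,
                collect_attention=None) -> Tensor:
        out = np.asarray(self._handle(token_ids, mask))
        if out.ndim != 2 or out.shape[1] != self.dim:
            raise ShapeError(f"external encoder returned shape {out.shape}")
        return Tensor(out)

    def encode(self, token_ids, mask=None) -> ContextualEmbeddings:
        return ContextualEmbeddings(self.forward(token_ids, mask).data, [])


def pretrained_adapter(encoder_handle, expected_dim: int) -> EncoderAdapter:
    """Validate and wrap an externally pretrained encoder handle."""
    return EncoderAdapter(encoder_handle, expected_dim)
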