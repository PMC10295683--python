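"""Bidirectional LSTM semantic encoding and the linear emission projection.

The recurrence is the standard gated cell: input, forget and output gates via
the logistic function of affine maps, a tanh candidate state, cell update
``c_t = i_t*c'_t + f_t*c_{t-1}`` and output ``h_t = o_t*tanh(c_t)``.  Forward
and backward streams are concatenated per position and projected to per-tag
emission scores for the CRF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autodiff import Tensor, concat, glorot, parameter, stack

GATES = ("i", "f", "o", "c")  # input, forget, output, candidate


class ShapeError(ValueError):
    pass


@dataclass
class LSTMParams:
    """One direction's weights: w_xh_* (input->hidden), w_hh_* (recurrent),
    b_h_* per gate."""

    w_xh: dict[str, Tensor]
    w_hh: dict[str, Tensor]
    b_h: dict[str, Tensor]

    @property
    def hidden_size(self) -> int:
        return self.w_hh["i"].shape[0]

    @classmethod
    def init(cls, rng: np.random.Generator, input_dim: int, hidden: int) -> "LSTMParams":
        w_xh = {g: glorot(rng, input_dim, hidden) for g in GATES}
        w_hh = {g: glorot(rng, hidden, hidden) for g in GATES}
        b_h = {g: parameter(np.zeros(hidden)) for g in GATES}
        b_h["f"].data[:] = 1.0  # forget-gate bias init; aids gradient flow
        return cls(w_xh, w_hh, b_h)

    def named(self, prefix: str) -> dict[str, Tensor]:
        out = {}
        for g in GATES:
            out[f"{prefix}.w_xh_{g}"] = self.w_xh[g]
            out[f"{prefix}.w_hh_{g}"] = self.w_hh[g]
            out[f"{prefix}.b_h_{g}"] = self.b_h[g]
        return out


@dataclass
class LSTMState:
    """Hidden and cell vectors (plus the last candidate) after a step."""

    h: Tensor
    c: Tensor
    candidate: Tensor | None = None

    @classmethod
    def zeros(cls, batch_shape: tuple[int, ...], hidden: int) -> "LSTMState":
        z = Tensor(np.zeros(batch_shape + (hidden,)))
        return cls(h=z, c=z)


def _lift(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def lstm_step(x_t, state: LSTMState, params: LSTMParams) -> LSTMState:
    """One gated-cell update; ``x_t`` is ``(..., input_dim)``."""
    xt, _ = _lift(x_t)
    if not np.all(np.isfinite(xt.data)):
        raise ValueError("non-finite LSTM input")
    if xt.shape[-1] != params.w_xh["i"].shape[0]:
        raise ShapeError(
            f"input dim {xt.shape[-1]} != {params.w_xh['i'].shape[0]}")
    h, c = state.h, state.c

    def gate(name: str) -> Tensor:
        return xt @ params.w_xh[name] + h @ params.w_hh[name] + params.b_h[name]

    i_t = gate("i").sigmoid()
    f_t = gate("f").sigmoid()
    o_t = gate("o").sigmoid()
    cand = gate("c").tanh()
    c_t = i_t * cand + f_t * c
    h_t = o_t * c_t.tanh()
    return LSTMState(h=h_t, c=c_t, candidate=cand)


def _run_direction(emb: Tensor, params: LSTMParams, mask: np.ndarray,
                   reverse: bool) -> list[Tensor]:
    """Unroll one stream over time with mask-gated state carries.

    ``emb`` is ``(B, n, d)``; padded steps (mask 0) leave the state
    untouched, so right-padding never leaks into real positions.
    """
    B, n, _ = emb.shape
    H = params.hidden_size
    state = LSTMState.zeros((B,), H)
    order = range(n - 1, -1, -1) if reverse else range(n)
    outputs: dict[int, Tensor] = {}
    for t in order:
        x_t = emb[:, t, :]
        new = lstm_step(x_t, state, params)
        m = Tensor(mask[:, t:t + 1].astype(np.float64))
        state = LSTMState(h=m * new.h + (1.0 - m) * state.h,
                          c=m * new.c + (1.0 - m) * state.c)
        outputs[t] = state.h
    return [outputs[t] for t in range(n)]


def bilstm_encode(embeddings, params_fwd: LSTMParams, params_bwd: LSTMParams,
                  mask: np.ndarray | None = None) -> Tensor:
    """Per-position concatenation ``[h_fwd_t ; h_bwd_t]`` of the two streams.

    Accepts ``(n, d)`` (one sequence) or ``(B, n, d)``; returns the matching
    shape with last dimension ``2H``.
    """
    emb, was_tensor = _lift(embeddings)
    single = emb.ndim == 2
    if single:
        emb = emb.reshape(1, *emb.shape)
    B, n, _ = emb.shape
    if n == 0:
        raise ShapeError("empty sequence")
    if mask is None:
        mask = np.ones((B, n), dtype=bool)
    mask = np.asarray(mask, dtype=bool).reshape(B, n)
    fwd = _run_direction(emb, params_fwd, mask, reverse=False)
    bwd = _run_direction(emb, params_bwd, mask, reverse=True)
    per_pos = [concat([f, b], axis=-1) for f, b in zip(fwd, bwd)]
    out = stack(per_pos, axis=1)  # (B, n, 2H)
    if single:
        out = out.reshape(n, out.shape[-1])
    return out if was_tensor else out.data


class BiLSTM:
    """Single-layer bidirectional LSTM with named, serializable parameters."""

    def __init__(self, input_dim: int, hidden: int = 128, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.hidden = hidden
        self.fwd = LSTMParams.init(rng, input_dim, hidden)
        self.bwd = LSTMParams.init(rng, input_dim, hidden)

    @property
    def params(self) -> dict[str, Tensor]:
        return {**self.fwd.named("fwd"), **self.bwd.named("bwd")}

    def forward(self, embeddings: Tensor, mask: np.ndarray | None = None) -> Tensor:
        return bilstm_encode(embeddings, self.fwd, self.bwd, mask=mask)


class EmissionHead:
    """Affine map from BiLSTM features to per-tag scores (the CRF's P),
    with dropout on its input during training only."""

    def __init__(self, input_dim: int, num_tags: int, dropout: float = 0.1,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dropout = dropout
        self.W = glorot(rng, input_dim, num_tags)
        self.b = parameter(np.zeros(num_tags))

    @property
    def params(self) -> dict[str, Tensor]:
        return {"emit.W": self.W, "emit.b": self.b}

    def forward(self, states: Tensor, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        if train and self.dropout > 0.0 and rng is not None:
            keep = (rng.random(states.shape) >= self.dropout)
            states = states * Tensor(keep.astype(np.float64) / (1.0 - self.dropout))
        return states @ self.W + self.b


def project_emissions(states, W, b, dropout: float = 0.0,
                      train: bool = False,
                      rng: np.random.Generator | None = None):
    """Functional emission projection: ``states @ W + b`` per position."""
    st, was_tensor = _lift(states)
    Wt, _ = _lift(W)
    bt, _ = _lift(b)
    if st.shape[-1] != Wt.shape[0]:
        raise ShapeError("projection input dim mismatch")
    if train and dropout > 0.0 and rng is not None:
        keep = (rng.random(st.shape) >= dropout)
        st = st * Tensor(keep.astype(np.float64) / (1.0 - dropout))
    out = st @ Wt + bt
    return out if was_tensor else out.data
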