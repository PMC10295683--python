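"""The full tagging stack: contextual encoder -> BiLSTM -> emission head ->
linear-chain CRF, with JSON checkpointing.

The encoder slot accepts either the bundled :class:`~ohcner.encoder.MiniEncoder`
or an :class:`~ohcner.encoder.EncoderAdapter` around an externally pretrained
model of matching dimension; parameters are partitioned into an encoder group
and a head (BiLSTM + projection + CRF) group so the two can train at
different learning rates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, no_grad, stack
from .bilstm import BiLSTM, EmissionHead
from .corpus_io import TaggedSequence, bio_to_spans
from .crf import LinearChainCRF
from .encoder import EncoderAdapter, EncoderConfig, MiniEncoder
from .labels import DEFAULT_SCHEME, LabelScheme
from .vocab import UNK_ID, Vocab

CHECKPOINT_FORMAT = "ohcner-checkpoint-v1"


@dataclass
class ModelConfig:
    d: int = 64                # encoder model dimension (pooler_fc_size)
    heads: int = 4
    layers: int = 2
    hidden: int = 128          # BiLSTM hidden size per direction
    dropout: float = 0.1
    char_dropout: float = 0.0    # train-time char->UNK rate
    entity_dropout: float = 0.15  # train-time whole-mention->UNK rate
    max_len: int = 128         # sequence_length
    constrain_bio: bool = False
    seed: int = 0


class NerTagger:
    """Character-level NER model over a fixed label scheme."""

    def __init__(self, vocab: Vocab, config: ModelConfig | None = None,
                 scheme: LabelScheme = DEFAULT_SCHEME,
                 encoder=None):
        self.vocab = vocab
        config = config if config is not None else ModelConfig()
        self.config = config
        self.scheme = scheme
        if encoder is None:
            encoder = MiniEncoder(
                EncoderConfig(vocab_size=len(vocab), d=config.d,
                              heads=config.heads, layers=config.layers,
                              max_len=config.max_len, dropout=config.dropout),
                seed=config.seed)
        elif encoder.d != config.d:
            raise ValueError(
                f"encoder dimension {encoder.d} != configured d={config.d}")
        self.encoder = encoder
        self.bilstm = BiLSTM(config.d, config.hidden, seed=config.seed + 1)
        self.head = EmissionHead(2 * config.hidden, scheme.num_tags,
                                 dropout=config.dropout, seed=config.seed + 2)
        self.crf = LinearChainCRF(scheme.num_tags, seed=config.seed + 3,
                                  constrain_bio=config.constrain_bio,
                                  scheme=scheme)

    # -- parameter groups --------------------------------------------------

    def encoder_parameters(self) -> dict[str, Tensor]:
        return {f"encoder.{k}": v for k, v in self.encoder.params.items()}

    def head_parameters(self) -> dict[str, Tensor]:
        return {**{f"bilstm.{k}": v for k, v in self.bilstm.params.items()},
                **self.head.params, **self.crf.params}

    def parameters(self) -> dict[str, Tensor]:
        return {**self.encoder_parameters(), **self.head_parameters()}

    # -- forward -----------------------------------------------------------

    def _batch_arrays(self, sequences: list[TaggedSequence]
                      ) -> tuple[list[list[int]], np.ndarray, np.ndarray]:
        ids = [self.vocab.encode(seq.tokens) for seq in sequences]
        n_max = max(len(i) for i in ids)
        B = len(ids)
        mask = np.zeros((B, n_max), dtype=bool)
        paths = np.zeros((B, n_max), dtype=np.int64)
        for b, seq in enumerate(sequences):
            mask[b, :len(seq)] = True
            paths[b, :len(seq)] = [self.scheme.tag_index(t) for t in seq.tags]
        return ids, paths, mask

    def _emissions(self, ids: list[list[int]], n_max: int,
                   train: bool = False,
                   rng: np.random.Generator | None = None) -> Tensor:
        rows = []
        for seq_ids in ids:
            seq_ids = np.asarray(seq_ids)
            if train and rng is not None and self.config.char_dropout > 0:
                # char-level dropout to UNK: the tagger must learn to label
                # unseen surfaces from their context
                drop = rng.random(seq_ids.shape) < self.config.char_dropout
                seq_ids = np.where(drop, UNK_ID, seq_ids)
            enc = self.encoder.forward(seq_ids, train=train, rng=rng)
            pad = n_max - len(seq_ids)
            if pad:
                enc = concat([enc, Tensor(np.zeros((pad, self.config.d)))], axis=0)
            rows.append(enc)
        emb = stack(rows, axis=0)                       # (B, n_max, d)
        mask = np.array([[i < len(s) for i in range(n_max)] for s in ids])
        feats = self.bilstm.forward(emb, mask=mask)     # (B, n_max, 2H)
        return self.head.forward(feats, train=train, rng=rng)

    def loss(self, sequences: list[TaggedSequence], train: bool = True,
             rng: np.random.Generator | None = None) -> Tensor:
        """Mean CRF negative log-likelihood over a batch of sequences."""
        ids, paths, mask = self._batch_arrays(sequences)
        if train and rng is not None and self.config.entity_dropout > 0:
            ids = self._mask_entities(ids, sequences, rng)
        emissions = self._emissions(ids, mask.shape[1], train=train, rng=rng)
        return self.crf.nll(emissions, paths, mask)

    def _mask_entities(self, ids: list[list[int]],
                       sequences: list[TaggedSequence],
                       rng: np.random.Generator) -> list[list[int]]:
        """Mention-masking augmentation: replace whole gold mentions by UNK
        at the configured rate, so unseen surfaces in familiar carrier
        contexts still decode correctly at test time."""
        out = []
        for seq_ids, seq in zip(ids, sequences):
            seq_ids = list(seq_ids)
            for span in bio_to_spans(seq.tags, self.scheme):
                if rng.random() < self.config.entity_dropout:
                    for i in range(span.start, span.end):
                        seq_ids[i] = UNK_ID
            out.append(seq_ids)
        return out

    def predict_tags(self, sequences: list[TaggedSequence]) -> list[list[str]]:
        """Viterbi-decode BIO tags for each sequence."""
        out: list[list[str]] = []
        batch = 32
        for lo in range(0, len(sequences), batch):
            chunk = sequences[lo:lo + batch]
            ids = [self.vocab.encode(seq.tokens) for seq in chunk]
            n_max = max(len(i) for i in ids)
            mask = np.array([[i < len(s) for i in range(n_max)] for s in ids])
            with no_grad():
                emissions = self._emissions(ids, n_max, train=False)
            paths = self.crf.decode(emissions.data, mask=mask)
            for path in paths:
                out.append([self.scheme.index_tag(int(i)) for i in path])
        return out

    def predict_spans(self, text: str, doc_id: str = ""):
        """Tag raw (already normalized) text and return entity spans."""
        from .corpus_io import AnnotatedDocument, slice_document

        doc = AnnotatedDocument(doc_id, text, [])
        slices = slice_document(doc, self.config.max_len, self.scheme)
        tags = self.predict_tags(slices)
        spans = []
        for seq, seq_tags in zip(slices, tags):
            for s in bio_to_spans(seq_tags, self.scheme):
                spans.append(s.shifted(seq.offset))
        return spans

    # -- checkpointing -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(state) != set(params):
            missing = set(params) ^ set(state)
            raise ValueError(f"checkpoint parameter mismatch: {sorted(missing)[:5]}")
        for k, v in state.items():
            arr = np.asarray(v, dtype=np.float64)
            if arr.shape != params[k].data.shape:
                raise ValueError(f"shape mismatch for {k}")
            params[k].data[...] = arr

    def save(self, path: str | Path) -> None:
        """Single-file JSON archive: config, vocabulary, labels, parameters."""
        if isinstance(self.encoder, EncoderAdapter):
            raise ValueError("cannot checkpoint an externally adapted encoder")
        payload = {
            "format": CHECKPOINT_FORMAT,
            "config": asdict(self.config),
            "categories": list(self.scheme.categories),
            "vocab": self.vocab.itos[2:],
            "params": {k: v.tolist() for k, v in self.state_dict().items()},
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "NerTagger":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != CHECKPOINT_FORMAT:
            raise ValueError("not an ohcner checkpoint")
        scheme = LabelScheme(tuple(payload["categories"]))
        model = cls(Vocab(payload["vocab"]), ModelConfig(**payload["config"]),
                    scheme=scheme)
        model.load_state_dict({k: np.asarray(v)
                               for k, v in payload["params"].items()})
        return model
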