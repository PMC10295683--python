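# Methods

## Task and data model

The toolkit labels Chinese consultation text at the character level with BIO
tags over eight entity categories: tests/examinations (`check`), diseases,
drugs, lifestyle (`life`), emotions (`mood`), socio-demographic context
(`social`), symptoms, and treatments (`treat`) — 17 tags including `O`.
Character tokenization is the standard choice for Chinese clinical NER; the
toolkit never segments words.

Annotations enter as Doccano-style JSONL (`{"id", "text", "label":
[[start, end, category], ...]}`) with 0-based half-open offsets. Validation
rejects out-of-bounds or overlapping spans; an opt-in `keep_longest` repair
drops the shorter of an overlapping pair. Normalization replaces emoji with
colon-delimited ASCII shortcodes from a bundled table (unknown emoji map to
`:emoji:`) and removes control/format characters, returning an offset map so
span positions can be remapped. Long documents are sliced to a maximum
length (default 128 characters) at sentence-ending punctuation where
possible, never through an entity; concatenating slices reproduces the
document, and the multiset of (surface, label) mentions is conserved —
both properties are tested exhaustively on random documents.

Splitting is test-first (fraction, default 0.1, or a fixed count), then the
remainder is divided train:validation 5:1 with floor rounding on the
validation side; all shuffling is seed-deterministic.

## Model

The tagger is encoder → BiLSTM → emission projection → linear-chain CRF.

**Encoder.** Scaled dot-product attention, multi-head projection and a
position-wise ReLU feed-forward are composed into standard transformer
blocks. Residual connections and layer normalization are included even
though they are not part of the minimal attention equations: without them
stacks of more than one block do not train. Position embeddings are learned,
absolute, and zero-initialized, so a zero-layer encoder degenerates exactly
to the character-embedding lookup (a tested contract). Padding positions are
masked with a −1e9 additive score, which underflows to exactly zero weight,
so padded batches reproduce unpadded outputs bitwise at real positions.
An adapter wraps any external per-character encoder exposing vectors of the
configured dimension; adapted encoders are treated as frozen feature
extractors and cannot be checkpointed by this package.

**BiLSTM.** One layer per direction, standard gates; the cell update uses
the previous cell state `c_{t−1}` (the conventional form). Forget-gate
biases initialize to 1. Masked (padded) steps carry state through unchanged,
so right-padding never leaks into real positions. Hidden size defaults to
128 per direction; the from-scratch synthetic experiments use 64.

**CRF.** Transitions live in a `(k+2)×(k+2)` matrix with synthetic START
(index k) and END (k+1); entries into START and out of END are structurally
pinned to −1e4 (a finite stand-in for −∞ that keeps gradients NaN-free).
The partition function is computed by the forward algorithm in log space
(stable for scores up to ±1e3, tested); the loss is the exact negative
log-likelihood averaged over the batch; decoding is Viterbi with ties broken
toward the lowest tag index, so the all-tie decode is deterministically all-O
(tag 0 is O). Transitions are learned freely by default; an opt-in hard BIO
mask forbids `START→I-x`, `O→I-x`, and `B-x/I-x→I-y (y≠x)`, and decodes
under the mask are repair-free by construction (property-tested).
Ill-formed predicted BIO from the unconstrained model is repaired by
reading a run-opening `I-x` as `B-x`.

All layers run on a small reverse-mode autodiff core over float64 NumPy
arrays (the only differentiable operations the stack needs: broadcasted
arithmetic, matmul, the activations, softmax/log-sum-exp with exact
gradients, gather/scatter indexing). Gradients are verified against central
finite differences in the test suite.

## Training protocol

AdamW (decoupled weight decay 0.01, applied to weight matrices only — never
biases or normalization gains) with two parameter groups: the encoder at a
base learning rate and the BiLSTM + projection + CRF head at five times that
rate. The schedule ramps linearly from 0 to the peak over the first tenth of
total optimizer steps, then follows a half-cosine to 0 at the final step
("one-tenth of total training" is read as optimizer steps, not epochs;
config-overridable). Gradients are clipped to global norm 1.0 per step.
After each epoch, validation entity-level macro F1 (unweighted mean of
per-category F1) is computed; the best checkpoint is kept under a strict
`>` improvement rule, and training stops after 10 consecutive
non-improving epochs or at the epoch cap (default 50). Runs are bitwise
reproducible under a seed. Five-fold cross-validation partitions the slices
seed-deterministically, holds each fold out once, re-splits the remainder
5:1, and reports per-fold and mean macro F1.

Defaults mirror the fine-tuning setting for a large pretrained encoder:
encoder rate 3e-5, batch 16, 50 epochs, dropout 0.1 at the input and hidden
layers, sequence length 128. Training the bundled tiny encoder from random
initialization is a different regime: the synthetic-corpus experiments use
encoder rate 3e-3 (head 1.5e-2, preserving the 5× ratio), d=48 with one
layer and two heads, and BiLSTM hidden 64, which converges within the
30-epoch budget those experiments use.

Two train-time augmentations address out-of-vocabulary generalization:
character-level dropout to `<unk>` (off by default) and mention masking
(default rate 0.15), which replaces an entire gold mention's characters with
`<unk>` so the model learns to tag unseen surfaces from their carrier
context. Mention masking exists because error analysis on synthetic corpora
showed misses concentrated on rare-category mentions whose surfaces never
occur in training: their characters carry randomly initialized embeddings,
and without masking the model fractures their boundaries instead of trusting
context.

## Evaluation

Entity-level scoring uses exact match: a predicted mention counts only if
document, span boundaries and category all equal a gold mention (set
intersection). Precision, recall and F1 follow the usual definitions with
zero denominators mapping to 0. The headline aggregate is the macro average
over the eight categories; micro (pooled) metrics are reported alongside.
"Accuracy" is token-level tag accuracy over non-padding positions, because
true negatives are undefined for open entity sets. Model comparison reports
pairwise metric differences in percentage points. Corpus statistics report,
per category, the share of records with at least one mention, total mention
counts, and the share of mentions covered by the top-k surface strings;
percentages are rounded half-up to two decimals. The token-level confusion
matrix pools `B-x`/`I-x` into `x`. The suite cross-checks entity metrics
against an independently coded run matcher and token accuracy against
scikit-learn.

## Synthetic corpus generator

Real consultation corpora from health communities are not freely
redistributable, so the pipeline is exercised on generated stand-ins. Each
document concatenates clause templates whose slot is filled with a gazetteer
surface, recording one gold span per insertion; a filler clause closes the
document. Per-category inclusion probabilities default to the record
frequencies characteristic of diabetes consultation corpora (social 0.90,
check 0.80, disease 0.80, drug 0.56, symptom 0.36, life 0.26, treat 0.22,
mood 0.08); gazetteers carry the characteristic high-frequency surfaces
(fasting blood glucose, metformin, hypertension, worry, ...) plus fillers;
documents cap at 128 characters by default (raise the cap to stress the
slicer). An optional noise pass substitutes characters outside gold spans
at a configured rate, emulating colloquial typos while keeping annotated
surfaces exact. Generation is seed-deterministic and returns exact
bookkeeping (per-category record counts, mention counts, surface counts)
that must equal `corpus_statistics` output — a tested loop closure.

One consistency rule the generator enforces (and the suite audits): carrier
templates and fillers must not contain any gazetteer surface as unannotated
text, or the generated gold would contradict the annotation scheme it
emulates.

What the generator does not emulate: natural Chinese syntax, discourse
structure, genuine misspellings-with-intent, nested or discontinuous
mentions, annotation disagreement. Passing the synthetic learnability check
therefore demonstrates that the pipeline wiring, optimization and decoding
work end-to-end — not that the model reaches any particular accuracy on
real consultation text.

## Problem sizes used in the checks

The acceptance script trains on a 200-document generated corpus (protocol
split 5:1 after a 15% test hold-out) and evaluates on a 300-document freshly
generated held-out corpus. The larger held-out set is an estimator-variance
choice: a 30-slice fold can contain a single rare-category mention, which
quantizes that category's F1 — and hence the macro — to coarse steps. CRF
exactness is checked against full `kⁿ` enumeration at `n ≤ 5, k ≤ 5` (200
random instances), attention/FFN/LSTM against per-position formula oracles,
and the BIO round-trip and slicing conservation over 1000 random documents.

## Known limitations

- The bundled encoder is intentionally small; headline-quality accuracy on
  real corpora would come from plugging a pretrained encoder into the
  adapter and fine-tuning, which this package supports only at the
  interface level (it ships no pretrained weights).
- Masked-language-model pretraining of the encoder is documented but not
  implemented; only supervised fine-tuning is.
- Single-layer BiLSTM, first-order CRF, exact inference only.
- The emission head applies dropout on its input; whether dropout belongs
  between the BiLSTM and CRF is ambiguous in the usual protocol
  descriptions, and the config follows the stated input/hidden rates
  literally.
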