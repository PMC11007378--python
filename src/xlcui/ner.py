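"""Span-scoring nested named-entity recognition.

The recognizer enumerates every candidate span (start, end) up to a maximum
length, scores each span for each semantic-group label with an independent
sigmoid, and keeps everything above a threshold — so nested and overlapping
mentions are first-class predictions, not exceptions.

Token encodings concatenate three views: a learned combination of the last
``context_layers`` outputs of a small trainable contextual stack, a static
word embedding, and max-pooled character-convolution features (so
out-of-vocabulary tokens still get informative vectors). Span representations
are produced by a multi-layer LSTM read over the span's token encodings with
learned per-layer combination weights; training minimizes binary
cross-entropy over all candidate/label pairs with Adam.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from ._autograd import Adam, Tensor, concat, gather
from ._tokenize import Token, tokenize
from .documents import AnnotatedDocument, Mention
from .terminology import SEMANTIC_GROUPS

logger = logging.getLogger(__name__)

_PAD, _UNK = 0, 1


@dataclass
class NerConfig:
    context_layers: int = 4       # contextual-stack outputs combined, as in a
                                  # last-4-layers transformer read-out
    word_dim: int = 20
    char_dim: int = 16
    char_emb_dim: int = 12
    hidden_dim: int = 28
    decoder_layers: int = 3
    max_span_len: int = 8
    threshold: float = 0.5
    epochs: int = 12
    learning_rate: float = 3e-3
    pos_weight: float = 2.0       # rebalances rare positives among candidates
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.decoder_layers < 1 or self.max_span_len < 1:
            raise ValueError("decoder_layers and max_span_len must be >= 1")


@dataclass(frozen=True, order=True)
class SpanCandidate:
    start: int   # token index, inclusive
    end: int     # token index, exclusive
    label: str
    score: float = field(compare=False, default=0.0)


class NerModel:
    """All trainable parameters plus tokenizer/vocabulary state."""

    def __init__(self, config: NerConfig, word_vocab: dict[str, int],
                 char_vocab: dict[str, int], labels=SEMANTIC_GROUPS):
        self.config = config
        self.word_vocab = word_vocab
        self.char_vocab = char_vocab
        self.labels = tuple(labels)
        self.loss_trace: list[tuple[float, float]] = []
        rng = np.random.default_rng(config.seed)
        c = config

        def par(*shape, scale=None):
            scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
            return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

        V, C = len(word_vocab) + 2, len(char_vocab) + 2
        self.p: dict[str, Tensor] = {}
        p = self.p
        p["E_ctx"] = par(V, c.word_dim, scale=0.1)
        p["E_static"] = par(V, c.word_dim, scale=0.1)
        p["E_char"] = par(C, c.char_emb_dim, scale=0.1)
        p["W_conv"] = par(3 * c.char_emb_dim, c.char_dim)
        p["b_conv"] = Tensor(np.zeros(c.char_dim), requires_grad=True)
        in_dim = c.word_dim + c.char_dim
        p["W_in"] = par(in_dim, c.hidden_dim)
        p["b_in"] = Tensor(np.zeros(c.hidden_dim), requires_grad=True)
        for l in range(c.context_layers):
            p[f"ctx_A{l}"] = par(c.hidden_dim, c.hidden_dim)
            p[f"ctx_B{l}"] = par(c.hidden_dim, c.hidden_dim)
            p[f"ctx_C{l}"] = par(c.hidden_dim, c.hidden_dim)
            p[f"ctx_b{l}"] = Tensor(np.zeros(c.hidden_dim), requires_grad=True)
        p["w_ctx"] = Tensor(np.zeros(c.context_layers), requires_grad=True)
        D = c.hidden_dim + c.word_dim + c.char_dim
        H = c.hidden_dim
        for j in range(c.decoder_layers):
            xin = D if j == 0 else H
            p[f"lstm_Wx{j}"] = par(xin, 4 * H)
            p[f"lstm_Wh{j}"] = par(H, 4 * H)
            p[f"lstm_b{j}"] = Tensor(np.zeros(4 * H), requires_grad=True)
        p["w_dec"] = Tensor(np.zeros(c.decoder_layers), requires_grad=True)
        p["W_out"] = par(H, len(self.labels))
        p["b_out"] = Tensor(np.zeros(len(self.labels)), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return list(self.p.values())

    def enc_dim(self) -> int:
        c = self.config
        return c.hidden_dim + c.word_dim + c.char_dim

    # -- vocab ----------------------------------------------------------------
    def word_id(self, w: str) -> int:
        return self.word_vocab.get(w.casefold(), _UNK - 2) + 2

    def char_ids(self, w: str) -> list[int]:
        return [self.char_vocab.get(ch, _UNK - 2) + 2 for ch in w]

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {k: t.data for k, t in self.p.items()}
        meta = json.dumps({
            "config": asdict(self.config),
            "word_vocab": self.word_vocab,
            "char_vocab": self.char_vocab,
            "labels": self.labels,
        })
        np.savez(path, __meta__=np.array(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "NerModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        model = cls(NerConfig(**meta["config"]), meta["word_vocab"],
                    meta["char_vocab"], tuple(meta["labels"]))
        for k in model.p:
            model.p[k].data = data[k]
        return model


def build_vocab(docs: list[AnnotatedDocument]) -> tuple[dict[str, int], dict[str, int]]:
    words: set[str] = set()
    chars: set[str] = set()
    for doc in docs:
        for tok in tokenize(doc.text):
            words.add(tok.text.casefold())
            chars.update(tok.text)
    return ({w: i for i, w in enumerate(sorted(words))},
            {ch: i for i, ch in enumerate(sorted(chars))})


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def encode_tokens(tokens: list[str], model: NerModel) -> Tensor:
    """One vector per token: [contextual combination | static word | char-CNN]."""
    c = model.config
    n = len(tokens)
    if n == 0:
        return Tensor(np.zeros((0, model.enc_dim())))
    word_ids = np.array([model.word_id(t) for t in tokens])
    w_ctx_in = gather(model.p["E_ctx"], word_ids)
    w_static = gather(model.p["E_static"], word_ids)

    # char-CNN: width-3 convolution, ReLU, masked max-pool
    max_len = max(3, max(len(t) for t in tokens))
    char_mat = np.full((n, max_len), _PAD, dtype=np.int64)
    for i, t in enumerate(tokens):
        ids = model.char_ids(t)[:max_len]
        char_mat[i, : len(ids)] = ids
    emb = gather(model.p["E_char"], char_mat)           # (n, L, ce)
    windows = concat([emb[:, 0:max_len - 2, :], emb[:, 1:max_len - 1, :],
                      emb[:, 2:max_len, :]], axis=-1)   # (n, L-2, 3ce)
    conv = (windows @ model.p["W_conv"] + model.p["b_conv"]).relu()
    lengths = np.array([len(t) for t in tokens])
    mask = np.zeros((n, max_len - 2, 1))
    for j in range(max_len - 2):
        mask[:, j, 0] = np.where(j + 3 <= np.maximum(lengths, 3), 0.0, -1e9)
    char_feat = (conv + Tensor(mask)).max(axis=1)       # (n, char_dim)

    h = (concat([w_ctx_in, char_feat], axis=-1) @ model.p["W_in"]
         + model.p["b_in"]).tanh()
    zero = Tensor(np.zeros((1, c.hidden_dim)))
    layer_outs = []
    for l in range(c.context_layers):
        left = concat([zero, h], axis=0)[0:n]           # h shifted right
        right = concat([h, zero], axis=0)[1:n + 1]      # h shifted left
        h = (h @ model.p[f"ctx_A{l}"] + left @ model.p[f"ctx_B{l}"]
             + right @ model.p[f"ctx_C{l}"] + model.p[f"ctx_b{l}"]).tanh()
        layer_outs.append(h)
    w = _softmax_weights(model.p["w_ctx"])
    combined = layer_outs[0] * w[0]
    for l in range(1, c.context_layers):
        combined = combined + layer_outs[l] * w[l]
    return concat([combined, w_static, char_feat], axis=-1)


def _softmax_weights(w: Tensor) -> list[Tensor]:
    e = w.exp()
    z = e.sum()
    return [e[i] / z for i in range(w.shape[0])]


def _lstm_over_span(span_enc: Tensor, model: NerModel) -> Tensor:
    """Run the multi-layer LSTM decoder over (m, l, D) span encodings and
    return the learned per-layer weighted combination of final hidden states."""
    c = model.config
    m, l, _ = span_enc.shape
    H = c.hidden_dim
    finals = []
    layer_input = [span_enc[:, t, :] for t in range(l)]
    for j in range(c.decoder_layers):
        h = Tensor(np.zeros((m, H)))
        cc = Tensor(np.zeros((m, H)))
        outs = []
        for t in range(l):
            z = (layer_input[t] @ model.p[f"lstm_Wx{j}"]
                 + h @ model.p[f"lstm_Wh{j}"] + model.p[f"lstm_b{j}"])
            i_g = z[:, 0:H].sigmoid()
            f_g = z[:, H:2 * H].sigmoid()
            o_g = z[:, 2 * H:3 * H].sigmoid()
            g_g = z[:, 3 * H:4 * H].tanh()
            cc = f_g * cc + i_g * g_g
            h = o_g * cc.tanh()
            outs.append(h)
        finals.append(h)
        layer_input = outs
    w = _softmax_weights(model.p["w_dec"])
    combined = finals[0] * w[0]
    for j in range(1, c.decoder_layers):
        combined = combined + finals[j] * w[j]
    return combined


def _span_logits(enc: Tensor, model: NerModel):
    """Yield (starts, length, logits Tensor) for every span length."""
    n = enc.shape[0]
    c = model.config
    for length in range(1, min(c.max_span_len, n) + 1):
        starts = np.arange(n - length + 1)
        idx = starts[:, None] + np.arange(length)[None, :]
        span_enc = gather(enc, idx)
        rep = _lstm_over_span(span_enc, model)
        logits = rep @ model.p["W_out"] + model.p["b_out"]
        yield starts, length, logits


def score_spans(enc: Tensor, model: NerModel) -> list[SpanCandidate]:
    """Sigmoid scores for every (start, end, label) with end-start <= max_span_len."""
    out: list[SpanCandidate] = []
    for starts, length, logits in _span_logits(enc, model):
        scores = 1.0 / (1.0 + np.exp(-logits.data))
        for si, s in enumerate(starts):
            for li, lab in enumerate(model.labels):
                out.append(SpanCandidate(int(s), int(s) + length, lab,
                                         float(scores[si, li])))
    return sorted(out)


# ---------------------------------------------------------------------------
# gold alignment and training
# ---------------------------------------------------------------------------

def align_gold_to_tokens(doc: AnnotatedDocument, tokens: list[Token]) -> list[tuple[int, int, str]]:
    """Snap gold character spans outward to covering token index spans."""
    out = []
    for m in doc.mentions:
        ts = next((i for i, t in enumerate(tokens) if t.end > m.start), None)
        te_candidates = [i for i, t in enumerate(tokens) if t.start < m.end]
        if ts is None or not te_candidates:
            logger.warning("%s: mention (%d, %d) outside token stream",
                           doc.doc_id, m.start, m.end)
            continue
        te = te_candidates[-1] + 1
        if tokens[ts].start != m.start or tokens[te - 1].end != m.end:
            logger.info("%s: snapped gold (%d, %d) to tokens [%d, %d)",
                        doc.doc_id, m.start, m.end, ts, te)
        out.append((ts, te, m.label))
    return out


def _doc_loss(doc: AnnotatedDocument, model: NerModel) -> Tensor | None:
    tokens = tokenize(doc.text)
    if not tokens:
        return None
    gold = set(align_gold_to_tokens(doc, tokens))
    enc = encode_tokens([t.text for t in tokens], model)
    logit_parts, target_parts = [], []
    for starts, length, logits in _span_logits(enc, model):
        targets = np.zeros((len(starts), len(model.labels)))
        for si, s in enumerate(starts):
            for li, lab in enumerate(model.labels):
                if (int(s), int(s) + length, lab) in gold:
                    targets[si, li] = 1.0
        logit_parts.append(logits)
        target_parts.append(targets)
    all_logits = concat(logit_parts, axis=0)
    all_targets = np.concatenate(target_parts, axis=0)
    return all_logits.bce_with_logits(all_targets, pos_weight=model.config.pos_weight)


def train_ner(train_docs: list[AnnotatedDocument],
              dev_docs: list[AnnotatedDocument] | None,
              config: NerConfig) -> NerModel:
    """Train the span scorer with Adam on binary cross-entropy.

    Seed-deterministic; the per-epoch (train, dev) loss trace is stored on
    the returned model. ``epochs=0`` returns the initialized model untouched.
    """
    if not train_docs:
        raise ValueError("empty training set")
    word_vocab, char_vocab = build_vocab(train_docs)
    model = NerModel(config, word_vocab, char_vocab)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_docs))
        total = 0.0
        for i in order:
            loss = _doc_loss(train_docs[i], model)
            if loss is None:
                continue
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data)
        train_loss = total / max(1, len(train_docs))
        dev_loss = float("nan")
        if dev_docs:
            dev_losses = []
            for d in dev_docs:
                dl = _doc_loss(d, model)
                if dl is not None:
                    dev_losses.append(float(dl.data))
            if dev_losses:
                dev_loss = float(np.mean(dev_losses))
        model.loss_trace.append((train_loss, dev_loss))
        logger.info("epoch %d: train loss %.4f dev loss %.4f",
                    epoch + 1, train_loss, dev_loss)
    return model


def predict_mentions(doc: AnnotatedDocument | str, model: NerModel,
                     config: NerConfig | None = None) -> list[Mention]:
    """All candidates scoring strictly above the threshold, as char-offset
    mentions. Nested and overlapping spans are all kept."""
    config = config or model.config
    text = doc.text if isinstance(doc, AnnotatedDocument) else doc
    tokens = tokenize(text)
    if not tokens:
        return []
    enc = encode_tokens([t.text for t in tokens], model)
    mentions = []
    for cand in score_spans(enc, model):
        if cand.score > config.threshold:
            start = tokens[cand.start].start
            end = tokens[cand.end - 1].end
            mentions.append(Mention(start, end, cand.label, score=cand.score))
    return sorted(mentions)
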