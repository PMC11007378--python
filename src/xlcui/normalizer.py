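"""Concept normalization: mention strings to CUIs by cosine-similarity ranking.

The normalizer treats entity linking as a very-many-class classification
problem: a text encoder maps a term to a unit vector, every CUI owns a unit
target vector, and the last layer is a softmax over scaled cosine
similarities. Training follows a two-phase protocol:

* phase 1 — the encoder and the per-CUI target vectors are trained jointly
  on (term → CUI) pairs for all concepts covered in the primary language
  (their primary-language terms plus cross-language synonyms);
* phase 2 — the encoder is frozen; only stored row embeddings for
  secondary-language-only terms (concepts with no primary-language term)
  are fitted, against frozen CUI anchors.

At inference a mention is embedded with the (frozen) encoder and CUIs are
ranked by their best term-row cosine; a semantic-group filter then picks the
first in-group candidate among the top *k*.

The encoder itself is a character-n-gram hashing featurizer followed by a
small dense network — deliberately lexical, since synthetic synonyms of a
concept share word material, mirroring how surface-form overlap drives
nearest-neighbour linking in terminology-only training.

``joint_extract_and_link`` is the terminology-oriented one-pass alternative:
a greedy longest-match dictionary scan that emits span, group and CUI
simultaneously (the role a ready-made tagger plays in the translated axis).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._autograd import Adam, Tensor
from ._tokenize import tokenize
from .documents import Mention
from .terminology import (Terminology, lookup_exact, normalize_term,
                          partition_terms_by_language_coverage)


@dataclass
class NormConfig:
    embed_dim: int = 32
    ngram_dim: int = 512
    hidden_dim: int = 64
    k: int = 5                  # candidate-list depth for the group filter
    scale: float = 10.0         # cosine logit temperature
    epochs: int = 300
    learning_rate: float = 0.05
    seed: int = 0
    phase: int = 1
    primary_lang: str = "FRE"
    secondary_lang: str = "ENG"

    def __post_init__(self):
        if self.k < 1 or self.embed_dim < 2:
            raise ValueError("k must be >= 1 and embed_dim >= 2")
        if self.phase not in (1, 2):
            raise ValueError("phase must be 1 or 2")


def _char_ngrams(s: str, n: int = 3) -> list[str]:
    s = f"#{normalize_term(s)}#"
    if len(s) < n:
        return [s]
    return [s[i:i + n] for i in range(len(s) - n + 1)]


def featurize(texts: list[str], dim: int) -> np.ndarray:
    """Hashed character-trigram count features, row-normalized."""
    out = np.zeros((len(texts), dim))
    for i, t in enumerate(texts):
        for g in _char_ngrams(t):
            out[i, zlib.crc32(g.encode()) % dim] += 1.0
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    return out / np.maximum(norms, 1e-12)


class DenseEncoder:
    """Frozen-able two-layer encoder over hashed n-gram features."""

    def __init__(self, W1, b1, W2, b2, ngram_dim: int):
        self.W1, self.b1, self.W2, self.b2 = W1, b1, W2, b2
        self.ngram_dim = ngram_dim

    def embed_batch(self, texts: list[str]) -> np.ndarray:
        F = featurize(texts, self.ngram_dim)
        H = np.tanh(F @ self.W1 + self.b1)
        X = H @ self.W2 + self.b2
        return X / np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)

    def embed(self, text: str) -> np.ndarray:
        return self.embed_batch([text])[0]


class HashEmbedder:
    """Exact-match oracle embedder: each distinct normalized string maps to a
    deterministic pseudo-random unit vector, so identical strings have cosine
    1 and distinct strings are near-orthogonal."""

    def __init__(self, dim: int = 256):
        self.dim = dim

    def embed(self, text: str) -> np.ndarray:
        seed = zlib.crc32(normalize_term(text).encode()) % (2**31)
        v = np.random.default_rng(seed).normal(size=self.dim)
        return v / np.linalg.norm(v)

    def embed_batch(self, texts: list[str]) -> np.ndarray:
        return np.stack([self.embed(t) for t in texts])


@dataclass
class IndexRow:
    term: str
    cui: str
    group: str
    lang: str


class ConceptIndex:
    """Unit-norm term-embedding matrix with (term, cui, group) metadata."""

    def __init__(self, embedder, rows: list[IndexRow], matrix: np.ndarray,
                 cui_anchors: dict[str, np.ndarray] | None = None,
                 config: NormConfig | None = None):
        if len(rows) != matrix.shape[0]:
            raise ValueError("row metadata and matrix size mismatch")
        norms = np.linalg.norm(matrix, axis=1)
        if len(rows) and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("index rows must be unit-norm")
        self.embedder = embedder
        self.rows = rows
        self.matrix = matrix
        self.cui_anchors = cui_anchors or {}
        self.config = config
        self._groups = {r.cui: r.group for r in rows}

    def __len__(self):
        return len(self.rows)

    def terms(self) -> list[str]:
        return [r.term for r in self.rows]


def embed_term(text: str, index: ConceptIndex) -> np.ndarray:
    """L2-normalized, deterministic embedding of a mention string."""
    if not text or not text.strip():
        raise ValueError("cannot embed an empty string")
    v = index.embedder.embed(text)
    return v / np.linalg.norm(v)


def rank_candidates(text: str, index: ConceptIndex, k: int) -> list[tuple[str, str, float]]:
    """Top-k distinct CUIs by maximum cosine over their term rows.

    Descending cosine; exact ties broken by lexicographic CUI. ``k`` larger
    than the number of CUIs returns them all.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(index) == 0:
        raise ValueError("empty concept index")
    q = embed_term(text, index)
    cos = index.matrix @ q
    best: dict[str, float] = {}
    for r, c in zip(index.rows, cos):
        if r.cui not in best or c > best[r.cui]:
            best[r.cui] = float(c)
    ranked = sorted(best.items(), key=lambda it: (-it[1], it[0]))
    return [(cui, index._groups[cui], c) for cui, c in ranked[:k]]


@dataclass(frozen=True)
class SelectedCui:
    cui: str
    group: str
    cosine: float
    fallback: bool   # True when no in-group candidate was within the top k


def select_cui(ranked: list[tuple[str, str, float]], target_group: str,
               k: int) -> SelectedCui:
    """First candidate among the top k whose group matches; else the overall
    top-1, flagged as a fallback."""
    if not ranked:
        raise ValueError("ranked list is empty")
    for cui, group, cos in ranked[:k]:
        if group == target_group:
            return SelectedCui(cui, group, cos, fallback=False)
    cui, group, cos = ranked[0]
    return SelectedCui(cui, group, cos, fallback=True)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _l2norm_rows(x: Tensor) -> Tensor:
    s = (x * x).sum(axis=1, keepdims=True)
    return x / (s.sqrt() + 1e-12)


def train_normalizer(terminology: Terminology, config: NormConfig,
                     prior: ConceptIndex | None = None) -> ConceptIndex:
    """Train the cosine-softmax normalizer (phase 1) or extend it (phase 2).

    Phase 1 trains encoder and CUI target vectors on the terms of all
    concepts covered in the primary language. Phase 2 requires the phase-1
    index as ``prior``; it freezes the encoder, keeps every phase-1 row
    bit-identical, and adds fitted rows for exactly the secondary-only term
    set. Deterministic under ``config.seed``.
    """
    if len(terminology) == 0:
        raise ValueError("empty terminology")
    shared, secondary_only = partition_terms_by_language_coverage(
        terminology, config.primary_lang, config.secondary_lang)
    if config.phase == 1:
        return _train_phase1(terminology, shared, config)
    if prior is None:
        raise ValueError("phase 2 requires the phase-1 index as prior")
    return _train_phase2(terminology, secondary_only, config, prior)


def _train_phase1(terminology, shared, config) -> ConceptIndex:
    if not shared:
        raise ValueError("no terms cover the primary language")
    rng = np.random.default_rng(config.seed)
    terms = [t for _, _, t in shared]
    cuis_of_terms = [c for c, _, _ in shared]
    cui_list = sorted(set(cuis_of_terms))
    cui_idx = {c: i for i, c in enumerate(cui_list)}
    labels = np.array([cui_idx[c] for c in cuis_of_terms])
    F = Tensor(featurize(terms, config.ngram_dim))

    def par(*shape):
        return Tensor(rng.normal(0, 1.0 / np.sqrt(shape[0]), size=shape),
                      requires_grad=True)

    W1 = par(config.ngram_dim, config.hidden_dim)
    b1 = Tensor(np.zeros(config.hidden_dim), requires_grad=True)
    W2 = par(config.hidden_dim, config.embed_dim)
    b2 = Tensor(np.zeros(config.embed_dim), requires_grad=True)
    C = Tensor(rng.normal(0, 0.1, size=(len(cui_list), config.embed_dim)),
               requires_grad=True)
    opt = Adam([W1, b1, W2, b2, C], lr=config.learning_rate)
    for _ in range(config.epochs):
        X = _l2norm_rows((F @ W1 + b1).tanh() @ W2 + b2)
        logits = (X @ _tp(_l2norm_rows(C))) * config.scale
        loss = logits.softmax_cross_entropy(labels)
        opt.zero_grad()
        loss.backward()
        opt.step()

    encoder = DenseEncoder(W1.data.copy(), b1.data.copy(), W2.data.copy(),
                           b2.data.copy(), config.ngram_dim)
    matrix = encoder.embed_batch(terms)
    lang_of = {(c, t): lang for c, lang, t in shared}
    rows = [IndexRow(t, c, terminology.group_of(c), lang_of[(c, t)])
            for c, t in zip(cuis_of_terms, terms)]
    Cn = _l2norm_rows(C).data
    anchors = {cui: Cn[i].copy() for cui, i in cui_idx.items()}
    return ConceptIndex(encoder, rows, matrix, anchors, config)


def _tp(t: Tensor) -> Tensor:
    out_data = t.data.T

    def backward(g):
        t._accum(g.T)

    return Tensor._make(out_data, (t,), backward)


def _train_phase2(terminology, secondary_only, config, prior) -> ConceptIndex:
    rng = np.random.default_rng(config.seed + 7)
    if not secondary_only:
        return ConceptIndex(prior.embedder, list(prior.rows),
                            prior.matrix.copy(), dict(prior.cui_anchors), config)
    terms = [t for _, _, t in secondary_only]
    cuis_of_terms = [c for c, _, _ in secondary_only]
    new_cuis = sorted(set(cuis_of_terms))
    # anchors for new CUIs: normalized mean of frozen-encoder term embeddings
    init = prior.embedder.embed_batch(terms)
    anchors = dict(prior.cui_anchors)
    for cui in new_cuis:
        mask = np.array([c == cui for c in cuis_of_terms])
        mean = init[mask].mean(axis=0)
        anchors[cui] = mean / np.linalg.norm(mean)
    all_cuis = sorted(anchors)
    cui_idx = {c: i for i, c in enumerate(all_cuis)}
    A = np.stack([anchors[c] for c in all_cuis])          # frozen anchors
    labels = np.array([cui_idx[c] for c in cuis_of_terms])
    V = Tensor(init + rng.normal(0, 1e-3, size=init.shape), requires_grad=True)
    opt = Adam([V], lr=config.learning_rate)
    for _ in range(max(1, config.epochs // 3)):
        logits = _l2norm_rows(V) @ Tensor(A.T) * config.scale
        loss = logits.softmax_cross_entropy(labels)
        opt.zero_grad()
        loss.backward()
        opt.step()
    fitted = V.data / np.linalg.norm(V.data, axis=1, keepdims=True)
    lang_of = {(c, t): lang for c, lang, t in secondary_only}
    new_rows = [IndexRow(t, c, terminology.group_of(c), lang_of[(c, t)])
                for c, t in zip(cuis_of_terms, terms)]
    return ConceptIndex(prior.embedder, list(prior.rows) + new_rows,
                        np.vstack([prior.matrix, fitted]), anchors, config)


def exact_match_index(terminology: Terminology, langs: set[str] | None = None,
                      dim: int = 256) -> ConceptIndex:
    """Oracle index: hash-orthogonal embeddings, exact-string retrieval."""
    embedder = HashEmbedder(dim)
    rows = [IndexRow(term, cui, group, lang)
            for cui, group, lang, term in terminology.iter_terms(langs)]
    if not rows:
        raise ValueError("no terms for requested languages")
    matrix = embedder.embed_batch([r.term for r in rows])
    return ConceptIndex(embedder, rows, matrix)


# ---------------------------------------------------------------------------
# joint dictionary extractor/linker
# ---------------------------------------------------------------------------

def joint_extract_and_link(text: str, terminology: Terminology, lang: str,
                           max_span_len: int = 8) -> list[Mention]:
    """Greedy left-to-right longest-match dictionary extraction + linking.

    Token n-grams (longest first, up to ``max_span_len``) are looked up
    exactly in the terminology; a match emits a mention with the concept's
    group and CUI (lexicographically smallest on multi-CUI strings) and
    consumes its tokens, so this extractor never produces overlaps.
    """
    tokens = tokenize(text)
    mentions: list[Mention] = []
    i = 0
    while i < len(tokens):
        matched = False
        for length in range(min(max_span_len, len(tokens) - i), 0, -1):
            surface = text[tokens[i].start:tokens[i + length - 1].end]
            hits = lookup_exact(surface, lang, terminology)
            if hits:
                cui, group = hits[0]  # CUI-sorted: smallest first
                mentions.append(Mention(tokens[i].start,
                                        tokens[i + length - 1].end,
                                        group, cui=cui))
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return mentions


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_index(index: ConceptIndex, path: str | Path) -> None:
    if not isinstance(index.embedder, DenseEncoder):
        raise ValueError("only trained DenseEncoder indices are serializable")
    meta = json.dumps({
        "rows": [[r.term, r.cui, r.group, r.lang] for r in index.rows],
        "anchor_cuis": sorted(index.cui_anchors),
        "ngram_dim": index.embedder.ngram_dim,
    })
    anchors = (np.stack([index.cui_anchors[c] for c in sorted(index.cui_anchors)])
               if index.cui_anchors else np.zeros((0, index.matrix.shape[1])))
    np.savez(path, __meta__=np.array(meta), matrix=index.matrix,
             W1=index.embedder.W1, b1=index.embedder.b1,
             W2=index.embedder.W2, b2=index.embedder.b2, anchors=anchors)


def load_index(path: str | Path) -> ConceptIndex:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    encoder = DenseEncoder(data["W1"], data["b1"], data["W2"], data["b2"],
                           meta["ngram_dim"])
    rows = [IndexRow(*r) for r in meta["rows"]]
    anchors = {c: data["anchors"][i] for i, c in enumerate(meta["anchor_cuis"])}
    return ConceptIndex(encoder, rows, data["matrix"], anchors)
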