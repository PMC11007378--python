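"""Pluggable document translation and the per-sentence BLEU metric.

Real machine-translation systems plug in through ``TranslatorContract`` — a
callable from document text to target text. Two built-ins are provided: an
identity translator and the dictionary translator, which renders an
annotated document through the synthetic lexicon with configurable noise
(see :mod:`xlcui.synthetic`) so the translated axes can be exercised without
an external MT model.

BLEU here is the per-sentence variant: the weighted geometric mean of
clipped n-gram precisions per sentence, averaged arithmetically over a
corpus. Add-one smoothing is applied on orders >= 2 and a 0.1/denominator
floor replaces a zero unigram precision (per-sentence BLEU degenerates to 0
without smoothing); no brevity penalty is applied. These are explicit,
configurable choices rather than claims about any particular toolkit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from ._tokenize import token_texts
from .documents import AnnotatedDocument, ParallelDocument
from .synthetic import GenConfig, apply_translation_noise


class TranslatorContract(Protocol):
    def __call__(self, doc: AnnotatedDocument) -> ParallelDocument: ...


def identity_translator(doc: AnnotatedDocument) -> ParallelDocument:
    return ParallelDocument(source=doc, target_text=doc.text,
                            target_mentions=list(doc.mentions),
                            noise_log=[("faithful", m.span(), doc.surface(m))
                                       for m in doc.sorted_mentions()])


def dictionary_translator(lexicon: dict[str, str],
                          config: GenConfig) -> Callable[[AnnotatedDocument], ParallelDocument]:
    """Deterministic dictionary translator with the configured noise modes."""

    def translate(doc: AnnotatedDocument) -> ParallelDocument:
        return apply_translation_noise(doc, lexicon, config)

    return translate


def translate_document(doc: AnnotatedDocument,
                       translator: TranslatorContract) -> ParallelDocument:
    """Run one document through a translator, wrapping failures with the id."""
    try:
        return translator(doc)
    except Exception as exc:
        raise RuntimeError(f"translation failed for document {doc.doc_id!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# BLEU
# ---------------------------------------------------------------------------

@dataclass
class BleuConfig:
    max_n: int = 4
    weights: tuple[float, ...] | None = None  # default: uniform over orders
    smoothing: bool = True                     # add-one on orders >= 2

    def __post_init__(self):
        if self.max_n < 1:
            raise ValueError("max_n must be >= 1")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != self.max_n or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("weights must be non-negative and sum to 1 "
                                 f"over {self.max_n} orders")

    def order_weights(self) -> np.ndarray:
        if self.weights is not None:
            return np.asarray(self.weights, dtype=float)
        return np.full(self.max_n, 1.0 / self.max_n)


def _ngrams(tokens: list[str], n: int) -> Counter:
    return Counter(tuple(tokens[i:i + n]) for i in range(len(tokens) - n + 1))


def bleu_sentence(hypothesis: list[str], reference: list[str],
                  config: BleuConfig | None = None) -> float:
    """Weighted geometric mean of clipped n-gram precisions for one sentence.

    Orders longer than the hypothesis (zero denominator) are dropped with
    weight renormalization; an empty hypothesis scores 0.
    """
    config = config or BleuConfig()
    if not reference:
        raise ValueError("reference must be non-empty")
    if not hypothesis:
        return 0.0
    weights = config.order_weights()
    logs, used_weights = [], []
    for n in range(1, config.max_n + 1):
        hyp_counts = _ngrams(hypothesis, n)
        denom = sum(hyp_counts.values())
        if denom == 0:
            continue  # order longer than the hypothesis: drop, renormalize
        ref_counts = _ngrams(reference, n)
        clipped = sum(min(c, ref_counts[g]) for g, c in hyp_counts.items())
        if config.smoothing and n >= 2:
            p = (clipped + 1.0) / (denom + 1.0)
        elif clipped == 0:
            if not config.smoothing:
                return 0.0
            p = 0.1 / denom  # floor for zero unigram overlap
        else:
            p = clipped / denom
        logs.append(np.log(p))
        used_weights.append(weights[n - 1])
    if not logs:
        return 0.0
    w = np.asarray(used_weights)
    if w.sum() == 0:
        return 0.0
    w = w / w.sum()
    return float(np.exp(np.dot(w, logs)))


def bleu_corpus(pairs: list[tuple[list[str], list[str]]],
                config: BleuConfig | None = None) -> float:
    """Arithmetic mean of sentence scores over (hypothesis, reference) pairs."""
    if not pairs:
        raise ValueError("no sentence pairs")
    return float(np.mean([bleu_sentence(h, r, config) for h, r in pairs]))


def bleu_texts(hypothesis_text: str, reference_text: str,
               config: BleuConfig | None = None) -> float:
    """Sentence BLEU over raw strings, using the pipeline tokenizer."""
    return bleu_sentence(token_texts(hypothesis_text),
                         token_texts(reference_text), config)


def read_parallel_tsv(path) -> list[tuple[str, str, str | None]]:
    """(source, reference, optional hypothesis) rows from a 2/3-column TSV."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"parallel TSV rows need >= 2 columns: {line!r}")
            rows.append((parts[0], parts[1], parts[2] if len(parts) > 2 else None))
    return rows
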