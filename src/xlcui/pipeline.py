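"""End-to-end experimental axes and their comparison.

Three document-to-CUI-set routes are compared on the same gold corpus:

* ``axis1`` — native route: span NER on the source-language text, then
  cosine-ranked normalization with semantic-group reranking;
* ``axis2_1`` — translated two-step route: translate, span NER on the target
  text, then normalization;
* ``axis2_2`` — translated terminology route: translate, then the one-pass
  greedy dictionary extractor/linker.

Each axis ends in the document-level CUI-set evaluation, which is what makes
the routes comparable without any cross-language span alignment.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Callable

import pandas as pd

from .documents import AnnotatedDocument, Mention, strip_cuis
from .evaluation import EvalConfig, EvalReport, doc_cui_prf
from .ner import NerModel, predict_mentions
from .normalizer import ConceptIndex, joint_extract_and_link, rank_candidates, select_cui
from .terminology import Terminology
from .translation import TranslatorContract, translate_document

logger = logging.getLogger(__name__)

AXES = ("axis1", "axis2_1", "axis2_2")

NerFn = Callable[[AnnotatedDocument], list[Mention]]


def gold_span_ner() -> NerFn:
    """Oracle recognizer: emits the document's own gold spans, CUIs stripped."""

    def run(doc: AnnotatedDocument) -> list[Mention]:
        return strip_cuis(doc).mentions

    return run


def model_ner(model: NerModel) -> NerFn:
    def run(doc: AnnotatedDocument) -> list[Mention]:
        return predict_mentions(doc, model)

    return run


@dataclass
class PipelineConfig:
    axis: str
    terminology: Terminology
    gold_docs: list[AnnotatedDocument]           # source-language gold corpus
    ner: NerFn | None = None                     # axis1 / axis2_1
    index: ConceptIndex | None = None            # axis1 / axis2_1
    translator: TranslatorContract | None = None  # axis2_1 / axis2_2
    target_lang: str = "ENG"
    k: int = 5
    max_span_len: int = 8
    eval_config: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0

    def __post_init__(self):
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}; expected one of {AXES}")

    def require(self, name: str):
        value = getattr(self, name)
        if value is None:
            raise ValueError(f"axis {self.axis} requires a configured {name}")
        return value

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(repr((self.axis, self.target_lang, self.k, self.max_span_len,
                       self.seed, self.eval_config.bootstrap_replicates,
                       self.eval_config.alpha, self.eval_config.seed,
                       sorted(d.doc_id for d in self.gold_docs))).encode())
        return h.hexdigest()[:16]


@dataclass
class AxisResult:
    axis: str
    cui_sets: dict[str, set[str]]        # doc_id -> predicted CUI set
    report: EvalReport
    gold_fingerprint: str
    config_hash: str
    stage_counts: dict[str, int] = field(default_factory=dict)


def _gold_fingerprint(gold_docs: list[AnnotatedDocument]) -> str:
    h = hashlib.sha256()
    for d in sorted(gold_docs, key=lambda d: d.doc_id):
        cuis = sorted({m.cui for m in d.mentions if m.cui is not None})
        h.update(f"{d.doc_id}:{','.join(cuis)};".encode())
    return h.hexdigest()[:16]


def _normalize_mentions(doc_text: str, mentions: list[Mention],
                        index: ConceptIndex, k: int) -> tuple[list[Mention], int]:
    out = []
    fallbacks = 0
    for m in mentions:
        surface = doc_text[m.start:m.end]
        ranked = rank_candidates(surface, index, k)
        sel = select_cui(ranked, m.label, k)
        fallbacks += sel.fallback
        out.append(Mention(m.start, m.end, m.label, cui=sel.cui, score=m.score))
    return out, fallbacks


def run_axis(config: PipelineConfig) -> AxisResult:
    """Run one experimental axis end-to-end and score it at document level."""
    gold = config.gold_docs
    counts = {"documents": len(gold), "ner_mentions": 0,
              "normalized_mentions": 0, "group_fallbacks": 0}
    predicted: list[AnnotatedDocument] = []
    for doc in gold:
        if config.axis == "axis1":
            mentions = config.require("ner")(strip_cuis(doc))
            counts["ner_mentions"] += len(mentions)
            normed, fb = _normalize_mentions(doc.text, mentions,
                                             config.require("index"), config.k)
            predicted.append(AnnotatedDocument(doc.doc_id, doc.text, normed))
        elif config.axis == "axis2_1":
            parallel = translate_document(doc, config.require("translator"))
            tdoc = parallel.target_document()
            mentions = config.require("ner")(tdoc)
            counts["ner_mentions"] += len(mentions)
            normed, fb = _normalize_mentions(tdoc.text, mentions,
                                             config.require("index"), config.k)
            predicted.append(AnnotatedDocument(doc.doc_id, tdoc.text, normed))
        else:  # axis2_2
            parallel = translate_document(doc, config.require("translator"))
            normed = joint_extract_and_link(parallel.target_text,
                                            config.terminology,
                                            config.target_lang,
                                            config.max_span_len)
            fb = 0
            counts["ner_mentions"] += len(normed)
            predicted.append(AnnotatedDocument(doc.doc_id,
                                               parallel.target_text, normed))
        counts["normalized_mentions"] += len(normed)
        counts["group_fallbacks"] += fb
    report = doc_cui_prf(predicted, gold, config.eval_config)
    cui_sets = {d.doc_id: {m.cui for m in d.mentions if m.cui} for d in predicted}
    logger.info("axis %s: %s", config.axis, counts)
    return AxisResult(config.axis, cui_sets, report,
                      _gold_fingerprint(gold), config.fingerprint(), counts)


def compare_axes(results: list[AxisResult]) -> pd.DataFrame:
    """One row per axis (P, R, F1, 95% CI), F1-descending, winner flagged."""
    if len(results) < 2:
        raise ValueError("need at least 2 axis results to compare")
    fps = {r.gold_fingerprint for r in results}
    if len(fps) != 1:
        raise ValueError("axis results were computed on different gold corpora")
    rows = []
    for r in results:
        ci = r.report.ci or (float("nan"), float("nan"))
        rows.append({
            "axis": r.axis,
            "precision": r.report.overall.precision,
            "recall": r.report.overall.recall,
            "f1": r.report.overall.f1,
            "f1_ci": f"({ci[0]:.2f}-{ci[1]:.2f})",
        })
    table = pd.DataFrame(rows).sort_values(
        ["f1", "axis"], ascending=[False, True]).reset_index(drop=True)
    table["winner"] = False
    table.loc[0, "winner"] = True
    return table
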