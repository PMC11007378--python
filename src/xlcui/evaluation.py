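"""Scoring: mention-level NER, gold-mention normalization accuracy, and
document-level CUI-set precision/recall with empirical bootstrap CIs.

Three levels mirror the stages of the pipeline:

* mention level — a predicted span is correct iff a gold mention with the
  identical (start, end, label) exists, matched one-to-one; precision,
  recall and F1 are reported per semantic group and pooled (micro) overall;
* normalization level — fraction of gold mentions whose predicted CUI equals
  the gold CUI (predictions are made on gold spans, isolating the linker);
* document level — predicted and gold CUIs are deduplicated into per-document
  sets, scored by set precision/recall/F1 and macro-averaged over documents.
  This comparison needs no cross-language span alignment, which is what lets
  a native and a translated pipeline be compared on equal terms.

Confidence intervals use the empirical (basic / pivotal) bootstrap over
documents: resample document scores with replacement, recompute the macro
mean, and take ``[2·m − q_{1−α/2}, 2·m − q_{α/2}]`` clipped to [0, 1].
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .documents import AnnotatedDocument
from .terminology import SEMANTIC_GROUPS


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float

    def astuple(self) -> tuple[float, float, float]:
        return (self.precision, self.recall, self.f1)

    @staticmethod
    def from_counts(tp: int, fp: int, fn: int) -> "PRF":
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return PRF(p, r, f)


@dataclass
class EvalConfig:
    bootstrap_replicates: int = 1000
    alpha: float = 0.05
    seed: int = 0
    overall: str = "micro"  # or "macro" over groups

    def __post_init__(self):
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class EvalReport:
    per_group: dict[str, PRF]
    overall: PRF
    counts: dict[str, tuple[int, int, int]]  # group -> (tp, fp, fn)
    ci: tuple[float, float] | None = None
    per_document: dict[str, PRF] = field(default_factory=dict)
    excluded_cuiless: int = 0


def _check_alignment(predicted: list[AnnotatedDocument],
                     gold: list[AnnotatedDocument]) -> None:
    pids = [d.doc_id for d in predicted]
    gids = [d.doc_id for d in gold]
    if sorted(pids) != sorted(gids) or len(set(pids)) != len(pids):
        raise ValueError("predicted and gold doc_id sets must align one-to-one")


def ner_prf(predicted: list[AnnotatedDocument], gold: list[AnnotatedDocument],
            config: EvalConfig | None = None) -> EvalReport:
    """Mention-level exact span+label matching, per group and pooled.

    Matching is one-to-one: duplicate identical predictions beyond the gold
    multiplicity count as false positives. Empty predictions against
    non-empty gold give precision 0 by convention.
    """
    config = config or EvalConfig()
    _check_alignment(predicted, gold)
    gold_by_id = {d.doc_id: d for d in gold}
    counts = {g: [0, 0, 0] for g in SEMANTIC_GROUPS}  # tp, fp, fn
    for pdoc in predicted:
        gdoc = gold_by_id[pdoc.doc_id]
        pred_c = Counter((m.start, m.end, m.label) for m in pdoc.mentions)
        gold_c = Counter((m.start, m.end, m.label) for m in gdoc.mentions)
        for key in pred_c | gold_c:
            tp = min(pred_c[key], gold_c[key])
            g = key[2]
            counts[g][0] += tp
            counts[g][1] += pred_c[key] - tp
            counts[g][2] += gold_c[key] - tp
    per_group = {g: PRF.from_counts(*counts[g]) for g in SEMANTIC_GROUPS}
    if config.overall == "micro":
        pooled = [sum(counts[g][i] for g in SEMANTIC_GROUPS) for i in range(3)]
        overall = PRF.from_counts(*pooled)
    else:
        present = [g for g in SEMANTIC_GROUPS if sum(counts[g]) > 0]
        overall = PRF(
            float(np.mean([per_group[g].precision for g in present])) if present else 0.0,
            float(np.mean([per_group[g].recall for g in present])) if present else 0.0,
            float(np.mean([per_group[g].f1 for g in present])) if present else 0.0,
        )
    return EvalReport(per_group, overall,
                      {g: tuple(counts[g]) for g in SEMANTIC_GROUPS})


def normalization_accuracy(gold_cuis: list[str], predicted_cuis: list[str],
                           ambiguous_pairs: set[frozenset] | None = None):
    """Fraction of gold mentions whose predicted CUI matches.

    If ``ambiguous_pairs`` (sets of CUIs known to be near-synonym concepts)
    is given, errors that land on the partner CUI of an ambiguous pair are
    additionally counted in a sub-report.
    """
    if len(gold_cuis) != len(predicted_cuis):
        raise ValueError("one predicted CUI is required per gold mention")
    if not gold_cuis:
        raise ValueError("no gold mentions to score")
    correct = sum(g == p for g, p in zip(gold_cuis, predicted_cuis))
    acc = correct / len(gold_cuis)
    if ambiguous_pairs is None:
        return acc
    amb_errors = sum(
        g != p and frozenset((g, p)) in ambiguous_pairs
        for g, p in zip(gold_cuis, predicted_cuis))
    return acc, amb_errors


def _doc_cui_prf_one(pred: set[str], gold: set[str]) -> PRF:
    if not pred and not gold:
        return PRF(1.0, 1.0, 1.0)
    inter = len(pred & gold)
    p = inter / len(pred) if pred else 0.0
    r = inter / len(gold) if gold else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return PRF(p, r, f)


def doc_cui_prf(predicted: list[AnnotatedDocument], gold: list[AnnotatedDocument],
                config: EvalConfig | None = None) -> EvalReport:
    """Document-level CUI-set scoring, macro-averaged over documents.

    Mentions are deduplicated to per-document CUI sets (a CUI mentioned five
    times counts once). Mentions lacking a CUI are excluded and counted.
    Conventions: both sets empty → P = R = 1; predictions empty against
    non-empty gold → P = 0. The F1 confidence interval is an empirical
    bootstrap over documents.
    """
    config = config or EvalConfig()
    _check_alignment(predicted, gold)
    gold_by_id = {d.doc_id: d for d in gold}
    per_document: dict[str, PRF] = {}
    excluded = 0
    for pdoc in sorted(predicted, key=lambda d: d.doc_id):
        gdoc = gold_by_id[pdoc.doc_id]
        excluded += sum(m.cui is None for m in pdoc.mentions)
        excluded += sum(m.cui is None for m in gdoc.mentions)
        pset = {m.cui for m in pdoc.mentions if m.cui is not None}
        gset = {m.cui for m in gdoc.mentions if m.cui is not None}
        per_document[pdoc.doc_id] = _doc_cui_prf_one(pset, gset)
    docs = sorted(per_document)
    macro = PRF(
        float(np.mean([per_document[d].precision for d in docs])),
        float(np.mean([per_document[d].recall for d in docs])),
        float(np.mean([per_document[d].f1 for d in docs])),
    )
    ci = bootstrap_ci([per_document[d].f1 for d in docs], config)
    return EvalReport({}, macro, {}, ci=ci, per_document=per_document,
                      excluded_cuiless=excluded)


def bootstrap_ci(scores: list[float], config: EvalConfig | None = None) -> tuple[float, float]:
    """Empirical (basic / pivotal) bootstrap CI for the mean of document scores.

    Resamples documents with replacement ``bootstrap_replicates`` times; the
    interval is ``[2m − q_{1−α/2}, 2m − q_{α/2}]`` of the resampled means,
    clipped to [0, 1]. Seed-deterministic.
    """
    config = config or EvalConfig()
    scores_arr = np.asarray(scores, dtype=float)
    if scores_arr.size == 0:
        raise ValueError("no scores to bootstrap")
    rng = np.random.default_rng(config.seed)
    n, B = scores_arr.size, config.bootstrap_replicates
    idx = rng.integers(0, n, size=(B, n))
    means = scores_arr[idx].mean(axis=1)
    m = scores_arr.mean()
    lo_q, hi_q = np.quantile(means, [config.alpha / 2, 1 - config.alpha / 2])
    low, high = 2 * m - hi_q, 2 * m - lo_q
    return (float(np.clip(low, 0.0, 1.0)), float(np.clip(high, 0.0, 1.0)))
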