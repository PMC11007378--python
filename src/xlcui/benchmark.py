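"""The default synthetic benchmark: native vs translated extraction axes.

Protocol (all sizes are the generator defaults):

1. generate a bilingual terminology and a 42-document annotated
   source-language corpus; split 80/20 (34 train / 8 test);
2. train the span NER once on the source-language training split (native
   axis) and once on *noise-free* dictionary translations of the same split
   (translated axis — its recognizer never sees translation noise, the way a
   target-language model trained on native target-language notes never saw
   machine-translated text);
3. train the two-phase cosine-softmax normalizer on the terminology; the
   same index serves both axes;
4. for each literal-translation noise level, translate the test split with
   the dictionary translator (abbreviation passthrough at its default rate)
   and run the three axes end-to-end;
5. score every axis with document-level CUI-set macro P/R/F1 and bootstrap
   confidence intervals.

The headline comparison is directional: the native axis should outscore both
translated axes, and the margin should grow with the literal-translation
noise rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .documents import AnnotatedDocument
from .evaluation import EvalConfig
from .ner import NerConfig, NerModel, train_ner
from .normalizer import ConceptIndex, NormConfig, train_normalizer
from .pipeline import AxisResult, PipelineConfig, model_ner, run_axis
from .synthetic import (GenConfig, build_lexicon, generate_corpus,
                        generate_terminology, split_corpus)
from .terminology import Terminology
from .translation import dictionary_translator

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkConfig:
    gen: GenConfig = field(default_factory=GenConfig)
    ner: NerConfig = field(default_factory=lambda: NerConfig(max_span_len=4, epochs=20))
    norm: NormConfig = field(default_factory=NormConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    train_frac: float = 0.8
    p_literal_grid: tuple[float, ...] = (0.0, 0.2, 0.4)
    seed: int = 0


@dataclass
class BenchmarkModels:
    terminology: Terminology
    lexicon: dict[str, str]
    train_docs: list[AnnotatedDocument]
    test_docs: list[AnnotatedDocument]
    ner_source: NerModel
    ner_target: NerModel
    index: ConceptIndex


def prepare_models(config: BenchmarkConfig) -> BenchmarkModels:
    """Generate the corpus and train every model the axes need (steps 1-3)."""
    gen = replace(config.gen, seed=config.seed)
    terminology = generate_terminology(gen)
    lexicon = build_lexicon(terminology)
    docs = generate_corpus(terminology, gen)
    train, test = split_corpus(docs, config.train_frac, seed=config.seed + 11)

    ner_cfg_src = replace(config.ner, seed=config.seed + 21)
    ner_source = train_ner(train, None, ner_cfg_src)

    clean = replace(gen, p_literal=0.0, p_abbrev_passthrough=0.0)
    translate_clean = dictionary_translator(lexicon, clean)
    target_train = [translate_clean(d).target_document() for d in train]
    ner_cfg_tgt = replace(config.ner, seed=config.seed + 22)
    ner_target = train_ner(target_train, None, ner_cfg_tgt)

    norm_cfg = replace(config.norm, seed=config.seed + 31, phase=1)
    index = train_normalizer(terminology, norm_cfg)
    index = train_normalizer(terminology, replace(norm_cfg, phase=2), prior=index)
    return BenchmarkModels(terminology, lexicon, train, test,
                           ner_source, ner_target, index)


def run_axes_at_noise(models: BenchmarkModels, config: BenchmarkConfig,
                      p_literal: float) -> dict[str, AxisResult]:
    """Run the three axes on the test split at one literal-noise level."""
    gen = replace(config.gen, seed=config.seed, p_literal=p_literal)
    translator = dictionary_translator(models.lexicon, gen)
    eval_cfg = replace(config.eval, seed=config.seed + 41)
    common = dict(terminology=models.terminology, gold_docs=models.test_docs,
                  eval_config=eval_cfg, k=config.norm.k,
                  max_span_len=config.ner.max_span_len, seed=config.seed)
    results = {}
    results["axis1"] = run_axis(PipelineConfig(
        axis="axis1", ner=model_ner(models.ner_source),
        index=models.index, **common))
    results["axis2_1"] = run_axis(PipelineConfig(
        axis="axis2_1", ner=model_ner(models.ner_target),
        index=models.index, translator=translator, **common))
    results["axis2_2"] = run_axis(PipelineConfig(
        axis="axis2_2", translator=translator, **common))
    return results


def run_benchmark(config: BenchmarkConfig | None = None,
                  models: BenchmarkModels | None = None):
    """Full sweep over the literal-noise grid.

    Returns ``(models, {p_literal: {axis: AxisResult}})``.
    """
    config = config or BenchmarkConfig()
    if models is None:
        models = prepare_models(config)
    sweep = {p: run_axes_at_noise(models, config, p)
             for p in config.p_literal_grid}
    for p, res in sweep.items():
        logger.info("p_literal=%.1f: %s", p,
                    {a: round(r.report.overall.f1, 3) for a, r in res.items()})
    return models, sweep
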