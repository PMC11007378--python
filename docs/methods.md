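# Methods

`xlcui` compares two strategies for extracting standardized medical concepts
(CUIs — concept unique identifiers in a UMLS-style terminology) from clinical
notes written in a lower-resourced source language: extract natively in that
language, or translate into a better-resourced target language first and
extract there. Because spans cannot be aligned across languages without
introducing alignment error, the comparison is done at the **document
level**: each route reduces a document to the set of distinct CUIs it
mentions, and predicted sets are scored against gold sets.

## Pipeline model

Three routes ("axes") share one evaluation:

* **axis1 (native)** — span NER on the source text, then normalization of
  each mention to a CUI;
* **axis2_1 (translate, two-step)** — translation, span NER on the target
  text, then normalization;
* **axis2_2 (translate, terminology-driven)** — translation, then a one-pass
  greedy longest-match dictionary extractor that emits span, semantic group
  and CUI simultaneously.

### Nested span NER

The recognizer scores every candidate span `(start, end)` with
`end − start ≤ max_span_len` for each of the four semantic groups (CHEM,
DEVI, DISO, PROC) with an independent sigmoid, so nested and overlapping
mentions are ordinary predictions. Token encodings concatenate (i) a
softmax-weighted combination of the last `context_layers` (default 4) outputs
of a small trainable contextual stack, (ii) a static word embedding, and
(iii) max-pooled width-3 character-convolution features, which keep
out-of-vocabulary tokens informative. Span representations come from a
3-layer LSTM read over the span's token encodings, with learned softmax
weights over the layers' final states. Training minimizes binary
cross-entropy over all candidate/label pairs with Adam; mentions whose
character span does not fall on token boundaries are snapped outward to the
covering token span. Decoding keeps all candidates scoring **strictly
above** the threshold (default 0.5) with no non-maximum suppression.

All neural components run on a compact reverse-mode autodiff core written on
numpy (`xlcui._autograd`), finite-difference-checked in the test suite. The
models are deliberately small (defaults: word 20, char 16, hidden 28) so a
full experiment trains in seconds to minutes on one CPU.

Key defaults and why: `max_span_len` 8 in the API (bounds the O(n·L)
candidate set; the benchmark uses 4 because generated terms are at most 3
tokens); `pos_weight` 2.0 rebalances the rare positives among enumerated
candidates; benchmark training runs 20 epochs, enough for both axes'
recognizers to converge at the 34-document corpus size.

### Concept normalization

Normalization is treated as classification over CUIs with a cosine-softmax
head: an encoder maps a string to a unit vector, each CUI owns a unit target
vector, and logits are scaled cosines (temperature 10). The encoder is a
hashed character-trigram featurizer (512 bins) followed by a two-layer dense
network into a 32-dimensional space — deliberately lexical, since
terminology-only training has no context to exploit. Training is two-phase:

1. **phase 1** — encoder and CUI vectors are trained jointly on the terms of
   every concept covered in the primary language (their primary-language
   terms plus cross-language synonyms of those CUIs);
2. **phase 2** — the encoder is frozen; rows are added for the terms of
   concepts with *no* primary-language coverage. Each new row is a free
   vector initialized at the frozen encoder's output and fitted by softmax
   cross-entropy against frozen CUI anchors (anchors of new CUIs are the
   normalized mean of their term embeddings). Phase-1 rows and the encoder
   are bit-identical afterwards, which the tests assert.

At inference, CUIs are ranked by the best cosine over their term rows
(synonyms never crowd the list because rows collapse to CUIs by max), ties
broken by lexicographic CUI for determinism. A **semantic-group filter**
then picks the first candidate within the top *k* (default 5) whose group
matches the mention's predicted group; if none matches, the overall top-1 is
returned with a fallback flag rather than dropping the mention, preserving a
prediction for document-level scoring.

An exact-match oracle embedder (deterministic hash of the normalized string
to a pseudo-random unit vector, dimension 256) provides the retrieval upper
bound used by the oracle-pipeline tests: identical strings get cosine 1,
distinct terminology strings stay below 0.5 on the fixtures.

### Translation stage and BLEU

Real MT systems plug in as a callable from document to translated document.
The built-in dictionary translator renders each outermost gold mention
through a source→target term lexicon and vowel-shifts filler words; its two
noise modes reproduce documented machine-translation failure classes on
clinical text: **literal translation** (per-word substitution with a
confusable non-term look-alike, probability `p_literal` per mention) and
**abbreviation passthrough** (source-language abbreviations copied
untranslated, probability `p_abbrev_passthrough`). Every choice is logged.

Translation quality is measured with per-sentence BLEU: the weighted
geometric mean of clipped n-gram precisions up to order 4, averaged
arithmetically over sentences. Add-one smoothing applies on orders ≥ 2 and a
0.1/denominator floor replaces a zero unigram precision; without smoothing,
per-sentence BLEU collapses to 0 whenever any order has no match. No brevity
penalty is applied; a score of 1 therefore certifies reference-consistency
of every hypothesis n-gram, not string equality. All of this is configurable
(`BleuConfig`).

### Evaluation

* **Mention level** (NER): a prediction is correct iff a gold mention with
  the identical (start, end, label) exists, matched one-to-one; per-group
  P/R/F1 plus a pooled micro overall (macro switchable). Exact matching is
  the strictest reproducible convention.
* **Normalization**: accuracy over gold mentions (predictions on gold spans),
  isolating the linker from NER errors. An optional sub-report counts errors
  that land on the partner of a known near-synonym CUI pair.
* **Document level**: per document, predicted and gold CUIs are deduplicated
  into sets; P = |∩|/|pred|, R = |∩|/|gold|, F1 harmonic; macro-averaged over
  documents. Conventions fixed for determinism: both sets empty → P = R = 1;
  predictions empty against non-empty gold → P = 0. Gold mentions without a
  CUI are excluded and counted.
* **Confidence intervals**: empirical (basic/pivotal) bootstrap over
  documents — resample document F1 scores with replacement B = 1000 times and
  take `[2m − q_{1−α/2}, 2m − q_{α/2}]`, clipped to [0, 1]. A percentile
  variant is available by flag. Monte-Carlo calibration on Bernoulli scores
  (n = 50, 200 simulations) sits within 0.95 ± 0.05 in the suite.

## Synthetic data: what it emulates, and what it does not

Real clinical corpora and licensed terminologies cannot be redistributed, so
the generator builds a world with the same *statistical structure*:

* a bilingual terminology over the four semantic groups, with multilingual
  synonyms built from pronounceable random syllables; a configurable
  fraction of concepts gets a **near-duplicate companion** — same group,
  shared stem token, distinct CUI — reproducing the real phenomenon of
  synonym pairs holding different CUIs; a fraction gets an uppercase
  **abbreviation stored in the source language only**;
* documents interleaving filler words with planted terms; every planted term
  is a gold mention with its CUI; nested pairs plant a multi-word synonym
  and annotate its stem word as an inner mention of the same concept (so
  document-level CUI sets are well-defined under non-overlapping extractors
  while NER still has to predict genuinely nested spans);
* noisy translations with the two error modes above.

Word populations are kept disjoint by construction (different consonant
inventories per language, longer filler words, corrupted words start with a
reserved letter), so gold annotation is unambiguous and a corrupted mention
is never accidentally a terminology term.

The generator does **not** emulate: realistic clinical language or
discourse, negation/hypothesis/experiencer attributes, context-dependent
disambiguation (every surface form maps to its CUIs independently of
context), morphological inflection, or the heavy group imbalance of real
notes (group balance is configurable; real notes had almost no Devices
mentions). Passing tests therefore show the pipeline's machinery is correct
and that the directional translation-loss effect holds under controlled
noise — not that these models reach any particular accuracy on real text.

## The benchmark protocol

Defaults (`GenConfig`): 6 concepts per group, 2 synonyms per language,
ambiguous-pair rate 0.2, 42 documents of 4 sentences, 1.5 mentions/sentence,
nesting rate 0.15, abbreviation rate 0.3, `p_literal` 0.2,
`p_abbrev_passthrough` 0.5. The corpus splits 80/20 (34/8) with
half-away-from-zero rounding. The native recognizer trains on the source
split; the translated axis' recognizer trains on *noise-free* translations
of the same split (a target-language model never trained on machine-translated
text), and both are tested under the configured noise. One normalizer index
serves both axes. The sweep runs `p_literal ∈ {0, 0.2, 0.4}`.

Expected behaviour: the native axis outscores both translated axes at the
default and high noise levels, with the F1 gap growing along the noise grid.
At `p_literal = 0` translation is lossless except for abbreviation
passthrough, and a dictionary matcher on faithful translations is close to
an oracle, so strict dominance at zero noise is *not* asserted — the gap
there can be within training variance of the two recognizers.

## Numerical and design choices

* Tokenization: one regex word/punctuation tokenizer with recorded character
  offsets is the single authority for NER, the joint extractor and BLEU.
* String normalization for terminology indexing: casefold + NFKD accent
  strip + whitespace collapse.
* Tie-breaks everywhere are lexicographic by CUI; all randomness flows from
  explicit integer seeds through `numpy.random.Generator`.
* Split sizing uses `floor(x + 0.5)` (half away from zero), which reproduces
  both published split shapes 38 → 30/8 and 42 → 34/8.
* Terminology rows with a group outside the four kept groups are dropped at
  load; a CUI appearing with two groups is an error (one group per CUI is
  assumed and conflicts are flagged).
* Degenerate inputs: empty documents encode to empty matrices and predict no
  mentions; `epochs=0` leaves an initialized, runnable model; an empty
  hypothesis scores BLEU 0; empty score lists refuse to bootstrap.
* The spec-level interface of this project is a library plus the numbered
  analysis drivers under `analysis/`; no console-script CLI is shipped, the
  drivers fill that role.

## Problem sizes

The shipped experiments are sized for a single CPU: 25-concept
terminologies, 42-document corpora, 34-document training splits (the NER
recovery check uses 200 training documents), bootstrap B = 1000, 200
Monte-Carlo coverage simulations, 10,000 randomized group-filter trials.
Every size is a config field and scales up unchanged.

## Known limitations

* The recognizer and normalizer are desk-scale stand-ins wired like their
  full-scale counterparts (pretrained contextual encoders would slot into
  the same interfaces); absolute scores on real corpora are out of scope.
* The joint dictionary extractor cannot produce overlapping mentions by
  design; it represents terminology-driven taggers, not nested NER.
* Phase-2 fitting assumes row vectors (not the encoder) carry the
  secondary-language information; with very few synonyms per concept the
  fitted rows stay close to their initialization.
* Document-level scoring hides within-document mention multiplicity; a CUI
  found once counts the same as one found five times (this is intentional,
  but it means mention-frequency errors are invisible at that level).
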