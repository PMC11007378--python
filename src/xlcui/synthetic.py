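"""Synthetic bilingual terminologies, annotated corpora and noisy translations.

Restricted clinical corpora and the licensed UMLS Metathesaurus cannot be
redistributed, so every downstream stage of the pipeline is exercised on
generated data that emulates their statistical structure:

* a bilingual terminology whose concepts carry synonyms in a source language
  (``FRE``) and a target language (``ENG``), spread over the four semantic
  groups, with a configurable fraction of near-duplicate concept pairs that
  share a surface token but have distinct CUIs (the "cardiac ultrasound" vs
  "echocardiography" phenomenon), and source-only uppercase abbreviations
  (the "MFIU" phenomenon);
* annotated documents interleaving filler words with planted terminology
  terms, every planted term a gold mention with its CUI and group, with
  optional properly nested mention pairs;
* noisy document "translations" exhibiting two documented machine-translation
  error modes: over-literal translation (word-level corruption yielding a
  string absent from the terminology) and untranslated abbreviations.

Vocabulary construction keeps the three word populations disjoint by shape:
source term words use one consonant inventory, target term words another,
filler words are longer, and corrupted words start with ``q``, which no
generated vocabulary uses. Filler is therefore never a terminology term and
corruption never collides with a real term.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass

import numpy as np

from .documents import AnnotatedDocument, Mention, ParallelDocument
from .terminology import SEMANTIC_GROUPS, Concept, Terminology, lookup_exact

SOURCE_LANG = "FRE"
TARGET_LANG = "ENG"

_SRC_CONS = "bdglmprtv"
_TGT_CONS = "cfhknswzj"
_VOWELS = "aeiou"
_VOWEL_SHIFT = str.maketrans("aeiou", "eioua")


@dataclass
class GenConfig:
    """Knobs of the synthetic world; defaults are the benchmark conditions."""

    concepts_per_group: int = 6
    synonyms_per_language: int = 2
    ambiguous_pair_rate: float = 0.2
    docs: int = 42
    sentences_per_doc: int = 4
    mentions_per_sentence: float = 1.5
    nesting_rate: float = 0.15
    abbreviation_rate: float = 0.3
    p_literal: float = 0.2
    p_abbrev_passthrough: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("ambiguous_pair_rate", "nesting_rate", "abbreviation_rate",
                     "p_literal", "p_abbrev_passthrough"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("concepts_per_group", "synonyms_per_language", "docs",
                     "sentences_per_doc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.p_literal + self.p_abbrev_passthrough > 1.0:
            raise ValueError("p_literal + p_abbrev_passthrough must be <= 1")


def _word(rng: np.random.Generator, consonants: str, n_syll: int) -> str:
    return "".join(
        consonants[rng.integers(len(consonants))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syll)
    )


def _fresh_word(rng, consonants, n_syll, used: set[str]) -> str:
    for _ in range(1000):
        w = _word(rng, consonants, n_syll)
        if w not in used:
            used.add(w)
            return w
    raise RuntimeError("vocabulary exhausted")


def is_abbreviation(term: str) -> bool:
    return term.isupper() and 2 <= len(term) <= 4 and " " not in term


# ---------------------------------------------------------------------------
# terminology
# ---------------------------------------------------------------------------

def generate_terminology(config: GenConfig) -> Terminology:
    """Build the bilingual four-group terminology for a configuration.

    Each base concept has a single-word stem synonym plus
    ``synonyms_per_language - 1`` two-word (modifier + stem) synonyms in each
    language, term *i* in the source language aligned with term *i* in the
    target language. A fraction ``ambiguous_pair_rate`` of base concepts gets
    a near-duplicate companion concept (same group, distinct CUI) whose terms
    reuse the stem token under a different modifier. A fraction
    ``abbreviation_rate`` gets an uppercase abbreviation stored in the source
    language only. Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    used: set[str] = set()
    used_abbrev: set[str] = set()
    concepts: list[Concept] = []
    counter = 1

    def next_cui() -> str:
        nonlocal counter
        cui = f"C{counter:07d}"
        counter += 1
        return cui

    for group in SEMANTIC_GROUPS:
        for _ in range(config.concepts_per_group):
            src_stem = _fresh_word(rng, _SRC_CONS, 2 + int(rng.integers(2)), used)
            tgt_stem = _fresh_word(rng, _TGT_CONS, 2 + int(rng.integers(2)), used)
            src_terms = [src_stem]
            tgt_terms = [tgt_stem]
            for _ in range(config.synonyms_per_language - 1):
                src_terms.append(
                    f"{_fresh_word(rng, _SRC_CONS, 2, used)} {src_stem}")
                tgt_terms.append(
                    f"{_fresh_word(rng, _TGT_CONS, 2, used)} {tgt_stem}")
            make_ambiguous = rng.random() < config.ambiguous_pair_rate
            make_abbrev = rng.random() < config.abbreviation_rate
            terms = [(SOURCE_LANG, t, i == 0) for i, t in enumerate(src_terms)]
            terms += [(TARGET_LANG, t, i == 0) for i, t in enumerate(tgt_terms)]
            if make_abbrev:
                abbr = _fresh_abbrev(rng, used_abbrev)
                terms.append((SOURCE_LANG, abbr, False))
            concepts.append(Concept(next_cui(), group, terms))
            if make_ambiguous:
                # companion concept sharing the stem token, distinct CUI
                amb_terms = []
                for lang, stem in ((SOURCE_LANG, src_stem), (TARGET_LANG, tgt_stem)):
                    cons = _SRC_CONS if lang == SOURCE_LANG else _TGT_CONS
                    for i in range(config.synonyms_per_language):
                        mod = _fresh_word(rng, cons, 3, used)
                        amb_terms.append((lang, f"{mod} {stem}", i == 0))
                concepts.append(Concept(next_cui(), group, amb_terms))
    return Terminology(concepts)


def _fresh_abbrev(rng, used: set[str]) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for _ in range(1000):
        n = 2 + int(rng.integers(3))
        a = "".join(letters[rng.integers(26)] for _ in range(n))
        if a not in used:
            used.add(a)
            return a
    raise RuntimeError("abbreviation space exhausted")


def build_lexicon(terminology: Terminology) -> dict[str, str]:
    """Faithful source→target term map derived from synonym alignment.

    Source term *i* of a concept maps to target term *i*; abbreviation terms
    (extra source-only rows) map to the concept's preferred target term.
    """
    lexicon: dict[str, str] = {}
    for concept in terminology:
        src = [t for lang, t, _ in concept.terms if lang == SOURCE_LANG]
        tgt = [t for lang, t, _ in concept.terms if lang == TARGET_LANG]
        if not tgt:
            continue
        for i, term in enumerate(src):
            lexicon[term] = tgt[i] if i < len(tgt) and not is_abbreviation(term) else tgt[0]
    return lexicon


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

def _filler_word(rng, used: set[str]) -> str:
    return _fresh_word(rng, _SRC_CONS, 4, used)


def generate_corpus(terminology: Terminology, config: GenConfig) -> list[AnnotatedDocument]:
    """Generate annotated source-language documents over a terminology.

    Sentences interleave filler words (4-syllable, never terminology terms)
    with planted source-language terms; every planted term becomes a gold
    mention carrying its CUI and group. With probability ``nesting_rate`` a
    planted mention is a multi-word synonym whose stem word is additionally
    annotated as a properly nested inner mention. The mention count per
    sentence is Poisson with rate ``mentions_per_sentence`` (forced to at
    least 1 when the rate is >= 1). Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 1)
    entries = []  # (cui, group, term)
    multiword = []  # (cui, group, term, stem) for nesting
    for cui, group, lang, term in terminology.iter_terms({SOURCE_LANG}):
        entries.append((cui, group, term))
        words = term.split(" ")
        if len(words) >= 2 and not is_abbreviation(term):
            stem = words[-1]
            # the inner stem must be a term of the same concept to be gold:
            # the nested pair then contributes one CUI, so document-level
            # CUI sets are well-defined under non-overlapping extractors too
            hits = lookup_exact(stem, SOURCE_LANG, terminology)
            if any(h[0] == cui for h in hits):
                multiword.append((cui, group, term, stem, cui, group))
    if not entries:
        raise ValueError("terminology has no source-language terms")

    filler_vocab: set[str] = set()
    fillers = [_filler_word(rng, filler_vocab) for _ in range(40)]

    docs = []
    for d in range(config.docs):
        parts: list[str] = []
        mentions: list[Mention] = []
        pos = 0

        def emit(s: str):
            nonlocal pos
            if parts:
                parts.append(" ")
                pos += 1
            parts.append(s)
            start = pos
            pos += len(s)
            return start, pos

        for _s in range(config.sentences_per_doc):
            n = int(rng.poisson(config.mentions_per_sentence))
            if config.mentions_per_sentence >= 1:
                n = max(1, n)
            for _ in range(1 + int(rng.integers(3))):
                emit(fillers[rng.integers(len(fillers))])
            for _m in range(n):
                nest = multiword and rng.random() < config.nesting_rate
                if nest:
                    cui, group, term, stem, in_cui, in_group = \
                        multiword[rng.integers(len(multiword))]
                    start, end = emit(term)
                    mentions.append(Mention(start, end, group, cui=cui))
                    in_start = start + term.rindex(stem)
                    mentions.append(
                        Mention(in_start, in_start + len(stem), in_group, cui=in_cui))
                else:
                    cui, group, term = entries[rng.integers(len(entries))]
                    start, end = emit(term)
                    mentions.append(Mention(start, end, group, cui=cui))
                for _ in range(1 + int(rng.integers(3))):
                    emit(fillers[rng.integers(len(fillers))])
            parts.append(" .")
            pos += 2
        docs.append(AnnotatedDocument(f"doc{d:04d}", "".join(parts), sorted(mentions)))
    return docs


# ---------------------------------------------------------------------------
# translation noise
# ---------------------------------------------------------------------------

def corrupt_word(word: str) -> str:
    """Literal-translation corruption: a confusable look-alike that is
    guaranteed not to be a vocabulary word (no generated word starts with q)."""
    return "q" + word[1:] if len(word) > 1 else "q" + word


def _map_filler(word: str) -> str:
    return word.translate(_VOWEL_SHIFT)


def apply_translation_noise(
    doc: AnnotatedDocument, lexicon: dict[str, str], config: GenConfig
) -> ParallelDocument:
    """Emit a noisy target-language rendering of an annotated document.

    Each *outermost* gold mention is translated as a unit: faithfully via the
    lexicon, or (probability ``p_literal``) as a per-word corrupted "literal"
    variant absent from the terminology, or — for abbreviation terms, with
    probability ``p_abbrev_passthrough`` — copied through untranslated.
    Nested inner mentions are projected onto the corresponding emitted word.
    Filler words are vowel-shifted word by word. Deterministic under
    ``config.seed`` and the document id.
    """
    seed = (config.seed * 1000003 + zlib.crc32(doc.doc_id.encode())) % (2**31)
    rng = np.random.default_rng(seed)

    mentions = doc.sorted_mentions()
    # outermost mentions: not contained in any other mention
    outer = [
        m for m in mentions
        if not any(o is not m and o.start <= m.start and m.end <= o.end
                   for o in mentions)
    ]
    inner = [m for m in mentions if m not in outer]

    out: list[str] = []
    out_pos = 0
    target_mentions: list[Mention] = []
    noise_log: list[tuple[str, tuple[int, int], str]] = []

    def emit_text(s: str) -> tuple[int, int]:
        nonlocal out_pos
        out.append(s)
        start = out_pos
        out_pos += len(s)
        return start, out_pos

    def emit_filler(segment: str):
        mapped = "".join(
            _map_filler(tok) if tok.strip() and tok.isalpha() else tok
            for tok in _split_keep(segment)
        )
        emit_text(mapped)

    cursor = 0
    for m in outer:
        if m.start > cursor:
            emit_filler(doc.text[cursor:m.start])
        surface = doc.surface(m)
        if surface not in lexicon:
            raise KeyError(f"lexicon has no entry for planted term {surface!r}")
        faithful = lexicon[surface]
        u = rng.random()
        if u < config.p_literal:
            words = faithful.split(" ")
            flags = rng.random(len(words)) < 0.5
            if not flags.any():
                flags[int(rng.integers(len(words)))] = True
            emitted = " ".join(
                corrupt_word(w) if f else w for w, f in zip(words, flags))
            op = "literal"
        elif is_abbreviation(surface) and u < config.p_literal + config.p_abbrev_passthrough:
            emitted = surface
            op = "abbrev_passthrough"
        else:
            emitted = faithful
            op = "faithful"
        start, end = emit_text(emitted)
        target_mentions.append(
            Mention(start, end, m.label, cui=m.cui, score=m.score))
        noise_log.append((op, (m.start, m.end), emitted))
        # project nested inner mentions by word index from the end
        src_words = surface.split(" ")
        for im in inner:
            if m.start <= im.start and im.end <= m.end:
                iw = doc.surface(im).split(" ")
                from_end = len(src_words) - src_words.index(iw[0])
                ewords = emitted.split(" ")
                j = max(0, len(ewords) - from_end)
                w_start = start + len(" ".join(ewords[:j])) + (1 if j else 0)
                w_end = w_start + len(" ".join(ewords[j:j + len(iw)]))
                target_mentions.append(
                    Mention(w_start, w_end, im.label, cui=im.cui, score=im.score))
        cursor = m.end
    if cursor < len(doc.text):
        emit_filler(doc.text[cursor:])

    return ParallelDocument(
        source=doc,
        target_text="".join(out),
        target_mentions=sorted(target_mentions),
        noise_log=noise_log,
    )


def _split_keep(segment: str) -> list[str]:
    """Split into alternating word / non-word chunks, preserving everything."""
    return re.findall(r"[^\W\d_]+|[^\w]+|\d+", segment, re.UNICODE)


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def split_corpus(docs: list, train_frac: float, seed: int) -> tuple[list, list]:
    """Seed-deterministic disjoint shuffle split.

    Train size is ``round(train_frac * n)`` with half-away-from-zero
    rounding, which reproduces the 38 → 30/8 and 42 → 34/8 splits of an
    80/20 protocol.
    """
    n = len(docs)
    if n < 2:
        raise ValueError("need at least 2 documents to split")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    n_train = int(np.floor(train_frac * n + 0.5))
    order = np.random.default_rng(seed).permutation(n)
    train = [docs[i] for i in sorted(order[:n_train])]
    test = [docs[i] for i in sorted(order[n_train:])]
    return train, test
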