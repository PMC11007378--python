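"""UMLS-like terminology: concepts keyed by CUI with multilingual synonyms.

A terminology restricted to four coarse semantic groups — Chemicals & Drugs
(CHEM), Devices (DEVI), Disorders (DISO) and Procedures (PROC) — is the
reference against which mentions are normalized. Each concept carries a
Concept Unique Identifier (CUI, e.g. ``C0013516``), a single semantic group
and a set of (language, surface string) synonyms. Distinct CUIs may hold
near-synonymous surface forms; that ambiguity is a property of real
metathesauri and is preserved here.

The on-disk format is a minimal self-contained pipe-delimited dialect, one
term per row: ``CUI|LANG|TERM|GROUP|PREF``.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

SEMANTIC_GROUPS = ("CHEM", "DEVI", "DISO", "PROC")

_CUI_RE = re.compile(r"^C\d+$")
_WS_RE = re.compile(r"\s+")


class TerminologyError(ValueError):
    pass


def normalize_term(s: str) -> str:
    """Casefold, strip accents and collapse whitespace for exact indexing."""
    s = unicodedata.normalize("NFKD", s)
    s = "".join(c for c in s if not unicodedata.combining(c))
    return _WS_RE.sub(" ", s).strip().casefold()


@dataclass
class Concept:
    """One concept: a CUI, its semantic group, and multilingual terms.

    ``terms`` is a list of (language-code, surface-string, preferred-flag).
    """

    cui: str
    group: str
    terms: list[tuple[str, str, bool]] = field(default_factory=list)

    def __post_init__(self):
        if not _CUI_RE.match(self.cui):
            raise TerminologyError(f"invalid CUI {self.cui!r}")
        if self.group not in SEMANTIC_GROUPS:
            raise TerminologyError(f"invalid semantic group {self.group!r}")

    def languages(self) -> set[str]:
        return {lang for lang, _, _ in self.terms}


class Terminology:
    """Collection of concepts with an exact-match (normalized string, lang) index."""

    def __init__(self, concepts: list[Concept]):
        self.concepts: dict[str, Concept] = {}
        for c in concepts:
            if not c.terms:
                raise TerminologyError(f"concept {c.cui} has no terms")
            if c.cui in self.concepts:
                raise TerminologyError(f"duplicate CUI {c.cui}")
            self.concepts[c.cui] = c
        self._index: dict[tuple[str, str], list[str]] = {}
        for c in self.concepts.values():
            for lang, term, _pref in c.terms:
                key = (normalize_term(term), lang)
                bucket = self._index.setdefault(key, [])
                if c.cui not in bucket:
                    bucket.append(c.cui)
        for bucket in self._index.values():
            bucket.sort()

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self):
        return iter(self.concepts.values())

    def cuis(self) -> list[str]:
        return sorted(self.concepts)

    def group_of(self, cui: str) -> str:
        return self.concepts[cui].group

    def iter_terms(self, langs: set[str] | None = None):
        """Yield (cui, group, lang, term) over all stored terms."""
        for cui in self.cuis():
            c = self.concepts[cui]
            for lang, term, _pref in c.terms:
                if langs is None or lang in langs:
                    yield cui, c.group, lang, term


def load_terminology(path: str | Path, allowed_groups=frozenset(SEMANTIC_GROUPS)) -> Terminology:
    """Load a pipe-delimited terminology file, keeping only allowed groups.

    Rows whose GROUP is outside ``allowed_groups`` are dropped silently (the
    analysis restricts itself to four groups); duplicate (CUI, LANG, TERM)
    rows are deduplicated with a warning; a CUI appearing with two different
    groups is a conflict and raises.
    """
    path = Path(path)
    rows: dict[str, Concept] = {}
    seen: set[tuple[str, str, str]] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("|")
            if len(parts) != 5:
                raise TerminologyError(
                    f"{path}:{lineno}: expected 5 pipe-delimited fields, got {len(parts)}"
                )
            cui, lang, term, group, pref = parts
            if not _CUI_RE.match(cui):
                raise TerminologyError(f"{path}:{lineno}: invalid CUI {cui!r}")
            if group not in SEMANTIC_GROUPS:
                raise TerminologyError(f"{path}:{lineno}: unknown group {group!r}")
            if pref not in ("0", "1"):
                raise TerminologyError(f"{path}:{lineno}: PREF must be 0 or 1")
            if not term:
                raise TerminologyError(f"{path}:{lineno}: empty term")
            if group not in allowed_groups:
                continue
            key = (cui, lang, term)
            if key in seen:
                logger.warning("%s:%d: duplicate row %s dropped", path, lineno, key)
                continue
            seen.add(key)
            if cui in rows:
                if rows[cui].group != group:
                    raise TerminologyError(
                        f"{path}:{lineno}: CUI {cui} assigned to both "
                        f"{rows[cui].group} and {group}"
                    )
                rows[cui].terms.append((lang, term, pref == "1"))
            else:
                rows[cui] = Concept(cui, group, [(lang, term, pref == "1")])
    return Terminology(list(rows.values()))


def save_terminology(terminology: Terminology, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for cui in terminology.cuis():
            c = terminology.concepts[cui]
            for lang, term, pref in c.terms:
                fh.write(f"{cui}|{lang}|{term}|{c.group}|{1 if pref else 0}\n")


def lookup_exact(term: str, lang: str, terminology: Terminology) -> list[tuple[str, str]]:
    """All (cui, group) indexed under the normalized string for a language.

    Results are CUI-sorted; an absent key is an empty list, never an error.
    """
    cuis = terminology._index.get((normalize_term(term), lang), [])
    return [(cui, terminology.group_of(cui)) for cui in cuis]


def partition_terms_by_language_coverage(
    terminology: Terminology, primary_lang: str, secondary_lang: str
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Split terms of two languages by whether their concept covers the primary language.

    Returns ``(shared, secondary_only)`` where each element is a
    (cui, lang, term) triple. ``secondary_only`` holds the terms of concepts
    that have *no* term at all in ``primary_lang`` (e.g. English-only
    concepts when the primary language is French); ``shared`` holds every
    other term of the two languages. The two sides are disjoint and jointly
    cover all terms in the two languages.
    """
    langs_present = {lang for c in terminology for lang in c.languages()}
    for lang in (primary_lang, secondary_lang):
        if lang not in langs_present:
            logger.warning("language %r not present in terminology", lang)
    shared: list[tuple[str, str, str]] = []
    secondary_only: list[tuple[str, str, str]] = []
    for cui in terminology.cuis():
        c = terminology.concepts[cui]
        has_primary = primary_lang in c.languages()
        for lang, term, _pref in c.terms:
            if lang not in (primary_lang, secondary_lang):
                continue
            (shared if has_primary else secondary_only).append((cui, lang, term))
    return shared, secondary_only
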