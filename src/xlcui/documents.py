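"""Annotated documents, mention spans, and BRAT standoff interchange.

Mentions are character spans (0-based, half-open) over a document's text,
labeled with one of the four semantic groups and, once normalized, a CUI.
Nesting and overlap are permitted: a span may properly contain another.

Standoff dialect: a ``.txt`` file with the raw text and an ``.ann`` file with
``T<i>\\t<LABEL> <start> <end>\\t<surface>`` span lines plus
``N<i>\\tReference T<i> UMLS:<CUI>`` normalization lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from .terminology import SEMANTIC_GROUPS


class StandoffError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Mention:
    start: int
    end: int
    label: str
    cui: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span ({self.start}, {self.end})")
        if self.label not in SEMANTIC_GROUPS:
            raise ValueError(f"invalid label {self.label!r}")

    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    mentions: list[Mention] = field(default_factory=list)

    def __post_init__(self):
        for m in self.mentions:
            if m.end > len(self.text):
                raise ValueError(
                    f"{self.doc_id}: mention span ({m.start}, {m.end}) exceeds "
                    f"text length {len(self.text)}"
                )

    def surface(self, m: Mention) -> str:
        return self.text[m.start:m.end]

    def sorted_mentions(self) -> list[Mention]:
        return sorted(self.mentions)


@dataclass
class ParallelDocument:
    """A source document with its (possibly noisy) translation.

    ``noise_log`` records, per emitted mention, which operation produced it:
    ``faithful`` (lexicon translation), ``literal`` (word-level corruption
    that mimics an over-literal machine translation), or
    ``abbrev_passthrough`` (an abbreviation copied untranslated).
    """

    source: AnnotatedDocument
    target_text: str
    target_mentions: list[Mention] = field(default_factory=list)
    noise_log: list[tuple[str, tuple[int, int], str]] = field(default_factory=list)

    def target_document(self) -> AnnotatedDocument:
        return AnnotatedDocument(self.source.doc_id, self.target_text,
                                 list(self.target_mentions))


def write_standoff(docs: list[AnnotatedDocument], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (directory / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        lines = []
        for i, m in enumerate(doc.sorted_mentions(), start=1):
            surface = doc.surface(m)
            lines.append(f"T{i}\t{m.label} {m.start} {m.end}\t{surface}")
            if m.cui is not None:
                lines.append(f"N{i}\tReference T{i} UMLS:{m.cui}")
        content = "\n".join(lines)
        (directory / f"{doc.doc_id}.ann").write_text(
            content + "\n" if content else "", encoding="utf-8")


def read_standoff(directory: str | Path) -> list[AnnotatedDocument]:
    """Read paired .txt/.ann files; inverse of write_standoff up to ordering."""
    directory = Path(directory)
    docs = []
    for txt_path in sorted(directory.glob("*.txt")):
        doc_id = txt_path.stem
        text = txt_path.read_text(encoding="utf-8")
        ann_path = directory / f"{doc_id}.ann"
        spans: dict[str, tuple[int, int, str]] = {}
        cuis: dict[str, str] = {}
        if ann_path.exists():
            for lineno, line in enumerate(ann_path.read_text(encoding="utf-8").splitlines(), 1):
                if not line.strip():
                    continue
                tid, rest = line.split("\t", 1)
                if tid.startswith("T"):
                    header = rest.split("\t")[0]
                    label, start_s, end_s = header.split(" ")
                    start, end = int(start_s), int(end_s)
                    if end > len(text):
                        raise StandoffError(
                            f"{ann_path}:{lineno}: span ({start}, {end}) exceeds "
                            f"text length {len(text)}")
                    spans[tid] = (start, end, label)
                elif tid.startswith("N"):
                    parts = rest.split(" ")
                    ref_t = parts[1]
                    if ref_t not in spans:
                        raise StandoffError(
                            f"{ann_path}:{lineno}: N-line references unknown {ref_t}")
                    cuis[ref_t] = parts[2].split(":", 1)[1]
        mentions = [
            Mention(start, end, label, cui=cuis.get(tid))
            for tid, (start, end, label) in spans.items()
        ]
        docs.append(AnnotatedDocument(doc_id, text, sorted(mentions)))
    return docs


def strip_cuis(doc: AnnotatedDocument) -> AnnotatedDocument:
    """Copy of a document whose mentions keep spans and labels but lose CUIs."""
    return AnnotatedDocument(doc.doc_id, doc.text,
                             [replace(m, cui=None) for m in doc.mentions])
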