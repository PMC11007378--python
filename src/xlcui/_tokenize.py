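"""Single tokenization authority for the whole pipeline.

Word/punctuation regex tokenizer that records character offsets so that
token-level predictions round-trip exactly to standoff character spans.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


@dataclass(frozen=True)
class Token:
    text: str
    start: int  # character offset, 0-based
    end: int    # exclusive


def tokenize(text: str) -> list[Token]:
    """Split text into word / single-punctuation tokens with offsets."""
    return [Token(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def token_texts(text: str) -> list[str]:
    return [t.text for t in tokenize(text)]
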