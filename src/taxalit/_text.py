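"""Tokenisation and name normalisation shared by the registry and the matcher.

All name/text comparisons in the package go through these functions so that a
registry name and an n-gram extracted from prose are normalised identically:
lowercase, punctuation stripped at token edges, hyphens treated as token
separators, internal whitespace collapsed.
"""

from __future__ import annotations

import re
import string

# token-edge punctuation: ASCII plus common typographic quotes/dashes/ellipsis
_EDGE_PUNCT = string.punctuation + "“”‘’«»…–—"

# sentence-final punctuation terminates bigram adjacency
_SENTENCE_SPLIT = re.compile(r"[.!?]+(?=\s|$)")

# characters that split a single raw token into several
_TOKEN_SPLIT = re.compile(r"[-–—/]+")


def split_sentences(text: str) -> list[str]:
    """Split text on sentence-final punctuation (``.``, ``!``, ``?``)."""
    if not text:
        return []
    return [s for s in _SENTENCE_SPLIT.split(text) if s.strip()]


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens; hyphens/slashes split, edge punctuation stripped."""
    tokens: list[str] = []
    for raw in text.split():
        for part in _TOKEN_SPLIT.split(raw):
            tok = part.strip(_EDGE_PUNCT).lower()
            if tok:
                tokens.append(tok)
    return tokens


def normalize_name(name: str) -> str:
    """Canonical form of a scientific name or n-gram for index lookup."""
    return " ".join(tokenize(name))
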