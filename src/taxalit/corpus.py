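"""Bibliographic corpus handling: RIS reading, ecosystem filtering, time bins.

A corpus is a list of :class:`BibRecord` (title, abstract, author keywords,
year).  Records are assigned to ecosystems by exact multi-word phrase match
("coral reef", "seagrass meadow", ...) over the three searchable fields —
single words like "coral" on their own never qualify.  Database-generated
keyword fields (KeyWords Plus style) are ignored on input; only author
keywords are searchable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from ._text import split_sentences, tokenize
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

#: Publication-year window of the analysis (inclusive).
DEFAULT_YEAR_RANGE: tuple[int, int] = (1957, 2009)

#: Default period boundaries: upper (inclusive) year of each bin.
DEFAULT_PERIOD_BOUNDARIES: tuple[int, ...] = (1999, 2006, 2009)

#: The study's ecosystem queries: exact phrases incl. singular/plural variants.
DEFAULT_QUERIES: dict[str, tuple[str, ...]] = {
    "coral_reef": ("coral reef", "coral reefs"),
    "kelp_forest": ("kelp forest", "kelp forests"),
    "mangrove_forest": ("mangrove forest", "mangrove forests"),
    "seagrass_bed": (
        "seagrass bed", "seagrass beds", "seagrass meadow", "seagrass meadows",
    ),
}


@dataclass(frozen=True)
class BibRecord:
    """One publication's searchable fields."""

    record_id: str
    title: str
    abstract: str
    author_keywords: tuple[str, ...]
    year: int

    def searchable_fields(self) -> tuple[str, ...]:
        """Title, each author keyword, abstract — the fields that are mined."""
        return (self.title, *self.author_keywords, self.abstract)


@dataclass(frozen=True)
class EcosystemQuery:
    """An ecosystem label with its exact search phrases (each >= 2 words)."""

    ecosystem_label: str
    phrases: tuple[str, ...]

    def __post_init__(self) -> None:
        for p in self.phrases:
            if len(p.split()) < 2:
                raise ConfigurationError(
                    f"query phrase {p!r} has fewer than 2 words; single words "
                    "are not admissible ecosystem search terms"
                )


def default_queries() -> list[EcosystemQuery]:
    return [EcosystemQuery(k, v) for k, v in DEFAULT_QUERIES.items()]


# ---------------------------------------------------------------------------
# RIS input
# ---------------------------------------------------------------------------

# RIS tags we interpret; KP-style database-generated keywords are dropped.
_IGNORED_TAGS = {"KP", "N1", "C1"}

_RIS_TAG = re.compile(r"^([A-Z][A-Z0-9])  -\s?(.*)$")


def read_ris(
    path: str | Path,
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
) -> list[BibRecord]:
    """Parse a tagged RIS export into :class:`BibRecord` objects.

    Entries are delimited by ``ER``; ``TI``/``AB``/``KW``/``PY`` fill the
    record, an optional ``ID`` tag supplies the record id (else sequential).
    Continuation lines extend the previous tag.  Entries without a parseable
    in-range year, or with both title and abstract empty, are skipped with a
    logged warning.
    """
    path = Path(path)
    entries: list[dict] = []
    current: dict | None = None
    last_key: str | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            m = _RIS_TAG.match(line)
            if m:
                tag, value = m.group(1), m.group(2)
                if tag == "TY":
                    current = {"KW": []}
                    last_key = None
                    continue
                if current is None:
                    continue
                if tag == "ER":
                    entries.append(current)
                    current, last_key = None, None
                elif tag == "KW":
                    current["KW"].append(value.strip())
                    last_key = "KW"
                elif tag in ("TI", "AB", "PY", "ID"):
                    current[tag] = value.strip()
                    last_key = tag
                elif tag in _IGNORED_TAGS:
                    last_key = None
                else:
                    last_key = None
            elif current is not None and last_key and line.strip():
                if last_key == "KW":
                    current["KW"][-1] += " " + line.strip()
                else:
                    current[last_key] += " " + line.strip()
    if current is not None:
        logger.warning("%s: trailing entry without ER tag skipped", path.name)

    records: list[BibRecord] = []
    n_skipped = 0
    lo, hi = year_range
    for i, entry in enumerate(entries, start=1):
        rid = entry.get("ID") or f"rec{i:06d}"
        title = entry.get("TI", "")
        abstract = entry.get("AB", "")
        try:
            year = int(str(entry.get("PY", "")).split("/")[0])
        except ValueError:
            logger.warning("entry %s skipped: missing or unparseable year", rid)
            n_skipped += 1
            continue
        if not (lo <= year <= hi):
            logger.warning("entry %s skipped: year %d outside %d-%d", rid, year, lo, hi)
            n_skipped += 1
            continue
        if not title.strip() and not abstract.strip():
            logger.warning("entry %s skipped: no title and no abstract", rid)
            n_skipped += 1
            continue
        records.append(
            BibRecord(rid, title, abstract, tuple(entry.get("KW", [])), year)
        )
    if n_skipped:
        logger.warning("%s: %d of %d entries skipped", path.name, n_skipped, len(entries))
    return records


def write_ris(records: Sequence[BibRecord], path: str | Path) -> None:
    """Write records in the same tagged format :func:`read_ris` reads."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write("TY  - JOUR\n")
            fh.write(f"ID  - {rec.record_id}\n")
            fh.write(f"TI  - {rec.title}\n")
            if rec.abstract:
                fh.write(f"AB  - {rec.abstract}\n")
            for kw in rec.author_keywords:
                fh.write(f"KW  - {kw}\n")
            fh.write(f"PY  - {rec.year}\n")
            fh.write("ER  - \n")


# ---------------------------------------------------------------------------
# Ecosystem phrase filter
# ---------------------------------------------------------------------------

def _phrase_in_tokens(phrase_tokens: Sequence[str], tokens: Sequence[str]) -> bool:
    k = len(phrase_tokens)
    if k == 0 or k > len(tokens):
        return False
    target = tuple(phrase_tokens)
    return any(tuple(tokens[i:i + k]) == target for i in range(len(tokens) - k + 1))


def record_matches_query(record: BibRecord, query: EcosystemQuery) -> bool:
    """True if any query phrase occurs whole in any searchable field.

    Matching is case-insensitive on whitespace tokens with edge punctuation
    stripped and hyphens splitting tokens ("coral-reef" matches "coral reef");
    phrases must not span sentence-final punctuation.
    """
    phrase_token_lists = [tokenize(p) for p in query.phrases]
    for text in record.searchable_fields():
        for sentence in split_sentences(text):
            toks = tokenize(sentence)
            if any(_phrase_in_tokens(pt, toks) for pt in phrase_token_lists):
                return True
    return False


def filter_corpus(
    records: Iterable[BibRecord],
    queries: Sequence[EcosystemQuery] | None = None,
) -> dict[str, set[str]]:
    """Assign records to every ecosystem whose phrases they contain.

    Returns ``{ecosystem_label: {record_id, ...}}``.  A record may belong to
    several ecosystems; records matching no query are dropped.
    """
    if queries is None:
        queries = default_queries()
    out: dict[str, set[str]] = {q.ecosystem_label: set() for q in queries}
    for rec in records:
        for q in queries:
            if record_matches_query(rec, q):
                out[q.ecosystem_label].add(rec.record_id)
    return out


# ---------------------------------------------------------------------------
# Time periods
# ---------------------------------------------------------------------------

def split_periods(
    records: Iterable[BibRecord],
    boundaries: Sequence[int] = DEFAULT_PERIOD_BOUNDARIES,
) -> dict[str, list[BibRecord]]:
    """Partition records into periods by publication year.

    ``boundaries`` are the inclusive upper years of each bin; the first bin is
    open below.  Defaults give pre-2000, 2000–2006 and 2007–2009.  A record
    published after the last boundary raises :class:`ConfigurationError`.
    """
    bounds = list(boundaries)
    if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
        raise ConfigurationError("period boundaries must be strictly increasing")
    labels = [f"pre-{bounds[0] + 1}"] + [
        f"{lo + 1}-{hi}" for lo, hi in zip(bounds, bounds[1:])
    ]
    out: dict[str, list[BibRecord]] = {lab: [] for lab in labels}
    for rec in records:
        for hi, lab in zip(bounds, labels):
            if rec.year <= hi:
                out[lab].append(rec)
                break
        else:
            raise ConfigurationError(
                f"record {rec.record_id!r} year {rec.year} falls outside all bins"
            )
    return out
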