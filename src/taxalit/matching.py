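"""Taxonomic name recognition in bibliographic text.

Every unique one- and two-word sequence from a record's title, author
keywords and abstract is matched against the registry's name index.  Synonym
hits are resolved to their valid names; a normalised string that resolves to
more than one valid taxon (a homonym, e.g. a genus name valid in two
kingdoms) is flagged ambiguous and, under the default policy, excluded from
assignment.  A record is retained only when at least one unambiguous match
places it at phylum level or better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._text import split_sentences, tokenize
from .corpus import BibRecord
from .registry import RANKS, TaxonomyRegistry

logger = logging.getLogger(__name__)

_RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}


@dataclass(frozen=True)
class MatchResult:
    """One n-gram hit resolved against the registry."""

    record_id: str
    matched_string: str
    taxon_id: str        # valid (synonym-resolved) taxon
    rank: str
    ambiguous: bool = False


@dataclass(frozen=True)
class RecordAssignment:
    """Per-record taxonomic assignment (presence/absence semantics)."""

    record_id: str
    species_set: frozenset[str]   # valid species taxon_ids
    class_set: frozenset[str]     # class names implied by class-or-better matches
    phylum_or_better: bool


def extract_ngrams(
    title: str,
    keywords: Sequence[str] = (),
    abstract: str = "",
) -> set[str]:
    """Unique normalised unigrams and adjacent bigrams over the three fields.

    Bigrams never span sentence-final punctuation, and each keyword is its own
    unit (no bigram joins two keywords).  Empty input yields the empty set.
    """
    grams: set[str] = set()
    for field in (title, *keywords, abstract):
        if not field:
            continue
        for sentence in split_sentences(field):
            toks = tokenize(sentence)
            grams.update(toks)
            grams.update(f"{a} {b}" for a, b in zip(toks, toks[1:]))
    return grams


def match_record(
    ngrams: Iterable[str],
    registry: TaxonomyRegistry,
    record_id: str = "",
) -> list[MatchResult]:
    """Match n-grams against the registry index, resolving synonyms.

    Each n-gram found in the index yields one :class:`MatchResult` per
    distinct valid taxon it resolves to; when a single string resolves to
    several valid taxa (a homonym) all its results are flagged ``ambiguous``.
    """
    results: list[MatchResult] = []
    for gram in sorted(set(ngrams)):
        ids = registry.name_index.get(gram)
        if not ids:
            continue
        valid = {}
        for tid in ids:
            rec = registry.resolve(tid)
            valid[rec.taxon_id] = rec
        ambiguous = len(valid) > 1
        if ambiguous:
            logger.debug(
                "record %s: %r is homonymous across %d valid taxa; flagged",
                record_id, gram, len(valid),
            )
        for rec in valid.values():
            results.append(
                MatchResult(record_id, gram, rec.taxon_id, rec.rank, ambiguous)
            )
    return results


def assign_record(
    matches: Sequence[MatchResult],
    registry: TaxonomyRegistry,
    include_ambiguous: bool = False,
) -> RecordAssignment | None:
    """Fold one record's matches into a taxonomic assignment.

    Species matches supersede their embedded genus match (the genus word of a
    matched binomial is not double-counted).  The class set collects the
    classes of all matches at class rank or below.  Returns ``None`` unless
    some usable match sits at phylum level or better.  With the default
    precision-protecting policy ambiguous (homonym) hits are excluded; set
    ``include_ambiguous=True`` to assign them to all their homonym senses.
    """
    if not matches:
        return None
    usable = [m for m in matches if include_ambiguous or not m.ambiguous]
    if not usable:
        return None
    record_id = matches[0].record_id
    species_ids = {m.taxon_id for m in usable if m.rank == "species"}
    superseded_genera = {
        registry.get(sid).lineage_at("genus") for sid in species_ids
    }
    kept = [
        m for m in usable
        if not (m.rank == "genus" and registry.get(m.taxon_id).name in superseded_genera)
    ]
    if not any(_RANK_DEPTH[m.rank] >= _RANK_DEPTH["phylum"] for m in kept):
        return None
    class_names = {
        registry.get(m.taxon_id).lineage_at("class")
        for m in kept
        if _RANK_DEPTH[m.rank] >= _RANK_DEPTH["class"]
    }
    class_names.discard(None)
    return RecordAssignment(
        record_id=record_id,
        species_set=frozenset(species_ids),
        class_set=frozenset(class_names),  # type: ignore[arg-type]
        phylum_or_better=True,
    )


def assign_corpus(
    records: Iterable[BibRecord],
    registry: TaxonomyRegistry,
    include_ambiguous: bool = False,
) -> dict[str, RecordAssignment]:
    """Run extraction → matching → assignment over a corpus.

    Returns ``{record_id: RecordAssignment}`` for retained records only.
    """
    out: dict[str, RecordAssignment] = {}
    for rec in records:
        grams = extract_ngrams(rec.title, rec.author_keywords, rec.abstract)
        matches = match_record(grams, registry, rec.record_id)
        assignment = assign_record(matches, registry, include_ambiguous)
        if assignment is not None:
            out[rec.record_id] = assignment
    return out


def match_audit_table(matches: Sequence[MatchResult], registry: TaxonomyRegistry):
    """Long-form audit table of matches (one row per hit) as a DataFrame."""
    import pandas as pd

    rows = []
    for m in matches:
        rec = registry.get(m.taxon_id)
        rows.append({
            "record_id": m.record_id,
            "matched_string": m.matched_string,
            "taxon_id": m.taxon_id,
            "valid_name": rec.name,
            "rank": m.rank,
            "class": rec.lineage_at("class") or "",
            "phylum": rec.lineage_at("phylum") or "",
            "kingdom": rec.kingdom,
            "ambiguous": m.ambiguous,
        })
    return pd.DataFrame(
        rows,
        columns=["record_id", "matched_string", "taxon_id", "valid_name",
                 "rank", "class", "phylum", "kingdom", "ambiguous"],
    )
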