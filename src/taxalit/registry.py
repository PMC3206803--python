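"""A WoRMS-like taxonomy registry: loading, synonym resolution, tree distances.

The registry holds scientific names (valid names and synonyms) on a fixed
seven-rank ladder (kingdom, phylum, class, order, family, genus, species).
Species names are binomials (exactly two words); all supraspecific names are
uninomials.  Synonyms resolve in one hop to a valid record via ``accepted_id``.

Pairwise taxonomic distance between valid species is the number of rank steps
up to the lowest shared lineage rank and back down.  With seven ranks the
maximum is 12 steps (species sharing only their kingdom).  Species in
different kingdoms are joined at the kingdom level acting as the tree root,
so they also receive the 12-step maximum; this keeps the scaled taxonomic
distinctness bounded at 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from ._text import normalize_name
from .exceptions import IntegrityError, RankError, SchemaError, TaxonLookupError

logger = logging.getLogger(__name__)

#: The fixed rank ladder, top down.
RANKS: tuple[str, ...] = (
    "kingdom", "phylum", "class", "order", "family", "genus", "species",
)

_RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}

#: Kingdoms admitted by default (animals, plants incl. red/green algae,
#: brown algae).
DEFAULT_KINGDOMS: frozenset[str] = frozenset({"Animalia", "Plantae", "Chromista"})

#: Columns a registry table must provide.
REGISTRY_COLUMNS: tuple[str, ...] = (
    "taxon_id", "name", "rank", "status", "accepted_id",
) + RANKS

#: Maximum rank-step path between two species on the 7-rank ladder.
MAX_PATH_STEPS: int = 2 * (len(RANKS) - 1)


@dataclass(frozen=True)
class TaxonRecord:
    """One registry row: a valid name or a synonym with its classification."""

    taxon_id: str
    name: str
    rank: str
    status: str  # "valid" or "synonym"
    accepted_id: str
    lineage: Mapping[str, str]  # rank -> name, contiguous from kingdom

    @property
    def is_valid(self) -> bool:
        return self.status == "valid"

    @property
    def kingdom(self) -> str:
        return self.lineage["kingdom"]

    def lineage_at(self, rank: str) -> str | None:
        return self.lineage.get(rank)

    def validate(self) -> list[str]:
        """Return a list of problems with this record (empty if well formed)."""
        problems: list[str] = []
        if self.rank not in _RANK_DEPTH:
            problems.append(f"unknown rank {self.rank!r}")
            return problems
        if self.status not in ("valid", "synonym"):
            problems.append(f"unknown status {self.status!r}")
        n_words = len(self.name.split())
        if self.rank == "species":
            if n_words != 2:
                problems.append(f"species name {self.name!r} must have 2 words")
        elif n_words != 1:
            problems.append(f"{self.rank} name {self.name!r} must have 1 word")
        depth = _RANK_DEPTH[self.rank]
        for r in RANKS[: depth + 1]:
            if not self.lineage.get(r):
                problems.append(f"lineage missing {r!r} (ladder must be contiguous)")
        for r in RANKS[depth + 1:]:
            if self.lineage.get(r):
                problems.append(f"lineage has {r!r} below the record's rank")
        if self.lineage.get(self.rank) and self.lineage[self.rank] != self.name:
            problems.append("lineage entry at own rank disagrees with name")
        return problems


class TaxonomyRegistry:
    """Indexed collection of :class:`TaxonRecord` with synonym resolution."""

    def __init__(
        self,
        records: Iterable[TaxonRecord],
        kingdoms: Iterable[str] | None = DEFAULT_KINGDOMS,
    ) -> None:
        self.kingdom_filter = frozenset(kingdoms) if kingdoms is not None else None
        self._records: dict[str, TaxonRecord] = {}
        for rec in records:
            if self.kingdom_filter is not None and rec.kingdom not in self.kingdom_filter:
                continue
            if rec.taxon_id in self._records:
                raise IntegrityError(f"duplicate taxon_id {rec.taxon_id!r}")
            self._records[rec.taxon_id] = rec
        self._check_synonyms()
        self.name_index: dict[str, frozenset[str]] = {}
        index: dict[str, set[str]] = {}
        for rec in self._records.values():
            index.setdefault(normalize_name(rec.name), set()).add(rec.taxon_id)
        self.name_index = {k: frozenset(v) for k, v in index.items()}

    def _check_synonyms(self) -> None:
        offenders = []
        for rec in self._records.values():
            if rec.is_valid:
                continue
            target = self._records.get(rec.accepted_id)
            if target is None or not target.is_valid:
                offenders.append(rec.taxon_id)
        if offenders:
            raise IntegrityError(
                "synonyms with unresolvable accepted_id: " + ", ".join(sorted(offenders))
            )

    # -- basic container protocol -------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._records

    def __iter__(self) -> Iterator[TaxonRecord]:
        return iter(self._records.values())

    def get(self, taxon_id: str) -> TaxonRecord:
        try:
            return self._records[taxon_id]
        except KeyError:
            raise TaxonLookupError(f"unknown taxon_id {taxon_id!r}") from None

    # -- queries -------------------------------------------------------------

    def lookup_name(self, name: str) -> frozenset[str]:
        """taxon_ids whose (normalised) name equals ``name``; empty if none."""
        return self.name_index.get(normalize_name(name), frozenset())

    def resolve(self, taxon_id: str) -> TaxonRecord:
        """The valid record for ``taxon_id`` (identity for valid records)."""
        rec = self.get(taxon_id)
        if rec.is_valid:
            return rec
        return self.get(rec.accepted_id)

    def valid_species(self) -> list[TaxonRecord]:
        return [r for r in self if r.is_valid and r.rank == "species"]

    def species_count_by_class(self) -> dict[str, int]:
        """Number of valid species per class name (registry metadata)."""
        counts: dict[str, int] = {}
        for rec in self.valid_species():
            cls = rec.lineage_at("class")
            if cls:
                counts[cls] = counts.get(cls, 0) + 1
        return counts

    def path_length(self, id_a: str, id_b: str) -> int:
        """Rank steps between two valid species through their lowest shared rank.

        0 iff the two ids are identical; 2 for congeners; 12 for species
        sharing only their kingdom (or nothing, see module docstring).
        """
        a, b = self.get(id_a), self.get(id_b)
        for rec in (a, b):
            if rec.rank != "species" or not rec.is_valid:
                raise RankError(
                    f"path_length needs valid species, got {rec.rank}/{rec.status} "
                    f"for {rec.taxon_id!r}"
                )
        if id_a == id_b:
            return 0
        shared = 0  # kingdom level is the root: minimum shared depth is 0
        for depth, rank in enumerate(RANKS):
            if a.lineage_at(rank) != b.lineage_at(rank):
                break
            shared = depth
        else:  # identical full lineage but distinct ids: treat as congeners
            shared = len(RANKS) - 2
        return 2 * (len(RANKS) - 1 - shared)


def _row_to_record(row: Mapping[str, str]) -> TaxonRecord:
    rank = row["rank"].strip()
    depth = _RANK_DEPTH.get(rank, len(RANKS) - 1)
    lineage = {
        r: row[r].strip() for r in RANKS[: depth + 1] if str(row[r]).strip()
    }
    # keep any spurious below-rank entries so validate() can flag them
    for r in RANKS[depth + 1:]:
        if str(row[r]).strip():
            lineage[r] = row[r].strip()
    accepted = row["accepted_id"].strip()
    return TaxonRecord(
        taxon_id=row["taxon_id"].strip(),
        name=" ".join(row["name"].split()),
        rank=rank,
        status=row["status"].strip(),
        accepted_id=accepted or row["taxon_id"].strip(),
        lineage=lineage,
    )


def load_registry(
    path: str | Path,
    kingdoms: Iterable[str] | None = DEFAULT_KINGDOMS,
) -> TaxonomyRegistry:
    """Load a tab-separated registry file.

    The file must be UTF-8 with a header row carrying
    ``taxon_id, name, rank, status, accepted_id`` plus one column per rank
    (kingdom ... species; cells below a record's rank empty).  Malformed rows
    are skipped and reported with their file line numbers; a missing column
    raises :class:`SchemaError`; a synonym whose ``accepted_id`` does not
    resolve to a valid record raises :class:`IntegrityError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    records: list[TaxonRecord] = []
    bad: list[tuple[int, list[str]]] = []
    for i, row in enumerate(df.to_dict("records")):
        rec = _row_to_record(row)
        problems = rec.validate()
        if problems:
            bad.append((i + 2, problems))  # +2: header line + 1-based
        else:
            records.append(rec)
    if bad:
        for line_no, problems in bad:
            logger.warning("%s line %d skipped: %s", path.name, line_no, "; ".join(problems))
    return TaxonomyRegistry(records, kingdoms=kingdoms)


def write_registry(registry: TaxonomyRegistry, path: str | Path) -> None:
    """Write a registry back out in the tab-separated exchange format."""
    rows = []
    for rec in registry:
        row = {
            "taxon_id": rec.taxon_id,
            "name": rec.name,
            "rank": rec.rank,
            "status": rec.status,
            "accepted_id": rec.accepted_id,
        }
        for r in RANKS:
            row[r] = rec.lineage_at(r) or ""
        rows.append(row)
    pd.DataFrame(rows, columns=list(REGISTRY_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
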