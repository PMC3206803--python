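"""Taxon × ecosystem occurrence matrices and their roll-ups.

Counts are numbers of research papers: a paper contributes at most 1 to each
(taxon, ecosystem) cell regardless of how often a name is mentioned, but may
contribute to several taxa and several ecosystems.  Species-level matrices
are keyed by valid species taxon_id; class-level matrices by class name.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import AbstractSet, Mapping

import pandas as pd

from .diversity import AbundanceVector
from .matching import RecordAssignment
from .registry import TaxonomyRegistry


@dataclass
class OccurrenceMatrix:
    """Per-ecosystem paper counts by taxon at one taxonomic level."""

    level: str                                   # "species" or "class"
    counts: dict[tuple[str, str], int]           # (taxon_key, ecosystem) -> papers
    paper_totals: dict[str, int] = field(default_factory=dict)
    ecosystems: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.ecosystems:
            self.ecosystems = tuple(sorted({e for _, e in self.counts}))
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("occurrence counts must be non-negative")

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted({t for t, _ in self.counts}))

    def count(self, taxon: str, ecosystem: str) -> int:
        return self.counts.get((taxon, ecosystem), 0)

    def taxa_in(self, ecosystem: str) -> set[str]:
        return {t for (t, e), n in self.counts.items() if e == ecosystem and n > 0}

    def class_totals(self) -> dict[str, int]:
        """Cross-ecosystem total per taxon: sum of the per-ecosystem counts."""
        totals: Counter[str] = Counter()
        for (t, _e), n in self.counts.items():
            totals[t] += n
        return dict(totals)

    def abundance_vector(self, ecosystem: str) -> AbundanceVector:
        """Paper counts per taxon in one ecosystem (papers-as-individuals)."""
        items = sorted(
            (t, n) for (t, e), n in self.counts.items() if e == ecosystem and n > 0
        )
        return AbundanceVector(
            taxon_ids=tuple(t for t, _ in items),
            abundances=tuple(float(n) for _, n in items),
        )

    def to_wide_df(self) -> pd.DataFrame:
        df = pd.DataFrame(0, index=list(self.taxa), columns=list(self.ecosystems))
        for (t, e), n in self.counts.items():
            if e in df.columns:
                df.loc[t, e] = n
        df.index.name = self.level
        return df

    def to_long_df(self, registry: TaxonomyRegistry | None = None) -> pd.DataFrame:
        rows = []
        for (t, e) in sorted(self.counts):
            n = self.counts[(t, e)]
            row = {"taxon": t, "ecosystem": e, "n_papers": n}
            if registry is not None and self.level == "species" and t in registry:
                rec = registry.get(t)
                row.update({
                    "name": rec.name,
                    "rank": rec.rank,
                    "class": rec.lineage_at("class") or "",
                    "phylum": rec.lineage_at("phylum") or "",
                })
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_wide_df(cls, df: pd.DataFrame, level: str) -> "OccurrenceMatrix":
        """Build a matrix from a taxa × ecosystems table of paper counts."""
        counts = {
            (str(t), str(e)): int(df.loc[t, e])
            for t in df.index for e in df.columns
            if int(df.loc[t, e]) != 0
        }
        return cls(level=level, counts=counts, ecosystems=tuple(str(c) for c in df.columns))


def build_matrix(
    assignments: Mapping[str, RecordAssignment],
    ecosystem_map: Mapping[str, AbstractSet[str]],
    level: str,
) -> OccurrenceMatrix:
    """Cross-tabulate retained record assignments against ecosystem membership.

    ``counts[(t, e)]`` is the number of distinct records assigned to taxon
    ``t`` and ecosystem ``e``; ``paper_totals[e]`` counts distinct records in
    ``e`` with any retained assignment.
    """
    if level not in ("species", "class"):
        raise ValueError(f"level must be 'species' or 'class', got {level!r}")
    counts: Counter[tuple[str, str]] = Counter()
    paper_totals: dict[str, int] = {}
    for eco, rec_ids in ecosystem_map.items():
        assigned = [assignments[r] for r in rec_ids if r in assignments]
        paper_totals[eco] = len(assigned)
        for a in assigned:
            taxa = a.species_set if level == "species" else a.class_set
            for t in taxa:
                counts[(t, eco)] += 1
    return OccurrenceMatrix(
        level=level,
        counts=dict(counts),
        paper_totals=paper_totals,
        ecosystems=tuple(sorted(ecosystem_map)),
    )


def summarize(
    species_matrix: OccurrenceMatrix | None = None,
    class_matrix: OccurrenceMatrix | None = None,
) -> pd.DataFrame:
    """Per-ecosystem paper, class and species counts.

    Columns (as available): ``papers`` (distinct assigned papers),
    ``n_classes`` (classes with at least one paper), ``n_species``.
    """
    if species_matrix is None and class_matrix is None:
        raise ValueError("need at least one matrix")
    some = class_matrix or species_matrix
    ecosystems = some.ecosystems  # type: ignore[union-attr]
    rows = {}
    for eco in ecosystems:
        row: dict[str, int] = {}
        for m in (species_matrix, class_matrix):
            if m is not None and m.paper_totals:
                row["papers"] = m.paper_totals.get(eco, 0)
        if class_matrix is not None:
            row["n_classes"] = len(class_matrix.taxa_in(eco))
        if species_matrix is not None:
            row["n_species"] = len(species_matrix.taxa_in(eco))
        rows[eco] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "ecosystem"
    return df
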