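from pathlib import Path

import pytest

from taxalit.registry import RANKS, TaxonomyRegistry, TaxonRecord, load_registry

DATA_DIR = Path(__file__).parent / "data"


def build_registry(lineages, synonyms=(), kingdoms=None):
    """Construct a registry from compact pipe-separated lineage strings.

    Each string lists names from kingdom down to any rank, e.g.
    ``"Animalia|Chordata|Actinopterygii|Perciformes|Pomacentridae|Amphiprion|Amphiprion percula"``.
    Ancestor records are created once.  ``synonyms`` is an iterable of
    ``(synonym_binomial, accepted_species_name)``.  Taxon ids are ``t1``,
    ``t2``, ... in creation order, deterministic for a given input order.
    """
    records = []
    seen: dict[tuple, str] = {}
    counter = 0

    def add(rank_idx, names):
        nonlocal counter
        key = tuple(names[: rank_idx + 1])
        if key in seen:
            return seen[key]
        counter += 1
        tid = f"t{counter}"
        records.append(TaxonRecord(
            taxon_id=tid, name=names[rank_idx], rank=RANKS[rank_idx],
            status="valid", accepted_id=tid,
            lineage={RANKS[i]: names[i] for i in range(rank_idx + 1)},
        ))
        seen[key] = tid
        return tid

    name_to_id = {}
    for line in lineages:
        names = [s.strip() for s in line.split("|")]
        for i in range(len(names)):
            tid = add(i, names)
        name_to_id[names[-1]] = tid
    for syn_name, accepted_name in synonyms:
        counter += 1
        accepted = next(r for r in records if r.name == accepted_name)
        lineage = dict(accepted.lineage)
        lineage[accepted.rank] = syn_name
        records.append(TaxonRecord(
            taxon_id=f"t{counter}", name=syn_name, rank=accepted.rank,
            status="synonym", accepted_id=accepted.taxon_id, lineage=lineage,
        ))
    return TaxonomyRegistry(records, kingdoms=kingdoms)


def species_id(registry, name):
    """The valid taxon_id behind a (possibly synonymous) species name."""
    (tid,) = registry.lookup_name(name)
    return registry.resolve(tid).taxon_id


@pytest.fixture(scope="session")
def small_registry():
    return load_registry(DATA_DIR / "registry_small.tsv")


@pytest.fixture(scope="session")
def small_corpus_path():
    return DATA_DIR / "corpus_small.ris"
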