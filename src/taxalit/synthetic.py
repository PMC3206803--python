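"""Ground-truthed synthetic registries and bibliographic corpora.

Every pipeline stage is testable without the (undeposited) literature corpus
and registry snapshot: this module generates a balanced random taxonomy on
the seven-rank ladder with pseudo-Latin names, and a tagged bibliographic
corpus with ecosystem phrases and taxon mentions planted at configurable
rates.  A plant log records the exact ground truth (which record got which
phrase and which taxon, under which surface form), so pipeline output can be
checked for exact agreement.

Name collisions cannot happen by accident: generated name tokens are drawn
from a syllable grammar, checked against a reserved filler lexicon (the
words that make up titles/abstracts/keywords) and a global used-token set.
The only duplicated names are deliberately planted cross-kingdom homonyms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import DEFAULT_QUERIES, DEFAULT_YEAR_RANGE, BibRecord, write_ris
from .exceptions import ConfigurationError
from .registry import RANKS, TaxonomyRegistry, TaxonRecord, write_registry

_REAL_KINGDOMS = ("Animalia", "Plantae", "Chromista")

#: Reserved filler vocabulary for generated prose.  Deliberately excludes
#: every word of every ecosystem search phrase.
FILLER_WORDS: tuple[str, ...] = (
    "abundance", "analysis", "assemblage", "baseline", "benthic", "biomass",
    "change", "community", "comparison", "condition", "data", "decline",
    "density", "design", "disturbance", "dynamics", "ecology", "effect",
    "estimate", "evidence", "experiment", "field", "function", "gradient",
    "growth", "habitat", "impact", "increase", "interaction", "larval",
    "local", "long", "term", "management", "marine", "method", "model",
    "monitoring", "nutrient", "observation", "pattern", "population",
    "predation", "process", "productivity", "recovery", "recruitment",
    "region", "response", "result", "richness", "sampling", "scale",
    "season", "sediment", "settlement", "shallow", "site", "spatial",
    "structure", "study", "survey", "temperature", "temporal", "transect",
    "trend", "variation", "water", "zone",
)

_ONSETS = (
    "b", "c", "d", "f", "g", "l", "m", "n", "p", "r", "s", "t", "v", "z",
    "th", "ch", "pl", "cr", "tr", "br", "cl", "st",
)
_VOWELS = ("a", "e", "i", "o", "u")
_GENUS_SUFFIX = ("us", "a", "um", "is", "ops", "ella", "ina", "odon")
_EPITHET_SUFFIX = ("ensis", "atus", "icola", "oides", "ianus", "ica", "ifer")


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults emulate the shape of the real analysis at desk scale: a
    three-kingdom registry with a heavy-tailed distribution of species over
    classes, a corpus whose ecosystem phrase rates mirror the relative sizes
    of the four literatures (coral reef >> seagrass > mangrove > kelp), and
    log-normal per-class mention rates.
    """

    n_kingdoms: int = 3
    n_phyla: int = 6
    n_classes: int = 20
    n_species: int = 200
    synonym_rate: float = 0.15
    homonym_count: int = 0
    n_records: int = 1000
    ecosystem_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "coral_reef": 0.55,
            "kelp_forest": 0.05,
            "mangrove_forest": 0.12,
            "seagrass_bed": 0.18,
        }
    )
    mention_rates: Mapping[str, float] | None = None  # per class; drawn if None
    mention_rate_median: float = 0.02
    mention_rate_sigma: float = 1.2
    synonym_mention_rate: float = 0.5
    homonym_mention_rate: float = 0.05
    class_weight_sigma: float = 1.0
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.n_kingdoms <= len(_REAL_KINGDOMS):
            raise ConfigurationError("n_kingdoms must be between 1 and 3")
        if not self.n_kingdoms <= self.n_phyla <= self.n_classes <= self.n_species:
            raise ConfigurationError(
                "tree shape must satisfy kingdoms <= phyla <= classes <= species"
            )
        rates = [self.synonym_rate, self.synonym_mention_rate,
                 self.homonym_mention_rate, *self.ecosystem_rates.values()]
        if self.mention_rates:
            rates += list(self.mention_rates.values())
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ConfigurationError("all rates must lie in [0, 1]")
        if self.homonym_count < 0:
            raise ConfigurationError("homonym_count must be >= 0")
        if self.homonym_count and self.n_kingdoms < 2:
            raise ConfigurationError("homonyms need at least 2 kingdoms")
        if self.year_range[0] > self.year_range[1]:
            raise ConfigurationError("year_range must be (lo, hi) with lo <= hi")


class _NameGenerator:
    """Syllable-grammar name factory with global collision avoidance."""

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng
        self.used: set[str] = set(FILLER_WORDS)

    def _stem(self, n_syllables: int) -> str:
        return "".join(
            self.rng.choice(_ONSETS) + self.rng.choice(_VOWELS)
            for _ in range(n_syllables)
        )

    def word(self, suffixes: Sequence[str]) -> str:
        for _ in range(1000):
            w = self._stem(int(self.rng.integers(2, 4))) + str(self.rng.choice(suffixes))
            if w not in self.used:
                self.used.add(w)
                return w
        raise RuntimeError("name space exhausted")  # pragma: no cover

    def uninomial(self) -> str:
        return self.word(_GENUS_SUFFIX).capitalize()

    def epithet(self) -> str:
        return self.word(_EPITHET_SUFFIX)


@dataclass
class RegistryBundle:
    """A synthetic registry plus its generation ground truth."""

    registry: TaxonomyRegistry
    species_by_class: dict[str, list[str]]      # class name -> valid species ids
    synonym_of: dict[str, str]                  # synonym id -> accepted species id
    synonym_name: dict[str, str]                # accepted species id -> synonym name
    homonym_names: tuple[str, ...]              # planted duplicate genus names
    homonym_ids: dict[str, tuple[str, ...]]     # homonym name -> valid genus ids


def _allocate(total: int, n_bins: int, weights: np.ndarray) -> list[int]:
    """Split ``total`` items into ``n_bins`` with >= 1 each, ~proportional."""
    base = [1] * n_bins
    remaining = total - n_bins
    if remaining > 0:
        shares = weights / weights.sum() * remaining
        alloc = np.floor(shares).astype(int)
        leftover = remaining - int(alloc.sum())
        order = np.argsort(-(shares - alloc), kind="stable")
        for i in range(leftover):
            alloc[order[i]] += 1
        base = [b + int(a) for b, a in zip(base, alloc)]
    return base


def make_registry(config: SyntheticConfig) -> RegistryBundle:
    """Generate a balanced random 7-rank taxonomy per the config.

    Deterministic per ``config.seed``.  Species are spread over classes with
    log-normal weights (a heavy right tail: a few speciose classes, many
    small ones).  Synonym records are emitted per ``synonym_rate``;
    ``homonym_count`` cross-kingdom duplicate genus names are planted.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = _NameGenerator(rng)

    kingdoms = list(_REAL_KINGDOMS[: config.n_kingdoms])
    phyla = [(names.uninomial(), kingdoms[i % len(kingdoms)])
             for i in range(config.n_phyla)]
    classes = [(names.uninomial(), phyla[i % len(phyla)])
               for i in range(config.n_classes)]

    weights = rng.lognormal(0.0, config.class_weight_sigma, size=config.n_classes)
    species_alloc = _allocate(config.n_species, config.n_classes, weights)

    # genus/family/order chains per class
    tree: list[dict] = []  # one entry per species: full lineage names
    genera_by_kingdom: dict[str, list[dict]] = {k: [] for k in kingdoms}
    for (cls_name, (phy_name, kingdom)), n_sp in zip(classes, species_alloc):
        n_gen = max(1, round(n_sp / 3))
        n_fam = max(1, n_gen // 2)
        n_ord = max(1, n_fam // 2)
        orders = [names.uninomial() for _ in range(n_ord)]
        families = [(names.uninomial(), orders[i % n_ord]) for i in range(n_fam)]
        genera = []
        for i in range(n_gen):
            fam, order = families[i % n_fam]
            g = {"genus": names.uninomial(), "family": fam, "order": order,
                 "class": cls_name, "phylum": phy_name, "kingdom": kingdom,
                 "species": []}
            genera.append(g)
            genera_by_kingdom[kingdom].append(g)
        for i in range(n_sp):
            genera[i % n_gen]["species"].append(names.epithet())
        tree.extend(genera)

    # plant homonyms: duplicate a genus name into a different kingdom
    homonym_names: list[str] = []
    if config.homonym_count:
        eligible = [k for k in kingdoms if genera_by_kingdom[k]]
        for i in range(config.homonym_count):
            k_a, k_b = eligible[i % len(eligible)], eligible[(i + 1) % len(eligible)]
            g_a = genera_by_kingdom[k_a][int(rng.integers(len(genera_by_kingdom[k_a])))]
            candidates = [g for g in genera_by_kingdom[k_b]
                          if g["genus"] not in homonym_names
                          and g["genus"] != g_a["genus"]]
            if not candidates or g_a["genus"] in homonym_names:
                continue
            g_b = candidates[int(rng.integers(len(candidates)))]
            g_b["genus"] = g_a["genus"]
            homonym_names.append(g_a["genus"])

    # emit records
    records: list[TaxonRecord] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"t{counter:06d}"

    def emit(rank: str, lineage: dict[str, str]) -> str:
        tid = new_id()
        records.append(TaxonRecord(
            taxon_id=tid, name=lineage[rank], rank=rank, status="valid",
            accepted_id=tid, lineage=dict(lineage),
        ))
        return tid

    emitted: dict[tuple[str, ...], str] = {}

    def emit_once(rank: str, lineage: dict[str, str]) -> str:
        depth = RANKS.index(rank)
        key = tuple(lineage[r] for r in RANKS[: depth + 1])
        if key not in emitted:
            emitted[key] = emit(rank, {r: lineage[r] for r in RANKS[: depth + 1]})
        return emitted[key]

    species_by_class: dict[str, list[str]] = {}
    synonym_of: dict[str, str] = {}
    synonym_name: dict[str, str] = {}
    homonym_ids: dict[str, list[str]] = {h: [] for h in homonym_names}
    for g in tree:
        lin = {"kingdom": g["kingdom"], "phylum": g["phylum"], "class": g["class"],
               "order": g["order"], "family": g["family"], "genus": g["genus"]}
        for rank in ("kingdom", "phylum", "class", "order", "family"):
            emit_once(rank, lin)
        genus_id = emit_once("genus", lin)
        if g["genus"] in homonym_ids and genus_id not in homonym_ids[g["genus"]]:
            homonym_ids[g["genus"]].append(genus_id)
        for epithet in g["species"]:
            binomial = f"{g['genus']} {epithet}"
            sp_lin = dict(lin, species=binomial)
            sp_id = emit("species", sp_lin)
            species_by_class.setdefault(g["class"], []).append(sp_id)
            if rng.random() < config.synonym_rate:
                syn_binomial = f"{names.uninomial()} {names.epithet()}"
                syn_id = new_id()
                records.append(TaxonRecord(
                    taxon_id=syn_id, name=syn_binomial, rank="species",
                    status="synonym", accepted_id=sp_id,
                    lineage=dict(lin, species=syn_binomial),
                ))
                synonym_of[syn_id] = sp_id
                synonym_name[sp_id] = syn_binomial

    registry = TaxonomyRegistry(records, kingdoms=kingdoms)
    return RegistryBundle(
        registry=registry,
        species_by_class=species_by_class,
        synonym_of=synonym_of,
        synonym_name=synonym_name,
        homonym_names=tuple(homonym_names),
        homonym_ids={h: tuple(v) for h, v in homonym_ids.items()},
    )


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def draw_mention_rates(
    config: SyntheticConfig, bundle: RegistryBundle
) -> dict[str, float]:
    """Per-class mention probabilities: configured, or log-normal draws.

    The log-normal default gives the heavy right tail seen in real
    class-level paper counts (a few intensively studied classes).
    Deterministic per ``config.seed``.
    """
    if config.mention_rates is not None:
        return dict(config.mention_rates)
    rng = np.random.default_rng(config.seed + 1)
    rates = {}
    for cls in sorted(bundle.species_by_class):
        r = rng.lognormal(np.log(config.mention_rate_median), config.mention_rate_sigma)
        rates[cls] = float(min(r, 0.5))
    return rates


def make_corpus(
    config: SyntheticConfig, bundle: RegistryBundle
) -> tuple[list[BibRecord], pd.DataFrame]:
    """Generate a corpus and its plant log.

    Each record gets template prose from the reserved filler lexicon, plus:
    ecosystem phrases (independent Bernoulli per ecosystem at
    ``ecosystem_rates``, random singular/plural variant, random field),
    species mentions (per class at the mention rate; surface form is the
    synonym with probability ``synonym_mention_rate`` when one exists), and —
    when homonyms were planted — ambiguous genus-name mentions at
    ``homonym_mention_rate``.

    The plant log has one row per planted item: ``record_id, kind, ecosystem,
    taxon_id, class_name, surface, ambiguous``.  Ambiguous homonym plants get
    one row per homonym sense.  Every surface form appears verbatim in the
    record's text.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    mention_rates = draw_mention_rates(config, bundle)
    registry = bundle.registry
    classes = sorted(bundle.species_by_class)
    lo, hi = config.year_range

    records: list[BibRecord] = []
    log_rows: list[dict] = []
    for i in range(1, config.n_records + 1):
        rid = f"rec{i:06d}"
        year = int(rng.integers(lo, hi + 1))
        title_extra: list[str] = []
        keyword_extra: list[str] = []
        sentences: list[str] = [_filler_sentence(rng)]

        def place(surface: str) -> None:
            field = rng.choice(["abstract", "title", "keywords"], p=[0.75, 0.15, 0.10])
            if field == "title":
                title_extra.append(surface)
            elif field == "keywords":
                keyword_extra.append(surface)
            else:
                sentences.append(_plant_sentence(rng, surface))

        for eco in sorted(config.ecosystem_rates):
            if rng.random() < config.ecosystem_rates[eco]:
                phrase = str(rng.choice(DEFAULT_QUERIES[eco]))
                place(phrase)
                log_rows.append(dict(record_id=rid, kind="ecosystem", ecosystem=eco,
                                     taxon_id="", class_name="", surface=phrase,
                                     ambiguous=False))

        for cls in classes:
            if rng.random() < mention_rates.get(cls, 0.0):
                sp_id = str(rng.choice(bundle.species_by_class[cls]))
                if (sp_id in bundle.synonym_name
                        and rng.random() < config.synonym_mention_rate):
                    surface = bundle.synonym_name[sp_id]
                else:
                    surface = registry.get(sp_id).name
                place(surface)
                log_rows.append(dict(record_id=rid, kind="mention", ecosystem="",
                                     taxon_id=sp_id, class_name=cls,
                                     surface=surface, ambiguous=False))

        if bundle.homonym_names and rng.random() < config.homonym_mention_rate:
            name = str(rng.choice(sorted(bundle.homonym_names)))
            place(name)
            for gid in bundle.homonym_ids[name]:
                g = registry.get(gid)
                log_rows.append(dict(record_id=rid, kind="mention", ecosystem="",
                                     taxon_id=gid,
                                     class_name=g.lineage_at("class") or "",
                                     surface=name, ambiguous=True))

        sentences.append(_filler_sentence(rng))
        title = " ".join(
            [w.capitalize() for w in _filler_words(rng, 4)] + title_extra
        )
        keywords = tuple(_filler_words(rng, 3)) + tuple(keyword_extra)
        records.append(BibRecord(rid, title, " ".join(sentences), keywords, year))

    plant_log = pd.DataFrame(
        log_rows,
        columns=["record_id", "kind", "ecosystem", "taxon_id", "class_name",
                 "surface", "ambiguous"],
    )
    return records, plant_log


def _filler_words(rng: np.random.Generator, n: int) -> list[str]:
    return [str(w) for w in rng.choice(FILLER_WORDS, size=n)]


def _sentence_case(s: str) -> str:
    # only upper-case the first character: planted names must stay verbatim
    return s[0].upper() + s[1:] if s else s


def _filler_sentence(rng: np.random.Generator) -> str:
    words = _filler_words(rng, int(rng.integers(5, 9)))
    return _sentence_case(" ".join(words)) + "."


def _plant_sentence(rng: np.random.Generator, surface: str) -> str:
    pre = _filler_words(rng, int(rng.integers(2, 4)))
    post = _filler_words(rng, int(rng.integers(2, 4)))
    return _sentence_case(" ".join(pre) + f" {surface} " + " ".join(post)) + "."


# ---------------------------------------------------------------------------
# Ground-truth cross-tabulation
# ---------------------------------------------------------------------------

def plant_log_crosstab(
    plant_log: pd.DataFrame, include_ambiguous: bool = False
) -> dict[tuple[str, str], int]:
    """Expected class × ecosystem paper counts implied by a plant log.

    For each record, the planted classes (optionally including ambiguous
    homonym senses) are crossed with the planted ecosystems; each record
    contributes at most 1 per (class, ecosystem) cell.
    """
    pairs: set[tuple[str, str, str]] = set()  # (record, class, eco)
    eco_by_rec: dict[str, set[str]] = {}
    cls_by_rec: dict[str, set[str]] = {}
    for row in plant_log.itertuples(index=False):
        if row.kind == "ecosystem":
            eco_by_rec.setdefault(row.record_id, set()).add(row.ecosystem)
        elif row.kind == "mention" and (include_ambiguous or not row.ambiguous):
            if row.class_name:
                cls_by_rec.setdefault(row.record_id, set()).add(row.class_name)
    for rid, classes in cls_by_rec.items():
        for eco in eco_by_rec.get(rid, ()):
            for cls in classes:
                pairs.add((rid, cls, eco))
    counts: dict[tuple[str, str], int] = {}
    for _rid, cls, eco in pairs:
        counts[(cls, eco)] = counts.get((cls, eco), 0) + 1
    return counts


def write_fixture_set(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Generate and write registry.tsv, corpus.ris and plantlog.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = make_registry(config)
    records, plant_log = make_corpus(config, bundle)
    reg_path, ris_path, log_path = (
        out / "registry.tsv", out / "corpus.ris", out / "plantlog.csv",
    )
    write_registry(bundle.registry, reg_path)
    write_ris(records, ris_path)
    plant_log.to_csv(log_path, index=False)
    return reg_path, ris_path, log_path
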