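# taxalit

**Quantifying taxonomic bias in ecological literature by text mining.**

Ecological knowledge is unevenly distributed across taxa: a handful of
classes (fishes, the habitat-forming corals, kelps, mangroves and
seagrasses) dominate the literature of whole ecosystems while most classes
are barely studied. `taxalit` implements the full analysis pipeline for
measuring that bias from a bibliographic export and a taxonomy registry:

1. **Corpus filter** — parse a tagged RIS export and keep records whose
   title, author keywords or abstract contain an exact ecosystem phrase
   ("coral reef/s", "kelp forest/s", "mangrove forest/s", "seagrass
   bed/s|meadow/s"); single words never qualify.
2. **Taxonomic assignment** — extract every unique one- and two-word
   sequence from the three searchable fields, match it against a WoRMS-style
   registry (valid names and synonyms on the seven-rank ladder
   kingdom→species), resolve synonyms to valid names, flag homonyms, and
   retain records assignable at phylum level or better.
3. **Occurrence matrices** — cross-tabulate papers by taxon and ecosystem at
   species and class level (presence/absence per paper: a paper counts once
   per taxon per ecosystem).
4. **Diversity battery** — per ecosystem: Shannon evenness
   `J = −Σ Pᵢ ln Pᵢ / ln S`; classic Chao1 richness
   `S_chao1 = S_obs + f₁²/(2 f₂)` with its standard error; average
   taxonomic distinctness `Δ⁺` (mean pairwise rank-path length between
   species, scaled so the maximum path = 100) with a randomisation funnel
   (simulated mean ± 2 sd over random subsets of the master species pool);
   and exact individual-based rarefaction
   `E[S_n] = Σᵢ (1 − C(N−Nᵢ, n)/C(N, n))` with analytic 95% clouds.
5. **Effort models** — per-class binomial occurrence probabilities with
   logit-scale Wald intervals, and a log₁₀–log₁₀ regression of paper counts
   on globally named species richness (fixed-df spline smooth + phylum
   random intercept). Residuals from the smooth rank classes as over- or
   under-studied relative to their known richness.

Because real literature corpora and registry snapshots are large and
proprietary, the package includes a first-class **synthetic data generator**
(`taxalit.synthetic`) that emits ground-truthed registries and corpora with
planted ecosystem phrases, species mentions (via valid names or synonyms)
and optional cross-kingdom homonyms, plus a plant log against which pipeline
output can be checked *exactly*.

## Worked example

```python
from taxalit import (SyntheticConfig, make_registry, make_corpus,
                     filter_corpus, assign_corpus, build_matrix,
                     diversity_summary)
from taxalit.synthetic import plant_log_crosstab

cfg = SyntheticConfig(seed=1)          # 3 kingdoms, 20 classes, 200 species,
bundle = make_registry(cfg)            # 1,000 records
records, plant_log = make_corpus(cfg, bundle)

eco_map = filter_corpus(records)
assignments = assign_corpus(records, bundle.registry)
classes = build_matrix(assignments, eco_map, "class")
species = build_matrix(assignments, eco_map, "species")

print({e: len(ids) for e, ids in eco_map.items()})
print(dict(classes.counts) == plant_log_crosstab(plant_log))
print(diversity_summary(species, classes, bundle.registry).round(2))
```

prints

```
{'coral_reef': 584, 'kelp_forest': 48, 'mangrove_forest': 121, 'seagrass_bed': 213}
True
                 papers  n_classes  n_species  class_evenness  species_evenness   chao1  chao1_se  delta_plus
ecosystem
coral_reef          286         19        112            0.85              0.93  145.33     13.81       94.04
kelp_forest          26         12         29            0.86              0.97   77.40     30.71       91.17
mangrove_forest      65         17         54            0.87              0.97   75.03     10.20       93.48
seagrass_bed        103         18         71            0.85              0.95  124.33     22.97       94.02
```

The Chao1 estimates sit above the observed species counts (as lower-bound
richness estimators must), and Δ⁺ is high in every ecosystem because
planted mentions are spread evenly across the synthetic tree — real
literatures, concentrated on a few classes, score markedly lower.

The phrase filter recovers exactly the planted ecosystem sets; the class ×
ecosystem matrix equals the generator's plant-log cross-tabulation cell for
cell (`True` above); and the diversity table mirrors the familiar
per-ecosystem summary layout (papers, classes, species, evenness at two
levels, Chao1 ± SE, Δ⁺).

The package also ships the published class × ecosystem paper-count table
for the four marine ecosystems (`taxalit.datasets.class_paper_counts()`,
36 classes) as a fixed input for roll-up checks — e.g. the Actinopterygii
row sums to its printed cross-ecosystem total of 1,559 papers.

A thin CLI wraps the library: `taxalit synth`, `taxalit filter`,
`taxalit pipeline` (see `taxalit --help`).

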