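# Methods

This note records the statistical conventions, defaults and open design
choices behind `taxalit`, in the order the pipeline runs.

## Text normalisation and phrase matching

All name and phrase comparisons share one normalisation: lowercase,
punctuation stripped at token edges, hyphens/slashes splitting tokens,
whitespace collapsed. Ecosystem queries are exact multi-word phrases
(singular and plural variants listed explicitly); a phrase must occur as a
contiguous token run within one sentence of the title, one author keyword,
or the abstract. Sentence boundaries are `.`, `!`, `?`. Consequences:
"coral-reef fish" matches the phrase "coral reef"; "…the coral. Reefs…"
does not. Whether the original analysis was case-sensitive or tolerated
intervening punctuation is not documented anywhere we know of; the
conventions above are the package's own and are applied identically to
registry names and extracted n-grams, which is what the exactness
guarantees below rely on.

Database-generated keyword fields (KeyWords-Plus style) are ignored when
reading RIS exports; only author keywords are searchable, so a record whose
only phrase occurrence is a database keyword is dropped by the filter —
mirroring the secondary filter step that reduces a raw keyword search to
the analysis corpus.

## Registry and taxonomic distances

The registry is a fixed seven-rank ladder (kingdom, phylum, class, order,
family, genus, species). Rows with gaps in the ladder are rejected rather
than imputed, because Δ⁺ needs a consistent tree depth. Synonyms resolve in
one hop; homonyms (one normalised name, several valid taxa) stay in the
index and are resolved by policy at matching time (default: excluded from
assignment, to protect precision; `include_ambiguous=True` assigns all
senses).

Pairwise distance between valid species is the number of rank steps up to
the lowest shared rank and back down: 2 for congeners, 12 for species
sharing only their kingdom. Species in *different* kingdoms are joined at
the kingdom level acting as the root and also receive 12. This keeps the
scaled Δ⁺ (steps × 100/12) bounded by 100, at the cost of not
distinguishing "same kingdom only" from "different kingdoms" — an
acceptable flattening given that cross-kingdom pairs are already at the
maximum distance the ladder can express.

## Assignment semantics

A record's matches are folded presence/absence: mention frequency is
irrelevant, a paper contributes at most 1 to each (taxon, ecosystem) cell,
but may contribute to several taxa and several ecosystems (so class totals
across ecosystems may exceed any single ecosystem's paper count). A
two-word species match supersedes its embedded genus unigram (counted once,
at species rank). Records are retained only if some unambiguous match sits
at phylum rank or below; matches above class rank count toward retention
but appear in class-level tables only via their class-or-better lineage.

## Diversity statistics

* **Shannon evenness** `H/ln S` with natural logs, zero-abundance taxa
  excluded; undefined for S < 2.
* **Chao1**: the classic estimator `S_obs + f₁²/(2 f₂)`, with the
  bias-corrected fallback `S_obs + f₁(f₁−1)/2` when no doubletons exist,
  and the matching classic variance forms for the SE. Note that recent
  versions of common ecology software report the *bias-corrected* variant
  by default (`S_obs + f₁(f₁−1)/(2(f₂+1))`), which differs for small
  samples; the classic form is used here and named in output metadata.
  The published per-ecosystem "±" values are treated as standard errors.
* **Δ⁺**: mean scaled pairwise distance over all unordered pairs of
  distinct species, presence/absence only (duplicating the species list
  changes nothing).
* **Funnel**: for each subset size m, draw `n_sim` subsets without
  replacement from a master pool and report mean ± 2 sd of Δ⁺. The master
  pool is, by default, the union of species observed across all ecosystems
  and periods being compared (configurable — whether the original figures
  used a global or per-ecosystem pool is unstated). A subset size equal to
  the pool yields sd exactly 0 (there is only one subset); a pool in which
  all pairwise distances are equal yields sd exactly 0 at every size.
  Under heterogeneous pools the ±2 sd envelope empirically covers ≈95–96%
  of random subsets, matching the normal-approximation reading of the
  funnel as a significance band.
* **Rarefaction**: exact hypergeometric expectation with the conditional
  (finite-pool) variance, which vanishes at n = N; 95% cloud =
  E ± 1.96 sd, truncated below at 1. This matches the SE reported by the
  standard community-ecology implementation to all printed digits. An
  analytic cloud was chosen over resampling for determinism.
* **Time periods**: publication years bin into pre-2000, 2000–2006 and
  2007–2009 (the boundary year 2006 belongs to the middle bin; the period
  description in running text is self-contradictory and the figure-caption
  reading was adopted). Boundaries are configurable.

## Effort models

Occurrence probability per class and ecosystem is the intercept-only
binomial MLE (hits/total) with a 95% Wald interval on the log-odds scale;
degenerate counts (0 or all) keep the raw point estimate, get a one-sided
interval via a 0.5 continuity adjustment, and are flagged.

The effort-vs-richness model regresses log₁₀(papers) on a B-spline smooth
(default 3 df — a global cubic; interior knots at quantiles for larger df)
of log₁₀(globally named species), with a phylum random intercept estimated
by iterative shrinkage: fit the smooth by OLS on the intercept-adjusted
response, take phylum means of the residuals, shrink them toward zero by
the variance-ratio factor σ²_b/(σ²_b + σ²_e/n_p) (method-of-moments
variance estimates), and repeat to a 1e-8 fixed point. This is a
deterministic, dependency-free stand-in for a penalized-spline mixed model:
it reproduces a noiseless linear single-phylum dataset exactly (R² = 1,
residuals 0) and recovers planted phylum intercepts and class deviations on
synthetic data (residual–truth correlation ≳ 0.97 at 60 classes / 6
phyla, noise sd 0.1, intercept sd 0.3). Full REML machinery and uncertainty
bands on the smooth are deliberately out of scope. The published R² range
for the real corpus (0.28–0.52) is corpus-dependent and is not a
reproduction target; the synthetic recovery experiment is the test surface.

Two residuals are reported: `residual` (response minus smooth minus phylum
intercept) and `effort_residual` (response minus smooth alone). Rankings
use `effort_residual`: a class in a heavily studied phylum is itself
heavily studied, which is what "research effort corrected for species
richness" should mean for a class-level ranking. Classes with zero papers
cannot enter the log-scale regression; they are excluded from the fit,
reported as "unstudied", and head the bottom of the ranking. Ties break
lexicographically by class name, so rankings are reproducible.

## Synthetic data: what it does and does not emulate

The generator's defaults are the study conditions used throughout the
tests: a 3-kingdom, 6-phylum, 20-class, 200-species registry; 15% of
species carrying one synonym; a 1,000-record corpus; per-ecosystem phrase
rates (0.55/0.05/0.12/0.18) mirroring the relative sizes of the four real
literatures; per-class mention rates drawn log-normal (median 0.02,
σ = 1.2, capped at 0.5) to produce the heavy right tail real class-level
paper counts show; publication years uniform on 1957–2009. Names come from
a syllable grammar with a reserved filler lexicon, so surface collisions
between taxon names, prose and ecosystem phrases are impossible except for
deliberately planted cross-kingdom homonyms. The plant log records every
planted phrase and mention with its surface form, which licenses *exact*
equality checks: with clean planting, pipeline counts equal the plant-log
cross-tabulation cell for cell; with planted homonyms under the default
exclusion policy, the shortfall equals exactly the records whose only route
to a cell was an ambiguous mention.

What passing these tests does *not* show: robustness to real prose
(abbreviated binomials like "A. millepora", vernacular names, genus names
that are English words, OCR noise), to registry gaps or misspellings, or to
real keyword conventions — all of which the matcher does not attempt to
handle, matching the scope of the original text-mining design. Uniform
years also mean the synthetic period bins are roughly equal by construction
rather than by publication growth.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen to exercise every code
path while completing in seconds: 1,000-record corpora, 200-species
registries, 5,000-draw funnels checked with 10,000 fresh subsets, 10⁵-draw
Monte-Carlo rarefaction checks, 60-class effort recovery. Every stochastic
step takes an explicit seed (`numpy.random.default_rng`); identical seeds
reproduce registries, corpora, funnels and fits bit for bit.
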