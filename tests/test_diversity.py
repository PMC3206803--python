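import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxalit.diversity import (
    AbundanceVector,
    chao_richness,
    delta_plus,
    distinctness_funnel,
    pairwise_distance_matrix,
    rarefy,
    shannon_evenness,
)
from taxalit.exceptions import UndefinedDiversityError

from conftest import build_registry


def vec(*counts):
    return AbundanceVector.from_counts({f"s{i}": c for i, c in enumerate(counts)})


# ---------------------------------------------------------------------------
# Shannon evenness
# ---------------------------------------------------------------------------

class TestShannonEvenness:
    def test_uniform_distribution_is_one(self):
        assert shannon_evenness(vec(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_direct_formula_evaluation(self):
        # counts (10, 1, 1): H = -(10/12 ln 10/12 + 2 * 1/12 ln 1/12)
        p = np.array([10, 1, 1]) / 12
        expected = float(-(p * np.log(p)).sum() / math.log(3))
        assert shannon_evenness(vec(10, 1, 1)) == pytest.approx(expected)

    def test_single_taxon_is_undefined(self):
        with pytest.raises(UndefinedDiversityError):
            shannon_evenness(vec(7))

    def test_zero_abundance_taxa_excluded(self):
        assert shannon_evenness(vec(3, 3, 0, 0)) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=2, max_size=15),
           st.integers(min_value=1, max_value=7))
    def test_invariant_under_permutation_and_scaling(self, counts, factor):
        base = shannon_evenness(vec(*counts))
        assert shannon_evenness(vec(*reversed(counts))) == pytest.approx(base)
        assert shannon_evenness(vec(*[c * factor for c in counts])) == pytest.approx(base)
        if len(set(counts)) > 1:
            assert base < 1.0


# ---------------------------------------------------------------------------
# Chao1
# ---------------------------------------------------------------------------

def chao_oracle(counts):
    """Independent transcription of the classic Chao1 point/variance formulas."""
    counts = [c for c in counts if c > 0]
    S = len(counts)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    if f2 > 0:
        est = S + f1 ** 2 / (2 * f2)
        var = f2 * ((f1 / f2) ** 2 / 2 + (f1 / f2) ** 3 + (f1 / f2) ** 4 / 4)
    else:
        est = S + f1 * (f1 - 1) / 2
        var = (f1 * (f1 - 1) / 2 + f1 * (2 * f1 - 1) ** 2 / 4
               - f1 ** 4 / (4 * est)) if f1 else 0.0
    return est, math.sqrt(max(var, 0.0))


class TestChaoRichness:
    def test_no_singletons_collapses_to_observed(self):
        est, se = chao_richness(vec(3, 4, 5, 2))
        assert est == pytest.approx(4 + 0)  # f1 = 0 term vanishes

    def test_spec_arithmetic(self):
        # S_obs = 10, f1 = 4, f2 = 2 -> 10 + 16/4 = 14
        est, _ = chao_richness(vec(1, 1, 1, 1, 2, 2, 3, 4, 5, 6))
        assert est == pytest.approx(14.0)

    def test_estimate_never_below_observed_richness(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            counts = rng.integers(1, 8, size=rng.integers(1, 20))
            est, se = chao_richness(vec(*counts))
            assert est >= len(counts)
            assert se >= 0

    def test_empty_vector_raises(self):
        with pytest.raises(UndefinedDiversityError):
            chao_richness(vec(0, 0))


# ---------------------------------------------------------------------------
# Delta+ (average taxonomic distinctness)
# ---------------------------------------------------------------------------

CONGENERS = [
    f"Animalia|Arthropoda|Malacostraca|Decapoda|Palaemonidae|Palaemon|Palaemon sp{i}"
    for i in range(5)
]

THREE_PHYLA = (
    [f"Animalia|Chordata|Actinopterygii|Perciformes|Labridae|Labrus|Labrus f{i}"
     for i in range(4)]
    + [f"Animalia|Chordata|Actinopterygii|Perciformes|Gobiidae|Gobius|Gobius f{i}"
       for i in range(2)]
    + [f"Animalia|Mollusca|Gastropoda|Trochida|Trochidae|Trochus|Trochus m{i}"
       for i in range(3)]
    + [f"Plantae|Tracheophyta|Liliopsida|Alismatales|Zosteraceae|Zostera|Zostera p{i}"
       for i in range(3)]
)


class TestDeltaPlus:
    def test_all_congeners_give_minimum_nonzero_distance(self):
        reg = build_registry(CONGENERS, kingdoms=None)
        ids = [r.taxon_id for r in reg.valid_species()]
        res = delta_plus(ids, reg)
        assert res.delta_plus == pytest.approx(2 * 100 / 12)
        assert res.S == 5

    def test_species_sharing_only_kingdom_score_100(self):
        reg = build_registry([
            "Animalia|Chordata|Mammalia|Carnivora|Otariidae|Zalophus|Zalophus a",
            "Animalia|Mollusca|Bivalvia|Ostreida|Ostreidae|Ostrea|Ostrea b",
            "Animalia|Annelida|Polychaeta|Phyllodocida|Nereididae|Nereis|Nereis c",
        ], kingdoms=None)
        ids = [r.taxon_id for r in reg.valid_species()]
        assert delta_plus(ids, reg).delta_plus == pytest.approx(100.0)

    def test_matches_bruteforce_pair_loop(self):
        reg = build_registry(THREE_PHYLA, kingdoms=None)
        ids = sorted(r.taxon_id for r in reg.valid_species())
        assert len(ids) == 12
        dists = [reg.path_length(a, b) * 100 / 12
                 for i, a in enumerate(ids) for b in ids[i + 1:]]
        assert len(dists) == 66
        assert delta_plus(ids, reg).delta_plus == pytest.approx(np.mean(dists))

    def test_invariant_under_duplication(self):
        reg = build_registry(THREE_PHYLA, kingdoms=None)
        ids = [r.taxon_id for r in reg.valid_species()]
        assert delta_plus(ids * 3, reg) == delta_plus(ids, reg)

    def test_fewer_than_two_species_undefined(self):
        reg = build_registry(CONGENERS, kingdoms=None)
        with pytest.raises(UndefinedDiversityError):
            delta_plus([reg.valid_species()[0].taxon_id], reg)


class TestDistinctnessFunnel:
    def test_full_pool_size_has_zero_sd(self):
        reg = build_registry(THREE_PHYLA, kingdoms=None)
        ids = [r.taxon_id for r in reg.valid_species()]
        env = distinctness_funnel(ids, reg, sizes=[len(ids)], n_sim=10, seed=0)
        assert env.sim_sd == (0.0,)
        assert env.sim_mean[0] == pytest.approx(delta_plus(ids, reg).delta_plus)

    def test_reproducible_for_fixed_seed(self):
        reg = build_registry(THREE_PHYLA, kingdoms=None)
        ids = [r.taxon_id for r in reg.valid_species()]
        e1 = distinctness_funnel(ids, reg, sizes=[3, 6], n_sim=2, seed=42)
        e2 = distinctness_funnel(ids, reg, sizes=[3, 6], n_sim=2, seed=42)
        assert e1 == e2

    def test_homogeneous_pool_has_zero_sd_everywhere(self):
        reg = build_registry(CONGENERS, kingdoms=None)
        ids = [r.taxon_id for r in reg.valid_species()]
        env = distinctness_funnel(ids, reg, sizes=[2, 3, 4], n_sim=50, seed=1)
        assert env.sim_sd == (0.0, 0.0, 0.0)

    def test_mean_approaches_pool_delta_plus(self):
        """Law of large numbers: the simulated mean at a fixed subset size
        converges on the pool Δ+ within Monte-Carlo error."""
        reg = build_registry(THREE_PHYLA, kingdoms=None)
        ids = [r.taxon_id for r in reg.valid_species()]
        env = distinctness_funnel(ids, reg, sizes=[6], n_sim=10_000, seed=7)
        target = delta_plus(ids, reg).delta_plus
        mc_se = env.sim_sd[0] / math.sqrt(env.n_sim)
        assert abs(env.sim_mean[0] - target) < 3 * mc_se

    def test_size_larger_than_pool_rejected(self):
        reg = build_registry(CONGENERS, kingdoms=None)
        ids = [r.taxon_id for r in reg.valid_species()]
        with pytest.raises(ValueError):
            distinctness_funnel(ids, reg, sizes=[len(ids) + 1], n_sim=5, seed=0)


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy_expectation_oracle(counts, n):
    """Exact integer-arithmetic hypergeometric expectation."""
    N = sum(counts)
    return float(sum(
        1 - (math.comb(N - c, n) / math.comb(N, n) if N - c >= n else 0.0)
        for c in counts
    ))


class TestRarefy:
    def test_full_sample_returns_observed_richness_with_zero_variance(self):
        v = vec(5, 3, 2)
        c = rarefy(v, [10])
        assert c.expected_S[0] == pytest.approx(3.0)
        assert c.ci_low[0] == pytest.approx(c.ci_high[0]) == pytest.approx(3.0)

    def test_one_individual_is_one_species(self):
        c = rarefy(vec(5, 3, 2), [1])
        assert c.expected_S[0] == pytest.approx(1.0)

    def test_against_monte_carlo_subsampling(self):
        v = vec(5, 3, 2)
        n, draws = 4, 100_000
        rng = np.random.default_rng(17)
        individuals = np.repeat(np.arange(3), [5, 3, 2])
        richness = np.array([
            len(np.unique(rng.choice(individuals, size=n, replace=False)))
            for _ in range(draws)
        ])
        c = rarefy(v, [n])
        mc_se = richness.std(ddof=1) / math.sqrt(draws)
        assert abs(c.expected_S[0] - richness.mean()) < 3 * mc_se

    def test_exact_expectation_matches_comb_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            counts = list(map(int, rng.integers(1, 10, size=rng.integers(2, 10))))
            N = sum(counts)
            n = int(rng.integers(1, N + 1))
            c = rarefy(AbundanceVector.from_counts(
                {f"s{i}": x for i, x in enumerate(counts)}), [n])
            assert c.expected_S[0] == pytest.approx(
                rarefy_expectation_oracle(counts, n), rel=1e-10)

    def test_curve_non_decreasing_and_concave(self):
        v = vec(40, 12, 6, 3, 1, 1, 1)
        sizes = list(range(1, int(v.total) + 1))
        c = rarefy(v, sizes)
        e = np.array(c.expected_S)
        assert np.all(np.diff(e) >= -1e-12)
        assert np.all(np.diff(e, 2) <= 1e-12)

    def test_oversized_subsample_rejected(self):
        with pytest.raises(ValueError):
            rarefy(vec(2, 2), [5])


def test_distance_matrix_is_symmetric_zero_diagonal():
    reg = build_registry(THREE_PHYLA, kingdoms=None)
    ids = sorted(r.taxon_id for r in reg.valid_species())
    D = pairwise_distance_matrix(ids, reg)
    assert np.allclose(D, D.T)
    assert np.all(np.diag(D) == 0)
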