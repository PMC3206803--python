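import math

import numpy as np
import pandas as pd
import pytest

from taxalit.effort import fit_effort_richness, occurrence_probability, rank_classes


def make_rows(y, x, phyla, prefix="C"):
    return pd.DataFrame({
        "class_id": [f"{prefix}{i:02d}" for i in range(len(y))],
        "phylum_id": phyla,
        "n_papers": 10.0 ** np.asarray(y),
        "n_species_worms": 10.0 ** np.asarray(x),
    })


class TestOccurrenceProbability:
    def test_point_estimate_is_binomial_mle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(1, 500))
            h = int(rng.integers(0, n + 1))
            assert occurrence_probability(h, n).probability == pytest.approx(h / n)

    def test_symmetric_on_logit_scale(self):
        r = occurrence_probability(50, 100)
        logit = lambda p: math.log(p / (1 - p))
        assert logit(r.ci_high) == pytest.approx(-logit(r.ci_low))
        assert not r.degenerate

    def test_degenerate_zero_hits(self):
        r = occurrence_probability(0, 100)
        assert r.probability == 0.0 and r.ci_low == 0.0
        assert r.degenerate and 0 < r.ci_high < 0.1

    def test_degenerate_all_hits(self):
        r = occurrence_probability(100, 100)
        assert r.probability == 1.0 and r.ci_high == 1.0 and r.degenerate

    def test_wald_interval_closed_form(self):
        h, n = 7, 322
        logit = math.log(h / (n - h))
        se = math.sqrt(1 / h + 1 / (n - h))
        z = 1.959963984540054
        expit = lambda t: 1 / (1 + math.exp(-t))
        r = occurrence_probability(h, n)
        assert r.probability == pytest.approx(h / n)
        assert r.ci_low == pytest.approx(expit(logit - z * se))
        assert r.ci_high == pytest.approx(expit(logit + z * se))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            occurrence_probability(5, 4)
        with pytest.raises(ValueError):
            occurrence_probability(0, 0)


class TestFitEffortRichness:
    def test_noiseless_line_single_phylum_interpolated(self):
        x = np.linspace(1, 3, 10)
        rows = make_rows(0.5 + 0.8 * x, x, ["P0"] * 10)
        with pytest.warns(UserWarning, match="fewer than 3 phyla"):
            fit = fit_effort_richness(rows)
        assert np.abs(fit.table["residual"]).max() < 1e-9
        assert fit.r_squared == pytest.approx(1.0)

    def test_noiseless_phylum_intercepts_recovered(self):
        x = np.tile(np.linspace(1, 3, 8), 3)
        phyla = np.repeat(["Pa", "Pb", "Pc"], 8)
        b = {"Pa": -0.4, "Pb": 0.0, "Pc": 0.4}
        y = 0.3 + 0.9 * x + np.array([b[p] for p in phyla])
        fit = fit_effort_richness(make_rows(y, x, phyla))
        # residuals sum to ~0 within each phylum after intercept removal
        t = fit.table
        for p in ("Pa", "Pb", "Pc"):
            assert abs(t.loc[t.phylum_id == p, "residual"].sum()) < 1e-6
        est = fit.phylum_effects
        assert est["Pa"] < est["Pb"] < est["Pc"]
        assert np.abs(t["residual"]).max() < 1e-6

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 4, 30)
        phyla = [f"P{i % 3}" for i in range(30)]
        y = 0.5 + 0.7 * x + rng.normal(0, 0.2, 30)
        rows = make_rows(y, x, phyla)
        f1, f2 = fit_effort_richness(rows), fit_effort_richness(rows.copy())
        assert np.array_equal(f1.table["residual"], f2.table["residual"])

    def test_doubling_papers_preserves_residuals_and_ranking(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 4, 24)
        phyla = [f"P{i % 4}" for i in range(24)]
        y = 0.2 + 0.8 * x + rng.normal(0, 0.3, 24)
        rows = make_rows(y, x, phyla)
        f1 = fit_effort_richness(rows)
        f2 = fit_effort_richness(rows.assign(n_papers=rows.n_papers * 2))
        assert np.allclose(f1.table["residual"], f2.table["residual"], atol=1e-10)
        assert list(f1.table.sort_values("effort_residual").class_id) == \
            list(f2.table.sort_values("effort_residual").class_id)

    def test_zero_paper_classes_excluded_but_reported(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(1, 4, 12)
        phyla = [f"P{i % 3}" for i in range(12)]
        rows = make_rows(0.5 + 0.7 * x, x, phyla)
        rows.loc[0, "n_papers"] = 0
        fit = fit_effort_richness(rows)
        assert fit.excluded_zero_paper == ("C00",)
        assert "C00" not in set(fit.table["class_id"])

    def test_degenerate_predictor_rejected(self):
        rows = make_rows(np.linspace(0, 1, 10), np.full(10, 2.0),
                         [f"P{i % 3}" for i in range(10)])
        with pytest.raises(ValueError, match="degenerate"):
            fit_effort_richness(rows)

    def test_too_few_classes_rejected(self):
        rows = make_rows([1, 2, 3], [1, 2, 3], ["Pa", "Pb", "Pc"])
        with pytest.raises(ValueError, match="at least 8"):
            fit_effort_richness(rows)


class TestRankClasses:
    def test_distinct_residuals_sorted(self):
        rows = pd.DataFrame({"class_id": ["A", "B", "C"],
                             "effort_residual": [0.5, -1.0, 2.0]})
        out = rank_classes(rows, k=3)
        assert out["residual_top"] == ["C", "A", "B"]
        assert out["residual_bottom"] == ["B", "A", "C"]

    def test_ties_break_lexicographically(self):
        rows = pd.DataFrame({"class_id": ["Zeta", "Alpha", "Mid"],
                             "effort_residual": [1.0, 1.0, 0.0]})
        out = rank_classes(rows, k=2)
        assert out["residual_top"] == ["Alpha", "Zeta"]

    def test_unstudied_classes_head_bottom_ranking(self):
        rows = pd.DataFrame({
            "class_id": ["A", "B", "Unseen2", "Unseen1"],
            "effort_residual": [0.5, -0.5, np.nan, np.nan],
        })
        out = rank_classes(rows, k=3)
        assert out["residual_bottom"] == ["Unseen1", "Unseen2", "B"]
        assert out["residual_bottom_unstudied"] == ["Unseen1", "Unseen2"]

    def test_probability_ranking_and_truncation_warning(self):
        rows = pd.DataFrame({"class_id": ["A", "B"],
                             "effort_residual": [0.1, 0.2],
                             "occ_prob_coral": [0.9, 0.3]})
        with pytest.warns(UserWarning, match="truncated"):
            out = rank_classes(rows, k=5, probability_cols=["occ_prob_coral"])
        assert out["probability_top_occ_prob_coral"] == ["A", "B"]
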