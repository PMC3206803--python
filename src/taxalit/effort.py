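"""Research-effort models per taxonomic class.

Three pieces: (1) an intercept-only binomial model of a class's probability
of occurrence in an ecosystem's literature (Wald interval on the log-odds
scale); (2) a log10–log10 regression of paper counts on globally named
species richness — a fixed-df spline smooth with a phylum-level random
intercept estimated by iterative variance-ratio shrinkage; (3) deterministic
over-/under-study rankings from the occurrence probabilities and the model
residuals.  A positive residual marks a class studied more than its global
named richness predicts; a negative residual marks an under-studied class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class OccurrenceProbability(NamedTuple):
    """Binomial occurrence probability with a 95% CI."""

    probability: float
    ci_low: float
    ci_high: float
    degenerate: bool


def occurrence_probability(n_hits: int, n_papers_total: int) -> OccurrenceProbability:
    """Intercept-only binomial fit: MLE = n_hits / n_total, logit-scale Wald CI.

    Degenerate inputs (0 or all hits) keep the raw point estimate but get a
    one-sided CI computed with a 0.5 continuity adjustment and are flagged.
    """
    if n_papers_total < 1:
        raise ValueError("n_papers_total must be >= 1")
    if not 0 <= n_hits <= n_papers_total:
        raise ValueError(f"n_hits {n_hits} outside [0, {n_papers_total}]")
    p = n_hits / n_papers_total
    degenerate = n_hits in (0, n_papers_total)
    h = min(max(n_hits, 0.5), n_papers_total - 0.5) if degenerate else float(n_hits)
    logit = np.log(h / (n_papers_total - h))
    se = np.sqrt(1.0 / h + 1.0 / (n_papers_total - h))
    lo = 1.0 / (1.0 + np.exp(-(logit - _Z95 * se)))
    hi = 1.0 / (1.0 + np.exp(-(logit + _Z95 * se)))
    if degenerate:  # one-sided: pin the boundary side at the MLE
        if n_hits == 0:
            lo = 0.0
        else:
            hi = 1.0
    return OccurrenceProbability(float(p), float(lo), float(hi), degenerate)


# ---------------------------------------------------------------------------
# Effort vs global richness: smooth + phylum random intercept
# ---------------------------------------------------------------------------

def _spline_knots(x: np.ndarray, df: int, degree: int = 3) -> tuple[np.ndarray, int]:
    """Knot vector for a ``df``-column B-spline basis over the range of ``x``.

    Interior knots at quantiles of ``x``; with df = degree the basis spans
    plain degree-``degree`` polynomials, so noiseless linear data is fit
    exactly.
    """
    if df < 1:
        raise ValueError("spline_df must be >= 1")
    degree = min(degree, df)
    n_inner = df - degree
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError("degenerate predictor: all values equal")
    inner = (
        np.quantile(x, np.linspace(0, 1, n_inner + 2)[1:-1]) if n_inner else np.array([])
    )
    return np.r_[[lo] * (degree + 1), inner, [hi] * (degree + 1)], degree


def _spline_basis(
    x: np.ndarray, knots: np.ndarray, degree: int
) -> np.ndarray:
    dm = BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()
    return dm[:, 1:]  # drop one column; the model supplies its own intercept


@dataclass
class EffortFit:
    """Fitted effort-vs-richness model."""

    table: pd.DataFrame            # class_id, phylum_id, x, y, fitted, residual
    phylum_effects: dict[str, float]
    r_squared: float
    sigma2_between: float
    sigma2_within: float
    converged: bool
    n_iter: int
    spline_df: int
    excluded_zero_paper: tuple[str, ...]

    def predict_smooth(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the fitted smooth (no phylum effect) at new log10 richness."""
        xs = np.clip(np.asarray(x, dtype=float), self._knots[0], self._knots[-1])
        B = _spline_basis(xs, self._knots, self._degree)
        return self._beta[0] + B @ self._beta[1:]


def fit_effort_richness(
    rows: pd.DataFrame,
    spline_df: int = 3,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> EffortFit:
    """Fit log10(papers) ~ smooth(log10(global species)) + phylum intercept.

    ``rows`` needs columns ``class_id``, ``phylum_id``, ``n_papers``,
    ``n_species_worms``.  Classes with 0 papers are excluded from the
    regression (log10 undefined) and reported separately.  The phylum random
    intercept is estimated by iterating: fit the smooth by OLS on the
    intercept-adjusted response, take phylum means of the residuals, shrink
    them toward 0 by the variance-ratio factor σ²_b / (σ²_b + σ²_e / n_p),
    repeat to convergence.  With fewer than 3 phyla the random effect is
    dropped with a warning.  Deterministic: identical input gives identical
    output.

    The output table carries two deviations: ``residual`` (response minus the
    full prediction, smooth plus phylum intercept) and ``effort_residual``
    (response minus the smooth alone).  The latter is the per-class
    over-/under-study signal used for ranking — a class in a heavily studied
    phylum counts as heavily studied.
    """
    required = {"class_id", "phylum_id", "n_papers", "n_species_worms"}
    if not required <= set(rows.columns):
        raise ValueError(f"rows must have columns {sorted(required)}")
    data = rows.copy()
    zero = data["n_papers"] < 1
    excluded = tuple(sorted(data.loc[zero, "class_id"].astype(str)))
    if zero.any():
        logger.warning(
            "%d classes with 0 papers excluded from the regression", int(zero.sum())
        )
    data = data.loc[~zero].reset_index(drop=True)
    if len(data) < 8:
        raise ValueError(f"need at least 8 classes with papers, got {len(data)}")
    x = np.log10(data["n_species_worms"].to_numpy(dtype=float))
    y = np.log10(data["n_papers"].to_numpy(dtype=float))
    phyla = data["phylum_id"].astype(str).to_numpy()
    uniq_phyla = sorted(set(phyla))
    use_random = len(uniq_phyla) >= 3
    if not use_random:
        warnings.warn(
            "fewer than 3 phyla: fitting without a phylum random intercept",
            stacklevel=2,
        )

    knots, degree = _spline_knots(x, spline_df)
    B = _spline_basis(x, knots, degree)
    X = np.column_stack([np.ones_like(x), B])
    groups = {p: np.flatnonzero(phyla == p) for p in uniq_phyla}

    b = {p: 0.0 for p in uniq_phyla}
    sigma2_b = sigma2_e = 0.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        offset = np.array([b[p] for p in phyla])
        beta, *_ = np.linalg.lstsq(X, y - offset, rcond=None)
        smooth = X @ beta
        r = y - smooth
        if not use_random:
            converged = True
            break
        means = {p: float(r[idx].mean()) for p, idx in groups.items()}
        within = sum(float(np.sum((r[idx] - means[p]) ** 2)) for p, idx in groups.items())
        dof = max(len(y) - len(uniq_phyla), 1)
        sigma2_e = max(within / dof, 1e-12)
        inv_n = np.mean([1.0 / len(idx) for idx in groups.values()])
        sigma2_b = max(
            float(np.mean([m * m for m in means.values()])) - sigma2_e * inv_n, 0.0
        )
        new_b = {
            p: sigma2_b / (sigma2_b + sigma2_e / len(groups[p])) * means[p]
            for p in uniq_phyla
        }
        # absorb any common level into the global intercept
        level = float(np.mean([new_b[p] for p in uniq_phyla]))
        new_b = {p: v - level for p, v in new_b.items()}
        delta = max(abs(new_b[p] - b[p]) for p in uniq_phyla)
        b = new_b
        if delta < tol:
            converged = True
            break
    offset = np.array([b[p] for p in phyla])
    beta, *_ = np.linalg.lstsq(X, y - offset, rcond=None)
    smooth = X @ beta
    fitted = smooth + offset
    resid = y - fitted
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    table = data.copy()
    table["log_species"] = x
    table["log_papers"] = y
    table["fitted"] = fitted
    table["residual"] = resid
    # deviation from the smooth alone: the phylum deviation stays in, which is
    # what "effort corrected for global richness" means for a class ranking
    table["effort_residual"] = y - smooth

    fit = EffortFit(
        table=table,
        phylum_effects=b,
        r_squared=r2,
        sigma2_between=float(sigma2_b),
        sigma2_within=float(sigma2_e),
        converged=converged,
        n_iter=n_iter,
        spline_df=spline_df,
        excluded_zero_paper=excluded,
    )
    # stash prediction state
    fit._beta = beta  # type: ignore[attr-defined]
    fit._knots = knots  # type: ignore[attr-defined]
    fit._degree = degree  # type: ignore[attr-defined]
    return fit


# ---------------------------------------------------------------------------
# Rankings
# ---------------------------------------------------------------------------

def rank_classes(
    rows: pd.DataFrame,
    k: int = 10,
    residual_col: str = "effort_residual",
    probability_cols: Sequence[str] = (),
) -> dict[str, object]:
    """Top-k / bottom-k classes by model residual and by occurrence probability.

    ``rows`` needs ``class_id`` and ``residual_col``; rows with NaN residual
    (classes excluded from the model, e.g. 0 papers) are treated as
    "unstudied" and head the bottom ranking.  Ties break lexicographically by
    class name, so rankings are stable across runs.  ``probability_cols``
    (e.g. per-ecosystem ``occ_prob_<eco>``) each yield a top-k list.
    """
    if k > len(rows):
        warnings.warn(
            f"k={k} exceeds {len(rows)} available classes; lists truncated",
            stacklevel=2,
        )
    df = rows.copy()
    df["class_id"] = df["class_id"].astype(str)
    fitted = df[df[residual_col].notna()]
    unstudied = df[df[residual_col].isna()].sort_values("class_id")

    top = fitted.sort_values(
        [residual_col, "class_id"], ascending=[False, True], kind="mergesort"
    ).head(k)
    bottom_pool = pd.concat(
        [
            unstudied.assign(unstudied=True),
            fitted.sort_values(
                [residual_col, "class_id"], ascending=[True, True], kind="mergesort"
            ).assign(unstudied=False),
        ]
    ).head(k)

    out: dict[str, object] = {
        "residual_top": list(top["class_id"]),
        "residual_bottom": list(bottom_pool["class_id"]),
        "residual_bottom_unstudied": list(
            bottom_pool.loc[bottom_pool["unstudied"], "class_id"]
        ),
    }
    for col in probability_cols:
        ranked = df[df[col].notna()].sort_values(
            [col, "class_id"], ascending=[False, True], kind="mergesort"
        )
        out[f"probability_top_{col}"] = list(ranked.head(k)["class_id"])
    return out
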