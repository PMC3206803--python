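"""Plot helpers for the funnel, rarefaction and effort-vs-richness figures.

These are thin matplotlib wrappers over the tidy results; all numbers come
from the diversity and effort modules.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .diversity import DistinctnessResult, FunnelEnvelope, RarefactionCurve
from .effort import EffortFit


def plot_funnel(
    envelope: FunnelEnvelope,
    observed: Mapping[str, Sequence[DistinctnessResult]] | None = None,
    ax=None,
):
    """Δ+ funnel: simulated mean (dashed) and ±2 sd limits (solid) vs subset
    size, with observed per-ecosystem/period points overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sizes = np.asarray(envelope.subset_sizes)
    mean = np.asarray(envelope.sim_mean)
    sd = np.asarray(envelope.sim_sd)
    ax.plot(sizes, mean, "k--", label="simulated mean")
    ax.plot(sizes, mean + 2 * sd, "k-", lw=0.8)
    ax.plot(sizes, mean - 2 * sd, "k-", lw=0.8, label="±2 sd")
    if observed:
        for label, results in observed.items():
            ax.scatter(
                [r.S for r in results], [r.delta_plus for r in results], label=label
            )
    ax.set_xlabel("Number of species")
    ax.set_ylabel("Taxonomic distinctness (Δ+)")
    ax.legend(fontsize="small")
    return ax


def plot_rarefaction(curves: Mapping[str, RarefactionCurve], ax=None):
    """Rarefaction curves with 95% confidence clouds, one per ecosystem."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, c in curves.items():
        n = np.asarray(c.sample_sizes)
        ax.plot(n, c.expected_S, label=label)
        ax.fill_between(n, c.ci_low, c.ci_high, alpha=0.25)
    ax.set_xlabel("Number of papers")
    ax.set_ylabel("Expected species richness")
    ax.legend(fontsize="small")
    return ax


def plot_effort_richness(fit: EffortFit, ax=None):
    """Log–log scatter of papers vs global named richness with the fitted smooth."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = fit.table
    ax.scatter(t["log_species"], t["log_papers"], s=12)
    grid = np.linspace(t["log_species"].min(), t["log_species"].max(), 100)
    ax.plot(grid, fit.predict_smooth(grid), "k-", label="fitted smooth")
    ax.set_xlabel("log10 named species in registry")
    ax.set_ylabel("log10 papers")
    ax.legend(fontsize="small")
    return ax
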