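"""Optional matplotlib views of the canonical tables.

All quantitative outputs live in the tables produced by
:mod:`sdart.reporting`; these helpers only render them.  Each function
returns the matplotlib Axes so callers can restyle or save.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_theta_medians", "plot_band_profile", "plot_ppp"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_theta_medians(results, ax=None, bins=20, **kwargs):
    """Histogram of the per-participant posterior median shifts (ms)."""
    ax = _ax(ax)
    med = results.theta_medians()
    ax.hist(med.to_numpy(), bins=bins, **kwargs)
    ax.set_xlabel("posterior median shift theta_j (ms)")
    ax.set_ylabel("participants")
    return ax


def plot_band_profile(cell_table, ax=None, **kwargs):
    """Cell-mean posteriors against frequency band (amalgamated over length)."""
    from .reporting import amalgamate

    ax = _ax(ax)
    prof = amalgamate(cell_table, over="length")
    ax.errorbar(prof["band"], prof["mean_ms"], yerr=prof["sd_ms"], fmt="o-", **kwargs)
    ax.set_xlabel("word-frequency band (ascending frequency)")
    ax.set_ylabel("stochastic-component mean E[x] (ms)")
    return ax


def plot_ppp(ppp_result, ax=None, **kwargs):
    """Violin of cell-level posterior predictive p-values; 0.5 marks fit."""
    ax = _ax(ax)
    v = np.asarray(ppp_result.values)
    ax.violinplot(v, showmedians=True, **kwargs)
    ax.axhline(0.5, ls="--", lw=0.8, color="grey")
    ax.set_ylim(-0.02, 1.02)
    ax.set_ylabel("posterior predictive p-value")
    return ax
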