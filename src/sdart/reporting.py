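"""Tabular summary products of a fitted analysis.

Canonical outputs are tables (all times in ms): per-participant shift
medians, per-cell posteriors of the stochastic-component mean with
amalgamations over length (frequency profile) and over frequency (length
profile), tidy ppp tables, and the delta-elpd comparison table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "theta_median_table",
    "cell_mean_table",
    "amalgamate",
    "ppp_table",
    "comparison_table",
]


def theta_median_table(results) -> pd.DataFrame:
    """Posterior median and 95% interval of the shift (ms) per participant."""
    tab = results.credible_intervals("theta").reset_index()
    tab.columns = ["participant_id", "theta_median_ms", "theta_lo_ms", "theta_hi_ms"]
    return tab


def cell_mean_table(results) -> pd.DataFrame:
    """Posterior summary of the stochastic-component mean E[x] (ms) per cell."""
    draws = results.cell_mean_draws()  # (S, C)
    tab = results.draws.cell_index.copy()
    tab["mean_ms"] = draws.mean(axis=0)
    tab["median_ms"] = np.median(draws, axis=0)
    q = np.quantile(draws, [0.025, 0.975], axis=0)
    tab["lo_ms"] = q[0]
    tab["hi_ms"] = q[1]
    return tab


def amalgamate(cell_table: pd.DataFrame, over: str = "length") -> pd.DataFrame:
    """Collapse the per-cell mean table over one stratification axis.

    ``over="length"`` gives the frequency profile (one row per band);
    ``over="band"`` gives the length profile (one row per length).  Cell
    posterior means are averaged across participants and the collapsed
    axis; dispersion columns carry the spread of the cell means.
    """
    if over not in ("length", "band"):
        raise ValueError("over must be 'length' or 'band'")
    keep = "band" if over == "length" else "length"
    g = cell_table.groupby(keep)["mean_ms"]
    out = g.agg(mean_ms="mean", sd_ms="std", q25_ms=lambda s: s.quantile(0.25),
                q75_ms=lambda s: s.quantile(0.75), n_cells="size").reset_index()
    out["sd_ms"] = out["sd_ms"].fillna(0.0)
    return out


def ppp_table(ppp_result) -> pd.DataFrame:
    """Tidy (participant, band, length, ppp) table of one model's ppp values."""
    tab = ppp_result.table.copy()
    tab.insert(0, "statistic", ppp_result.statistic)
    tab.insert(1, "R", ppp_result.R)
    return tab


def comparison_table(comparison) -> pd.DataFrame:
    """The delta-elpd ranking (model, delta_elpd, se) with the reference first."""
    tab = comparison.table.copy()
    tab.insert(0, "reference", comparison.reference)
    return tab
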