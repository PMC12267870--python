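"""Results object returned by :meth:`StratifiedRTModel.fit`."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assessment
from .model import HyperParams, PosteriorDraws, StratifiedRTModel

__all__ = ["SDAResults"]


class SDAResults:
    """Posterior draws plus the diagnostics and summaries derived from them.

    Carries the fitted :class:`~sdart.model.StratifiedRTModel` and its
    :class:`~sdart.model.PosteriorDraws`; assessment (posterior predictive
    replication, ppp, elpd) hangs off this object.
    """

    def __init__(self, model: StratifiedRTModel, draws: PosteriorDraws) -> None:
        self.model = model
        self.draws = draws

    # ------------------------------------------------------------------ #
    # point summaries
    # ------------------------------------------------------------------ #
    def theta_medians(self) -> pd.Series:
        """Posterior median shift (ms) per participant."""
        return self.draws.posterior_medians("theta")

    def cell_medians(self, quantity: str = "cell_mean") -> pd.Series:
        """Posterior median of a per-cell quantity (rho1, rho2 or cell_mean)."""
        return self.draws.posterior_medians(quantity)

    def credible_intervals(self, quantity: str, level: float = 0.95) -> pd.DataFrame:
        """Central credible intervals per unit of ``quantity``."""
        lo = (1.0 - level) / 2.0
        arr = self.draws.stacked(quantity)
        q = np.quantile(arr, [lo, 1.0 - lo], axis=0)
        med = self.draws.posterior_medians(quantity)
        return pd.DataFrame({"median": med, "lower": q[0], "upper": q[1]}, index=med.index)

    def cell_mean_draws(self) -> np.ndarray:
        """Pooled draws of the stochastic-component mean E[x] per cell."""
        return self.draws.stacked("cell_mean")

    # ------------------------------------------------------------------ #
    # assessment
    # ------------------------------------------------------------------ #
    def posterior_predictive(self, R: int = 200, seed=None) -> np.ndarray:
        return assessment.posterior_predictive_sample(self.draws, self.model.dataset, R, seed)

    def ppp(self, R: int = 200, seed=None, by: str = "cell") -> assessment.PppResult:
        reps = self.posterior_predictive(R=R, seed=seed)
        return assessment.ppp_values(self.model.dataset, reps, by=by)

    def elpd(self, method: str = "loo", label: str | None = None) -> assessment.ElpdResult:
        return assessment.elpd_estimate(self.draws, self.model.dataset, method=method, label=label)

    def log_likelihood(self) -> np.ndarray:
        return assessment.log_likelihood_matrix(self.draws, self.model.dataset)

    # ------------------------------------------------------------------ #
    # summary
    # ------------------------------------------------------------------ #
    def summary(self) -> str:
        m, d = self.model, self.draws
        meta = d.metadata
        lines = [
            "Stratified distributional analysis of response times",
            "=" * 56,
            f"family:        shifted {m.family.value}",
            f"participants:  {m.n_participants}",
            f"cells (j,k,l): {m.n_cells}   lengths: {list(m.lengths)}",
            f"trials:        {m.n_trials}",
            f"chains x draws: {d.n_chains} x {d.n_draws}  (warmup {meta.get('warmup')})",
            f"max split R-hat: {meta.get('rhat_max'):.4f}   min ESS: {meta.get('ess_min'):.0f}"
            if np.isfinite(meta.get("rhat_max", np.nan))
            else "convergence diagnostics unavailable (too few draws)",
        ]
        small = meta.get("small_cells", [])
        if small:
            lines.append(f"sparse cells (<{m.min_cell_size} trials, shrunk by hierarchy): {len(small)}")
        lines.append("")
        theta_ci = self.credible_intervals("theta")
        lines.append("participant shift theta_j (ms): median [95% CI]")
        for pid, row in theta_ci.iterrows():
            lines.append(
                f"  {pid!s:>12}: {row['median']:8.1f}  [{row['lower']:7.1f}, {row['upper']:7.1f}]"
            )
        names = HyperParams.names(d.lengths)
        psi_med = np.median(d.stacked("psi"), axis=0)
        lines.append("")
        lines.append("hyperparameters psi (posterior medians):")
        for n, v in zip(names, psi_med):
            lines.append(f"  {n:>12}: {v:10.4g}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SDAResults family={self.model.family.value} "
            f"J={self.model.n_participants} cells={self.model.n_cells} "
            f"draws={self.draws.n_chains}x{self.draws.n_draws}>"
        )
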