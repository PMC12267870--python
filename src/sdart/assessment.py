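"""Posterior predictive assessment and predictive-density model selection.

Two complementary questions are answered here.  *Is each fitted model
consistent with the data?* — answered by posterior predictive p-values
(ppp): the proportion of model-replicated datasets whose cell-mean RT is at
least the observed cell mean; values near 0.5 indicate fit.  *Which model
predicts best?* — answered by the expected log pointwise predictive
density (elpd), approximated by Pareto-smoothed importance-sampling
leave-one-out (default), WAIC, or the in-sample log pointwise predictive
density, and summarised as differences to the best model with a paired
standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .families import log_density_arrays, sample_arrays
from .model import PosteriorDraws
from .preprocessing import StratifiedDataset

__all__ = [
    "PppResult",
    "ElpdResult",
    "ModelComparison",
    "posterior_predictive_sample",
    "ppp_values",
    "pointwise_log_predictive",
    "log_likelihood_matrix",
    "elpd_estimate",
    "compare_models",
]


def _alignment(draws: PosteriorDraws, dataset: StratifiedDataset):
    """Per-trial participant and cell indices of ``dataset`` under ``draws``.

    Raises ``ValueError`` when the dataset contains a cell the draws do not
    know (structural mismatch).
    """
    ci = draws.cell_index
    cell_pos = {
        (r.participant_id, r.band, r.length): i for i, r in enumerate(ci.itertuples())
    }
    part_pos = {p: i for i, p in enumerate(draws.participant_ids)}
    df = dataset.df
    try:
        tc = np.array(
            [cell_pos[(p, b, l)] for p, b, l in zip(df["participant_id"], df["band"], df["length"])],
            dtype=np.int64,
        )
        tj = np.array([part_pos[p] for p in df["participant_id"]], dtype=np.int64)
    except KeyError as e:  # pragma: no cover - message matters, not the path
        raise ValueError(f"dataset cell {e} absent from the posterior draws") from e
    return tj, tc, df["rt"].to_numpy(dtype=float)


def posterior_predictive_sample(
    draws: PosteriorDraws, dataset: StratifiedDataset, R: int, seed=None
) -> np.ndarray:
    """Draw ``R`` replicated datasets from the posterior predictive.

    Each replicate picks one joint posterior draw and samples every trial's
    RT from the shifted family at that draw's cell parameters, so replicate
    ``r`` is cell-aligned with the observed data: the returned array has
    shape ``(R, n_trials)`` in the dataset's trial order.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    tj, tc, _ = _alignment(draws, dataset)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = draws.stacked("theta")
    rho1 = draws.stacked("rho1")
    rho2 = draws.stacked("rho2")
    pick = rng.integers(0, theta.shape[0], size=R)
    out = np.empty((R, tj.size))
    for r, s in enumerate(pick):
        out[r] = sample_arrays(
            rng, theta[s][tj], rho1[s][tc], rho2[s][tc], draws.family, size=tj.size
        )
    return out


@dataclass
class PppResult:
    """Posterior predictive p-values, one per assessed unit."""

    statistic: str
    R: int
    by: str  # "cell" or "participant"
    table: pd.DataFrame  # index columns + "ppp"

    @property
    def values(self) -> np.ndarray:
        return self.table["ppp"].to_numpy()


def ppp_values(
    dataset: StratifiedDataset,
    replicates: np.ndarray,
    by: str = "cell",
    statistic: str = "mean",
) -> PppResult:
    """ppp per cell (or participant): share of replicates whose statistic
    meets or exceeds the observed one (ties count toward the numerator).

    Only the mean statistic is supported; empty units cannot occur because
    units are defined by the observed trials themselves.
    """
    if statistic != "mean":
        raise NotImplementedError("only the mean statistic is implemented")
    if replicates.ndim != 2 or replicates.shape[1] != dataset.n_trials:
        raise ValueError("replicates are not cell-aligned with the dataset")
    R = replicates.shape[0]
    df = dataset.df
    keys = ["participant_id", "band", "length"] if by == "cell" else ["participant_id"]
    codes, uniques = pd.factorize(pd.MultiIndex.from_frame(df[keys]) if by == "cell" else df[keys[0]])
    n_units = len(uniques)
    counts = np.bincount(codes, minlength=n_units).astype(float)
    obs = np.bincount(codes, weights=df["rt"].to_numpy(), minlength=n_units) / counts
    ge = np.zeros(n_units)
    for r in range(R):
        rep_mean = np.bincount(codes, weights=replicates[r], minlength=n_units) / counts
        ge += rep_mean >= obs
    ppp = ge / R
    if by == "cell":
        out = pd.DataFrame(list(uniques), columns=keys)
    else:
        out = pd.DataFrame({keys[0]: list(uniques)})
    out["n_trials"] = counts.astype(int)
    out["ppp"] = ppp
    return PppResult(statistic=statistic, R=R, by=by, table=out)


def log_likelihood_matrix(
    draws: PosteriorDraws, dataset: StratifiedDataset, chunk: int = 256
) -> np.ndarray:
    """Per-draw per-trial log-likelihood, shape (chains, draws, n_trials)."""
    tj, tc, y = _alignment(draws, dataset)
    ch, S, _ = draws.theta.shape
    out = np.empty((ch, S, y.size))
    for c in range(ch):
        for s0 in range(0, S, chunk):
            s1 = min(s0 + chunk, S)
            out[c, s0:s1] = log_density_arrays(
                y[None, :],
                draws.theta[c, s0:s1][:, tj],
                draws.rho1[c, s0:s1][:, tc],
                draws.rho2[c, s0:s1][:, tc],
                draws.family,
            )
    return out


def pointwise_log_predictive(draws: PosteriorDraws, dataset: StratifiedDataset) -> np.ndarray:
    """Per-trial log posterior predictive density: log mean over draws of
    the family density at the trial.

    A trial at or below every drawn shift contributes ``-inf`` (flagged by
    the caller via non-finiteness).
    """
    ll = log_likelihood_matrix(draws, dataset)
    S = ll.shape[0] * ll.shape[1]
    flat = ll.reshape(S, -1)
    with np.errstate(divide="ignore"):
        return special.logsumexp(flat, axis=0) - np.log(S)


@dataclass
class ElpdResult:
    """Estimated elpd for one model on one trial set."""

    label: str
    method: str
    elpd: float
    se: float
    pointwise: np.ndarray
    flags: np.ndarray = field(default=None)  # per-point reliability warnings
    n: int = 0

    def __post_init__(self) -> None:
        self.pointwise = np.asarray(self.pointwise, dtype=float)
        self.n = self.pointwise.size
        if self.flags is None:
            self.flags = np.zeros(self.n, dtype=bool)
        if np.isfinite(self.elpd) and not np.isclose(
            self.elpd, float(np.sum(self.pointwise)), rtol=1e-6, atol=1e-6
        ):
            raise ValueError("elpd total must equal the sum of pointwise contributions")


def elpd_estimate(
    draws: PosteriorDraws,
    dataset: StratifiedDataset,
    method: str = "loo",
    label: str | None = None,
) -> ElpdResult:
    """Approximate the expected log pointwise predictive density.

    ``method`` is one of

    * ``"loo"`` (default) — Pareto-smoothed importance-sampling
      leave-one-out; points with Pareto k > 0.7 are flagged as unreliable;
    * ``"waic"`` — widely applicable information criterion;
    * ``"lpd"`` — in-sample log pointwise predictive density (optimistic;
      used as a brute-force cross-check).
    """
    import warnings as _warnings

    label = label or draws.family.value
    if method == "lpd":
        pw = pointwise_log_predictive(draws, dataset)
        se = float(np.sqrt(pw.size * np.var(pw, ddof=1))) if pw.size > 1 else 0.0
        return ElpdResult(label, "lpd", float(np.sum(pw)), se, pw, ~np.isfinite(pw))

    import arviz as az

    ll = log_likelihood_matrix(draws, dataset)
    idata = draws.to_inference_data(log_likelihood=ll)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        if method == "loo":
            res = az.loo(idata, pointwise=True)
            pw = np.asarray(res.loo_i)
            flags = np.asarray(res.pareto_k) > 0.7
        elif method == "waic":
            res = az.waic(idata, pointwise=True)
            pw = np.asarray(res.waic_i) if hasattr(res, "waic_i") else np.asarray(res.elpd_i)
            flags = None
        else:
            raise ValueError(f"unknown elpd method {method!r}")
    return ElpdResult(label, method, float(np.sum(pw)), float(res.se), pw, flags)


@dataclass
class ModelComparison:
    """Delta-elpd ranking of several models against the best one."""

    reference: str
    table: pd.DataFrame  # columns: model, delta_elpd, se

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ModelComparison(reference={self.reference!r})\n{self.table.to_string(index=False)}"


def compare_models(results: list[ElpdResult]) -> ModelComparison:
    """Rank models by elpd difference to the best model.

    The model with the largest elpd is the reference (delta = 0, se = 0);
    every other model gets ``delta = elpd_m - elpd_ref`` (non-positive) and
    the paired standard error ``sqrt(n) * sd(pointwise differences)``.
    All models must be estimated on the identical trial set.
    """
    if not results:
        raise ValueError("no models to compare")
    n = results[0].n
    if any(r.n != n for r in results):
        raise ValueError("models were not evaluated on the same trial set")
    ref = max(results, key=lambda r: r.elpd)
    rows = []
    for r in results:
        diff = r.pointwise - ref.pointwise
        if r is ref:
            se = 0.0
        else:
            se = float(np.sqrt(n * np.var(diff, ddof=1))) if n > 1 else 0.0
        rows.append({"model": r.label, "delta_elpd": float(np.sum(diff)), "se": se})
    table = pd.DataFrame(rows).sort_values("delta_elpd", ascending=False, kind="stable")
    return ModelComparison(reference=ref.label, table=table.reset_index(drop=True))
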