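"""Hierarchical Bayesian model for stratified RT distributions.

Every response time is decomposed as ``y_ijkl = theta_j + x_ijkl``: a
deterministic participant shift ``theta_j`` plus a stochastic component
``x_ijkl`` following a shifted lognormal, Wald or gamma distribution whose
two free parameters ``rho_jkl = (rho1, rho2)`` are specific to the
(participant j, frequency band k, word length l) cell.  The hierarchy is

* ``rho_jkl[m] ~ Gamma(alpha_l[m], beta_l[m])`` — length-specific priors,
* ``theta_j    ~ Gamma(alpha_theta, beta_theta)``,
* every hyperparameter in ``psi = (alpha_l[1], beta_l[1], alpha_l[2],
  beta_l[2] for each modelled length; alpha_theta, beta_theta)`` gets its
  own ``Gamma(a_i, b_i)`` hyperprior with fixed ``(a_i, b_i)``.

With the full 4-10 character range that makes 30 hyperparameters.  All
gamma distributions are shape/rate parametrized.

Posterior sampling uses an adaptive Metropolis-within-Gibbs scheme:
Gaussian random walks for each ``theta_j`` on the natural scale (the
likelihood is ``-inf`` at ``theta_j >=`` the participant's minimum RT, so
proposals beyond it are rejected), joint log-scale random walks for each
cell's ``(rho1, rho2)`` pair, conjugate gamma draws for the rate
hyperparameters, and log-scale random walks for the shape hyperparameters.
Step sizes adapt per block during warmup only, leaving the post-warmup
chain a valid Markov chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .families import Family, log_density_arrays
from .preprocessing import StratifiedDataset

__all__ = ["PriorConfig", "HyperParams", "PosteriorDraws", "StratifiedRTModel"]

_ADAPT_BATCH = 25
_TARGET_1D = 0.44
_TARGET_2D = 0.35


def _gamma_logpdf(x, a, b):
    """Shape/rate gamma log-density, vectorized."""
    x = np.asarray(x, dtype=float)
    return special.xlogy(a, b) - special.gammaln(a) + special.xlogy(a - 1.0, x) - b * x


@dataclass(frozen=True)
class HyperParams:
    """The hyperparameter set psi: per-length gamma pairs plus the shift pair."""

    lengths: tuple[int, ...]
    alpha1: np.ndarray
    beta1: np.ndarray
    alpha2: np.ndarray
    beta2: np.ndarray
    alpha_theta: float
    beta_theta: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (len(self.lengths),) or np.any(v <= 0):
                raise ValueError(f"{name} must be positive with one entry per length")
        if self.alpha_theta <= 0 or self.beta_theta <= 0:
            raise ValueError("shift hyperparameters must be positive")

    @staticmethod
    def names(lengths) -> list[str]:
        out = []
        for l in lengths:
            out += [f"alpha1[{l}]", f"beta1[{l}]", f"alpha2[{l}]", f"beta2[{l}]"]
        return out + ["alpha_theta", "beta_theta"]

    def to_vector(self) -> np.ndarray:
        cols = np.column_stack([self.alpha1, self.beta1, self.alpha2, self.beta2])
        return np.concatenate([cols.ravel(), [self.alpha_theta, self.beta_theta]])

    @classmethod
    def from_vector(cls, lengths, vec) -> "HyperParams":
        vec = np.asarray(vec, dtype=float)
        L = len(lengths)
        cols = vec[: 4 * L].reshape(L, 4)
        return cls(
            lengths=tuple(lengths),
            alpha1=cols[:, 0],
            beta1=cols[:, 1],
            alpha2=cols[:, 2],
            beta2=cols[:, 3],
            alpha_theta=float(vec[-2]),
            beta_theta=float(vec[-1]),
        )


@dataclass(frozen=True)
class PriorConfig:
    """Fixed (a_i, b_i) pairs of the gamma hyperpriors, one per psi entry."""

    lengths: tuple[int, ...]
    ab: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        expected = HyperParams.names(self.lengths)
        missing = set(expected) - set(self.ab)
        if missing:
            raise ValueError(f"missing hyperprior pairs: {sorted(missing)}")
        for name, (a, b) in self.ab.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"hyperprior pair for {name} must be positive")

    @classmethod
    def default(cls, lengths, a: float = 0.1, b: float = 0.1) -> "PriorConfig":
        """Diffuse default: every pair Gamma(a, b) (mean a/b, variance a/b^2)."""
        lengths = tuple(sorted(lengths))
        return cls(lengths=lengths, ab={n: (a, b) for n in HyperParams.names(lengths)})

    def vectors(self) -> tuple[np.ndarray, np.ndarray]:
        names = HyperParams.names(self.lengths)
        a = np.array([self.ab[n][0] for n in names])
        b = np.array([self.ab[n][1] for n in names])
        return a, b


@dataclass
class PosteriorDraws:
    """Joint posterior draws of all theta_j, rho_jkl and psi for one model."""

    family: Family
    participant_ids: list
    cell_index: pd.DataFrame  # columns: participant_id, band, length
    lengths: tuple[int, ...]
    theta: np.ndarray  # (chains, S, J)
    rho1: np.ndarray  # (chains, S, C)
    rho2: np.ndarray  # (chains, S, C)
    psi: np.ndarray  # (chains, S, P)
    metadata: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def stacked(self, quantity: str) -> np.ndarray:
        """Draws pooled over chains, shape (chains * S, dim)."""
        arr = self._array(quantity)
        return arr.reshape(-1, arr.shape[-1])

    def _array(self, quantity: str) -> np.ndarray:
        from .families import cell_mean_arrays

        if quantity in ("theta", "rho1", "rho2", "psi"):
            return getattr(self, quantity)
        if quantity == "cell_mean":
            # E[x] of the stochastic component per cell (no shift), the
            # quantity amalgamated in the frequency/length summaries.
            return np.asarray(
                cell_mean_arrays(0.0, self.rho1, self.rho2, self.family)
            )
        raise KeyError(f"unknown quantity {quantity!r}")

    def posterior_medians(self, quantity: str) -> pd.Series:
        """Per-unit posterior medians, chains pooled.

        Even draw counts use numpy's midpoint convention (mean of the two
        central order statistics).
        """
        med = np.median(self.stacked(quantity), axis=0)
        if quantity == "theta":
            return pd.Series(med, index=pd.Index(self.participant_ids, name="participant_id"))
        if quantity == "psi":
            return pd.Series(med, index=HyperParams.names(self.lengths))
        idx = pd.MultiIndex.from_frame(self.cell_index)
        return pd.Series(med, index=idx)

    def psi_draws(self, name: str) -> np.ndarray:
        names = HyperParams.names(self.lengths)
        return self.psi[..., names.index(name)]

    def to_inference_data(self, log_likelihood: np.ndarray | None = None):
        """Pack draws (and optionally a (chains, S, N) log-likelihood) for arviz."""
        import arviz as az

        posterior = {
            "theta": self.theta,
            "rho1": self.rho1,
            "rho2": self.rho2,
            "psi": self.psi,
        }
        kwargs = {}
        if log_likelihood is not None:
            kwargs["log_likelihood"] = {"rt": log_likelihood}
        return az.from_dict(posterior=posterior, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: one row per (chain, draw, quantity, unit)."""
        rows = []
        J = len(self.participant_ids)
        names = HyperParams.names(self.lengths)
        cell_labels = [
            f"{r.participant_id}|{r.band}|{r.length}" for r in self.cell_index.itertuples()
        ]
        for q, labels in (
            ("theta", [str(p) for p in self.participant_ids]),
            ("rho1", cell_labels),
            ("rho2", cell_labels),
            ("psi", names),
        ):
            arr = self._array(q)
            for ch in range(arr.shape[0]):
                df = pd.DataFrame(arr[ch], columns=labels)
                df.insert(0, "draw", np.arange(arr.shape[1]))
                df.insert(0, "chain", ch)
                long = df.melt(id_vars=["chain", "draw"], var_name="unit", value_name="value")
                long.insert(2, "quantity", q)
                rows.append(long)
        return pd.concat(rows, ignore_index=True)

    def save(self, path_csv, path_meta=None) -> None:
        import json
        from pathlib import Path

        self.to_frame().to_csv(path_csv, index=False)
        if path_meta is None:
            path_meta = Path(path_csv).with_suffix(".meta.json")
        meta = dict(self.metadata)
        meta.update(
            family=str(self.family.value),
            participant_ids=[str(p) for p in self.participant_ids],
            lengths=list(self.lengths),
        )
        Path(path_meta).write_text(json.dumps(meta, indent=2, default=float))


class StratifiedRTModel:
    """Hierarchical shifted-distribution model over a stratified RT dataset.

    Parameters
    ----------
    dataset
        A :class:`~sdart.preprocessing.StratifiedDataset` (or ``None`` for
        prior-only mode together with ``structure``).
    family
        ``"lognormal"``, ``"wald"`` or ``"gamma"``.
    prior
        A :class:`PriorConfig`; defaults to the diffuse Gamma(0.1, 0.1)
        pairs on every hyperparameter.
    structure
        Only for prior-only mode: ``(participant_ids, bands, lengths)``
        defining the cell grid when there are no trials.
    theta_by_band
        Accepted for forward compatibility (band-dependent shifts); only
        ``False`` is implemented.
    min_cell_size
        Cells with fewer trials are still modelled (the hierarchy shrinks
        them) but flagged in the fit metadata.
    """

    def __init__(
        self,
        dataset: StratifiedDataset | None,
        family: Family | str,
        prior: PriorConfig | None = None,
        structure: tuple | None = None,
        theta_by_band: bool = False,
        min_cell_size: int = 5,
    ) -> None:
        if theta_by_band:
            raise NotImplementedError("band-dependent shifts are a config hook only")
        self.family = Family.coerce(family)
        self.dataset = dataset
        self.min_cell_size = min_cell_size
        self._build_index(dataset, structure)
        self.prior = prior if prior is not None else PriorConfig.default(self.lengths)
        if tuple(self.prior.lengths) != self.lengths:
            raise ValueError("prior lengths do not match the dataset lengths")
        self._prior_a, self._prior_b = self.prior.vectors()

    # ------------------------------------------------------------------ #
    # construction
    # ------------------------------------------------------------------ #
    @classmethod
    def from_trials(
        cls,
        annotated: pd.DataFrame,
        band_spec,
        family,
        prior: PriorConfig | None = None,
        **kwargs,
    ) -> "StratifiedRTModel":
        from .preprocessing import stratify

        return cls(stratify(annotated, band_spec), family, prior=prior, **kwargs)

    def _build_index(self, dataset, structure) -> None:
        if dataset is not None and len(dataset.df):
            df = dataset.df
            self.participant_ids = sorted(df["participant_id"].unique().tolist())
            self.lengths = tuple(sorted(df["length"].unique().tolist()))
            cells = (
                df.groupby(["participant_id", "band", "length"], sort=True)
                .size()
                .reset_index(name="n")
            )
            self.cell_index = cells[["participant_id", "band", "length"]].copy()
            self._cell_n = cells["n"].to_numpy()
            key = list(zip(cells["participant_id"], cells["band"], cells["length"]))
            cell_pos = {k: i for i, k in enumerate(key)}
            part_pos = {p: i for i, p in enumerate(self.participant_ids)}
            self.y = df["rt"].to_numpy(dtype=float)
            self.trial_cell = np.array(
                [cell_pos[(p, b, l)] for p, b, l in zip(df["participant_id"], df["band"], df["length"])],
                dtype=np.int64,
            )
            self.trial_part = np.array(
                [part_pos[p] for p in df["participant_id"]], dtype=np.int64
            )
            self.cell_part = np.array([part_pos[k[0]] for k in key], dtype=np.int64)
            len_pos = {l: i for i, l in enumerate(self.lengths)}
            self.cell_len = np.array([len_pos[k[2]] for k in key], dtype=np.int64)
            self.min_rt = np.full(len(self.participant_ids), np.inf)
            np.minimum.at(self.min_rt, self.trial_part, self.y)
        else:
            if structure is None:
                raise ValueError("prior-only mode needs structure=(participants, bands, lengths)")
            pids, bands, lengths = structure
            self.participant_ids = list(pids)
            self.lengths = tuple(sorted(lengths))
            rows = [
                (p, k, l) for p in self.participant_ids for k in bands for l in self.lengths
            ]
            self.cell_index = pd.DataFrame(rows, columns=["participant_id", "band", "length"])
            self._cell_n = np.zeros(len(rows), dtype=int)
            part_pos = {p: i for i, p in enumerate(self.participant_ids)}
            len_pos = {l: i for i, l in enumerate(self.lengths)}
            self.y = np.empty(0)
            self.trial_cell = np.empty(0, dtype=np.int64)
            self.trial_part = np.empty(0, dtype=np.int64)
            self.cell_part = np.array([part_pos[r[0]] for r in rows], dtype=np.int64)
            self.cell_len = np.array([len_pos[r[2]] for r in rows], dtype=np.int64)
            self.min_rt = np.full(len(self.participant_ids), np.inf)
        self.n_trials = self.y.size
        self.n_cells = len(self.cell_index)
        self.n_participants = len(self.participant_ids)

    # ------------------------------------------------------------------ #
    # densities
    # ------------------------------------------------------------------ #
    def loglike_trials(self, theta, rho1, rho2) -> np.ndarray:
        """Per-trial shifted-family log-likelihood for one parameter state."""
        if self.n_trials == 0:
            return np.empty(0)
        return log_density_arrays(
            self.y,
            np.asarray(theta)[self.trial_part],
            np.asarray(rho1)[self.trial_cell],
            np.asarray(rho2)[self.trial_cell],
            self.family,
        )

    def log_joint(self, theta, rho1, rho2, psi: HyperParams) -> float:
        """Unnormalized log posterior density at one parameter state.

        Sum of the trial log-likelihood, the gamma priors of rho given the
        length-specific psi pairs, the gamma prior of theta, and the fixed
        gamma hyperpriors of psi.  ``-inf`` whenever a support constraint
        (positivity, theta below the participant's minimum RT) fails.
        """
        theta = np.asarray(theta, dtype=float)
        rho1 = np.asarray(rho1, dtype=float)
        rho2 = np.asarray(rho2, dtype=float)
        if theta.shape != (self.n_participants,) or rho1.shape != (self.n_cells,):
            raise ValueError("parameter arrays do not match the model's cell structure")
        if np.any(theta < 0) or np.any(theta >= self.min_rt) or np.any(rho1 <= 0) or np.any(rho2 <= 0):
            return -np.inf
        psi_vec = psi.to_vector()
        if np.any(psi_vec <= 0):
            return -np.inf
        ll = float(np.sum(self.loglike_trials(theta, rho1, rho2)))
        lp = float(
            np.sum(_gamma_logpdf(rho1, psi.alpha1[self.cell_len], psi.beta1[self.cell_len]))
            + np.sum(_gamma_logpdf(rho2, psi.alpha2[self.cell_len], psi.beta2[self.cell_len]))
            + np.sum(_gamma_logpdf(theta, psi.alpha_theta, psi.beta_theta))
            + np.sum(_gamma_logpdf(psi_vec, self._prior_a, self._prior_b))
        )
        return ll + lp

    # ------------------------------------------------------------------ #
    # fitting
    # ------------------------------------------------------------------ #
    def fit(
        self,
        draws: int = 1000,
        warmup: int = 1000,
        chains: int = 2,
        seed: int | None = None,
        thin: int = 1,
        fix_psi: HyperParams | None = None,
        rhat_warn: float = 1.01,
    ):
        """Sample the posterior and return an :class:`~sdart.results.SDAResults`.

        A fixed ``seed`` makes the draws reproducible.  Split-chain R-hat
        is computed for every scalar quantity; a warning is raised (and
        flagged in the metadata) if any exceeds ``rhat_warn``.
        ``fix_psi`` freezes the hyperparameters (used by low-dimensional
        oracle checks); otherwise psi is sampled.
        """
        if draws < 1 or warmup < 0 or chains < 1:
            raise ValueError("draws >= 1, warmup >= 0, chains >= 1 required")
        root = np.random.SeedSequence(seed)
        chain_seeds = root.spawn(chains)
        store = {
            "theta": np.empty((chains, draws, self.n_participants)),
            "rho1": np.empty((chains, draws, self.n_cells)),
            "rho2": np.empty((chains, draws, self.n_cells)),
            "psi": np.empty((chains, draws, 4 * len(self.lengths) + 2)),
        }
        accept = []
        for ch in range(chains):
            rng = np.random.default_rng(chain_seeds[ch])
            acc = self._run_chain(rng, draws, warmup, thin, fix_psi, store, ch)
            accept.append(acc)

        draws_obj = PosteriorDraws(
            family=self.family,
            participant_ids=self.participant_ids,
            cell_index=self.cell_index,
            lengths=self.lengths,
            theta=store["theta"],
            rho1=store["rho1"],
            rho2=store["rho2"],
            psi=store["psi"],
        )
        diag = self._diagnostics(draws_obj, rhat_warn)
        small = np.flatnonzero(self._cell_n < self.min_cell_size)
        draws_obj.metadata = {
            "seed": seed,
            "chains": chains,
            "warmup": warmup,
            "draws": draws,
            "thin": thin,
            "family": self.family.value,
            "acceptance": accept,
            "psi_fixed": fix_psi is not None,
            "small_cells": self.cell_index.iloc[small].to_dict("records"),
            "prior": {k: list(v) for k, v in self.prior.ab.items()},
            **diag,
        }
        from .results import SDAResults

        return SDAResults(self, draws_obj)

    def _diagnostics(self, draws_obj: PosteriorDraws, rhat_warn: float) -> dict:
        import arviz as az

        if draws_obj.n_chains * draws_obj.n_draws < 4:
            return {"rhat_max": np.nan, "ess_min": np.nan, "converged": None}
        idata = draws_obj.to_inference_data()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        rhat_max = float(max(float(rhat[v].max()) for v in rhat.data_vars))
        ess_min = float(min(float(ess[v].min()) for v in ess.data_vars))
        if draws_obj.metadata.get("psi_fixed"):
            pass
        converged = bool(rhat_max <= rhat_warn)
        if not converged:
            warnings.warn(
                f"split-chain R-hat up to {rhat_max:.3f} exceeds {rhat_warn}; "
                "draws returned anyway — consider more warmup/draws",
                RuntimeWarning,
                stacklevel=3,
            )
        return {"rhat_max": rhat_max, "ess_min": ess_min, "converged": converged}

    # ------------------------------------------------------------------ #
    # the Markov chain
    # ------------------------------------------------------------------ #
    def _init_state(self, rng, fix_psi):
        J, C, L = self.n_participants, self.n_cells, len(self.lengths)
        finite_min = np.where(np.isfinite(self.min_rt), self.min_rt, 400.0)
        theta = finite_min * rng.uniform(0.3, 0.8, size=J)

        if self.n_trials:
            d = self.y - theta[self.trial_part]
            n = np.bincount(self.trial_cell, minlength=C).astype(float)
            s1 = np.bincount(self.trial_cell, weights=d, minlength=C)
            m = s1 / np.maximum(n, 1.0)
            s2 = np.bincount(self.trial_cell, weights=d * d, minlength=C)
            v = s2 / np.maximum(n, 1.0) - m**2
            m = np.clip(m, 1.0, None)
            v = np.where((n > 1) & (v > 1e-8), v, (0.5 * m) ** 2)
            if self.family is Family.LOGNORMAL:
                r2 = np.log1p(v / m**2)
                r1 = np.log(m) - r2 / 2.0
            elif self.family is Family.WALD:
                r1, r2 = m, m**3 / v
            else:
                r1, r2 = m**2 / v, m / v
            jitter = lambda a: a * np.exp(0.05 * rng.standard_normal(a.shape))  # noqa: E731
            rho1 = np.clip(jitter(np.clip(r1, 1e-4, 1e7)), 1e-6, 1e8)
            rho2 = np.clip(jitter(np.clip(r2, 1e-6, 1e7)), 1e-8, 1e8)
        else:
            rho1 = np.clip(rng.gamma(2.0, 1.0, size=C), 1e-3, None)
            rho2 = np.clip(rng.gamma(2.0, 1.0, size=C), 1e-3, None)

        if fix_psi is not None:
            psi = fix_psi.to_vector()
        else:
            def mom_pair(vals):
                m_, v_ = float(np.mean(vals)), float(np.var(vals))
                if not np.isfinite(v_) or v_ < 1e-12:
                    v_ = max(0.25 * m_**2, 1e-6)
                return np.clip(m_**2 / v_, 1e-3, 1e6), np.clip(m_ / v_, 1e-8, 1e6)

            psi = np.empty(4 * L + 2)
            for li in range(L):
                sel = self.cell_len == li
                if sel.any():
                    psi[4 * li : 4 * li + 2] = mom_pair(rho1[sel])
                    psi[4 * li + 2 : 4 * li + 4] = mom_pair(rho2[sel])
                else:  # pragma: no cover - empty length never built
                    psi[4 * li : 4 * li + 4] = 1.0
            psi[-2:] = mom_pair(theta) if J > 1 else (2.0, 2.0 / max(theta[0], 1.0))
            psi *= np.exp(0.05 * rng.standard_normal(psi.shape))
        return theta, rho1, rho2, psi

    def _run_chain(self, rng, draws, warmup, thin, fix_psi, store, ch) -> dict:
        J, C, L = self.n_participants, self.n_cells, len(self.lengths)
        theta, rho1, rho2, psi = self._init_state(rng, fix_psi)
        lr1, lr2 = np.log(rho1), np.log(rho2)
        ll = self.loglike_trials(theta, rho1, rho2)
        if ll.size and not np.all(np.isfinite(ll)):
            # nudge theta below the offending trials
            bad = ~np.isfinite(ll)
            for j in np.unique(self.trial_part[bad]):
                theta[j] = 0.5 * self.min_rt[j]
            ll = self.loglike_trials(theta, rho1, rho2)
        step_theta = np.full(J, 5.0)
        step_shift = np.full(J, 10.0)
        # separately adapted scales: rho1 alone, rho2 alone, coupled move
        step_r1 = np.full(C, 0.05)
        step_r2 = np.full(C, 0.2)
        step_r12 = np.full(C, 0.1)
        step_shape = np.full(2 * L + 1, 0.3)  # alpha1/alpha2 per length + alpha_theta
        step_ridge = np.full(2 * L + 1, 0.3)  # coupled (alpha, beta) scale move
        acc_theta = np.zeros(J)
        acc_shift = np.zeros(J)
        acc_r1 = np.zeros(C)
        acc_r2 = np.zeros(C)
        acc_r12 = np.zeros(C)
        acc_shape = np.zeros(2 * L + 1)
        acc_ridge = np.zeros(2 * L + 1)
        tot_theta = tot_rho = tot_shape = 0
        # per-cell observed stats driving the shift-rescale remap
        if self.n_trials:
            nc = np.maximum(np.bincount(self.trial_cell, minlength=C).astype(float), 1.0)
            cell_ybar = np.bincount(self.trial_cell, weights=self.y, minlength=C) / nc
        else:
            cell_ybar = np.full(C, np.inf)
            nc = np.ones(C)

        cells_of_len = [np.flatnonzero(self.cell_len == li) for li in range(L)]
        a0, b0 = self._prior_a, self._prior_b
        n_iter = warmup + draws * thin
        kept = 0
        acc_theta_post = np.zeros(J)
        acc_shift_post = np.zeros(J)
        acc_rho_post = np.zeros(C)
        post_iters = 0

        for it in range(n_iter):
            in_warmup = it < warmup

            # --- theta block (per participant, natural-scale RW) -------- #
            prop = theta + step_theta * rng.standard_normal(J)
            valid = (prop > 0) & (prop < self.min_rt)
            if self.n_trials:
                ll_prop = self.loglike_trials(prop, rho1, rho2)
                delta = np.bincount(self.trial_part, weights=ll_prop - ll, minlength=J)
            else:
                ll_prop = ll
                delta = np.zeros(J)
            with np.errstate(divide="ignore", invalid="ignore"):
                dprior = (psi[-2] - 1.0) * (np.log(prop) - np.log(theta)) - psi[-1] * (
                    prop - theta
                )
            logacc = np.where(valid, delta + dprior, -np.inf)
            accept = np.log(rng.uniform(size=J)) < logacc
            if accept.any():
                theta = np.where(accept, prop, theta)
                if self.n_trials:
                    tm = accept[self.trial_part]
                    ll = np.where(tm, ll_prop, ll)
            acc_frac = accept.astype(float)
            acc_theta += acc_frac
            tot_theta += 1
            if not in_warmup:
                acc_theta_post += acc_frac

            # --- joint shift-rescale block ------------------------------- #
            # theta_j and the cell locations lie on a narrow ridge: raising
            # the shift must shrink the stochastic component.  Propose
            # theta_j' = theta_j + delta and remap every cell of the
            # participant by its maximum-likelihood response to the new
            # shift, computed from fixed observed cell statistics so the
            # remap is a deterministic diffeomorphism (Jacobian included;
            # reverse proposal is the exact inverse).  Lognormal cells
            # shift mu by the change in the cell's mean log-residual; Wald
            # and gamma cells rescale by the ratio of mean residuals.
            if self.n_trials:
                prop = theta + step_shift * rng.standard_normal(J)
                valid = (prop > 0) & (prop < self.min_rt)
                prop = np.where(valid, prop, theta)
                r1p, r2p, logJ_cell = self._shift_remap(theta, prop, rho1, rho2, nc, cell_ybar)
                ll_prop = self.loglike_trials(prop, r1p, r2p)
                delta = np.bincount(self.trial_part, weights=ll_prop - ll, minlength=J)
                a1 = psi[4 * self.cell_len + 0]
                b1 = psi[4 * self.cell_len + 1]
                a2 = psi[4 * self.cell_len + 2]
                b2 = psi[4 * self.cell_len + 3]
                with np.errstate(divide="ignore", invalid="ignore"):
                    dp_cell = (
                        _gamma_logpdf(r1p, a1, b1)
                        - _gamma_logpdf(rho1, a1, b1)
                        + _gamma_logpdf(r2p, a2, b2)
                        - _gamma_logpdf(rho2, a2, b2)
                        + logJ_cell
                    )
                    dp_cell = np.where(np.isnan(dp_cell), -np.inf, dp_cell)
                    dprior = np.bincount(self.cell_part, weights=dp_cell, minlength=J)
                    dprior += (psi[-2] - 1.0) * (np.log(prop) - np.log(theta)) - psi[-1] * (
                        prop - theta
                    )
                logacc = np.where(valid, delta + dprior, -np.inf)
                accept = np.log(rng.uniform(size=J)) < logacc
                if accept.any():
                    theta = np.where(accept, prop, theta)
                    cm = accept[self.cell_part]
                    rho1 = np.where(cm, r1p, rho1)
                    rho2 = np.where(cm, r2p, rho2)
                    lr1 = np.where(cm, np.log(rho1), lr1)
                    lr2 = np.where(cm, np.log(rho2), lr2)
                    tm = accept[self.trial_part]
                    ll = np.where(tm, ll_prop, ll)
                acc_shift += accept
                if not in_warmup:
                    acc_shift_post += accept

            # --- rho block (per cell, log-scale RW sub-moves) ------------- #
            # Three separately scaled moves: each component alone, then a
            # coupled move (same-sign for gamma/Wald, whose two parameters
            # ride a narrow ridge; independent for the lognormal).
            def rho_mh(p1, p2, acc_arr):
                nonlocal lr1, lr2, rho1, rho2, ll
                r1p, r2p = np.exp(p1), np.exp(p2)
                if self.n_trials:
                    ll_prop = self.loglike_trials(theta, r1p, r2p)
                    delta = np.bincount(self.trial_cell, weights=ll_prop - ll, minlength=C)
                else:
                    ll_prop = ll
                    delta = np.zeros(C)
                a1 = psi[4 * self.cell_len + 0]
                b1 = psi[4 * self.cell_len + 1]
                a2 = psi[4 * self.cell_len + 2]
                b2 = psi[4 * self.cell_len + 3]
                # gamma prior + log-scale Jacobian: a*log(rho) - b*rho
                dprior = (
                    a1 * (p1 - lr1)
                    - b1 * (r1p - rho1)
                    + a2 * (p2 - lr2)
                    - b2 * (r2p - rho2)
                )
                accept = np.log(rng.uniform(size=C)) < delta + dprior
                if accept.any():
                    lr1 = np.where(accept, p1, lr1)
                    lr2 = np.where(accept, p2, lr2)
                    rho1 = np.where(accept, r1p, rho1)
                    rho2 = np.where(accept, r2p, rho2)
                    if self.n_trials:
                        tm = accept[self.trial_cell]
                        ll = np.where(tm, ll_prop, ll)
                acc_arr += accept
                return accept

            rho_mh(lr1 + step_r1 * rng.standard_normal(C), lr2, acc_r1)
            rho_mh(lr1, lr2 + step_r2 * rng.standard_normal(C), acc_r2)
            if self.family is Family.LOGNORMAL:
                z1 = rng.standard_normal(C)
                z2 = rng.standard_normal(C)
            else:
                z1 = z2 = rng.standard_normal(C)
            accept = rho_mh(lr1 + step_r12 * z1, lr2 + step_r12 * z2, acc_r12)
            tot_rho += 1
            if not in_warmup:
                acc_rho_post += accept
                post_iters += 1

            # --- psi block (cheap: no trial likelihood) ------------------ #
            if fix_psi is None:
                for _ in range(2):
                    psi = self._update_psi(
                        rng, psi, theta, rho1, rho2, cells_of_len, a0, b0,
                        step_shape, acc_shape, step_ridge, acc_ridge,
                    )
                    tot_shape += 1

            # --- adaptation (warmup only) -------------------------------- #
            if in_warmup and (it + 1) % _ADAPT_BATCH == 0:
                step_theta *= np.exp(np.clip(acc_theta / tot_theta - _TARGET_1D, -0.5, 0.5))
                step_shift *= np.exp(np.clip(acc_shift / tot_theta - _TARGET_1D, -0.5, 0.5))
                step_r1 *= np.exp(np.clip(acc_r1 / tot_rho - _TARGET_1D, -0.5, 0.5))
                step_r2 *= np.exp(np.clip(acc_r2 / tot_rho - _TARGET_1D, -0.5, 0.5))
                step_r12 *= np.exp(np.clip(acc_r12 / tot_rho - _TARGET_2D, -0.5, 0.5))
                if fix_psi is None and tot_shape:
                    step_shape *= np.exp(
                        np.clip(acc_shape / tot_shape - _TARGET_1D, -0.5, 0.5)
                    )
                    step_ridge *= np.exp(
                        np.clip(acc_ridge / tot_shape - _TARGET_1D, -0.5, 0.5)
                    )
                acc_theta[:] = 0
                acc_shift[:] = 0
                acc_r1[:] = 0
                acc_r2[:] = 0
                acc_r12[:] = 0
                acc_shape[:] = 0
                acc_ridge[:] = 0
                tot_theta = tot_rho = tot_shape = 0

            if not in_warmup and (it - warmup + 1) % thin == 0:
                store["theta"][ch, kept] = theta
                store["rho1"][ch, kept] = rho1
                store["rho2"][ch, kept] = rho2
                store["psi"][ch, kept] = psi
                kept += 1

        denom = max(post_iters, 1)
        return {
            "theta": float(np.mean(acc_theta_post) / denom),
            "shift": float(np.mean(acc_shift_post) / denom),
            "rho": float(np.mean(acc_rho_post) / denom),
            "step_theta_mean": float(np.mean(step_theta)),
            "step_shift_mean": float(np.mean(step_shift)),
        }

    def _shift_remap(self, theta, prop, rho1, rho2, nc, cell_ybar):
        """Deterministic per-cell parameter response to a shift proposal.

        Maps each cell's (rho1, rho2) to the values that keep the cell's
        fit optimal when the participant shift moves from ``theta`` to
        ``prop``: for the lognormal, mu follows the cell's mean
        log-residual and sigma^2 the variance of the log-residuals; for
        the Wald, the mean follows the mean residual and the shape the
        inverse-residual statistic of its maximum-likelihood equation;
        for the gamma, the shape follows the log-moment gap
        ``log(mean d) - mean(log d)`` and the rate keeps the cell mean.
        Everything is a function of observed data and (theta, prop) only,
        so the remap is an exact diffeomorphism; returns the proposed
        (rho1, rho2) and the per-cell log-Jacobian.
        """
        C = self.n_cells
        d0 = self.y - theta[self.trial_part]
        d1 = self.y - prop[self.trial_part]
        if self.family is Family.LOGNORMAL:
            ld0, ld1 = np.log(d0), np.log(d1)
            m0 = np.bincount(self.trial_cell, weights=ld0, minlength=C) / nc
            m1 = np.bincount(self.trial_cell, weights=ld1, minlength=C) / nc
            v0 = np.bincount(self.trial_cell, weights=ld0**2, minlength=C) / nc - m0**2
            v1 = np.bincount(self.trial_cell, weights=ld1**2, minlength=C) / nc - m1**2
            k = np.where((nc > 1) & (v0 > 1e-12) & (v1 > 1e-12), v1 / v0, 1.0)
            return rho1 + (m1 - m0), rho2 * k, np.log(k)
        mb0 = cell_ybar - theta[self.cell_part]
        mb1 = cell_ybar - prop[self.cell_part]
        c = mb1 / mb0
        if self.family is Family.WALD:
            i0 = np.bincount(self.trial_cell, weights=1.0 / d0, minlength=C) / nc
            i1 = np.bincount(self.trial_cell, weights=1.0 / d1, minlength=C) / nc
            g0, g1 = i0 - 1.0 / mb0, i1 - 1.0 / mb1
            k = np.where((nc > 1) & (g0 > 1e-14) & (g1 > 1e-14), g0 / g1, c)
            return rho1 * c, rho2 * k, np.log(c) + np.log(k)
        # gamma: shape tracks the log-moment gap, rate keeps the cell mean
        ml0 = np.bincount(self.trial_cell, weights=np.log(d0), minlength=C) / nc
        ml1 = np.bincount(self.trial_cell, weights=np.log(d1), minlength=C) / nc
        s0, s1 = np.log(mb0) - ml0, np.log(mb1) - ml1
        ka = np.where((nc > 1) & (s0 > 1e-14) & (s1 > 1e-14), s0 / s1, 1.0)
        kb = ka / c
        return rho1 * ka, rho2 * kb, np.log(ka) + np.log(kb)

    def _update_psi(
        self, rng, psi, theta, rho1, rho2, cells_of_len, a0, b0, step, acc, step_ridge, acc_ridge
    ):
        """Gibbs/MH sweep over the hyperparameters.

        Rates (beta entries) are conjugate given the shapes: with n gamma
        observations summing to S, beta | alpha ~ Gamma(a0 + n*alpha,
        b0 + S).  Shapes (alpha entries) take a log-scale random walk on
        their conditional.
        """
        psi = psi.copy()
        L = len(self.lengths)

        def shape_update(idx_a, idx_b, vals, slot):
            n = vals.size
            if n == 0:
                # no data for this block: sample from the hyperprior
                psi[idx_a] = rng.gamma(a0[idx_a], 1.0 / b0[idx_a])
                psi[idx_b] = rng.gamma(a0[idx_b], 1.0 / b0[idx_b])
                return
            S, SL = float(np.sum(vals)), float(np.sum(np.log(vals)))
            # conjugate rate draw
            psi[idx_b] = rng.gamma(a0[idx_b] + n * psi[idx_a], 1.0 / (b0[idx_b] + S))
            # log-scale MH for the shape
            a_cur = psi[idx_a]
            a_new = a_cur * np.exp(step[slot] * rng.standard_normal())

            def cond(a):
                return (
                    n * (a * np.log(psi[idx_b]) - special.gammaln(a))
                    + a * SL
                    + a0[idx_a] * np.log(a)
                    - b0[idx_a] * a
                )

            if np.log(rng.uniform()) < cond(a_new) - cond(a_cur):
                psi[idx_a] = a_new
                acc[slot] += 1

            # coupled ridge move: (alpha, beta) -> (alpha, beta) * e^eps
            # keeps the prior mean alpha/beta fixed, which is the narrow
            # direction the one-at-a-time updates cannot travel along.
            a_c, b_c = psi[idx_a], psi[idx_b]
            eps = step_ridge[slot] * rng.standard_normal()
            a_n, b_n = a_c * np.exp(eps), b_c * np.exp(eps)

            def joint(a, b):
                return (
                    n * (a * np.log(b) - special.gammaln(a))
                    + a * SL
                    - b * S
                    + (a0[idx_a] - 1.0) * np.log(a)
                    - b0[idx_a] * a
                    + (a0[idx_b] - 1.0) * np.log(b)
                    - b0[idx_b] * b
                )

            if np.log(rng.uniform()) < joint(a_n, b_n) - joint(a_c, b_c) + 2.0 * eps:
                psi[idx_a], psi[idx_b] = a_n, b_n
                acc_ridge[slot] += 1

        for li in range(L):
            sel = cells_of_len[li]
            shape_update(4 * li + 0, 4 * li + 1, rho1[sel], 2 * li)
            shape_update(4 * li + 2, 4 * li + 3, rho2[sel], 2 * li + 1)
        shape_update(4 * L, 4 * L + 1, np.asarray(theta), 2 * L)
        return psi
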