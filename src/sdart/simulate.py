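"""Synthetic lexicons and trial archives with known ground truth.

The generator emulates the structure of lexical-decision megastudy data:
a lexicon of words (4-10 characters) whose occurrence values follow a
Zipf law, with three rank-correlated occurrence measures (word-form
frequency WF and two contextual-diversity measures DCD/UCD), and
trial-level RT tables produced by the exact generative model the package
fits — participant shifts ``theta_j*`` drawn from a gamma distribution,
cell parameters ``rho_jkl*`` drawn from length-specific gamma priors at a
known ``psi*``, and RTs from the chosen shifted family.  Every trial's
generating (participant, band, length) cell is recorded, so preprocessing
and model recovery can be verified end to end.

The default design is a desk-scale version of the megastudy conditions:
20 participants x 4 frequency bands x 3 word lengths x 50 trials per cell
(12,000 word trials), lognormal stochastic component with a median around
245 ms, shifts averaging 250 ms — comparable to observed lexical-decision
RTs — sized so that a full fit-and-assess cycle runs in minutes.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .families import Family, sample_arrays
from .model import HyperParams
from .preprocessing import BandSpec

__all__ = [
    "SimDesign",
    "SimTruth",
    "default_true_psi",
    "gen_lexicon",
    "gen_trials",
    "gen_contaminated",
    "expected_exclusions",
    "write_trials",
    "write_archive",
    "write_lexicon",
]

MEASURES = ("WF", "DCD", "UCD")


def default_true_psi(family: Family | str, lengths) -> HyperParams:
    """Ground-truth hyperparameters giving realistic lexical-decision RTs.

    Cell means sit near 250-350 ms of stochastic time on top of a ~250 ms
    shift, with a mild increase over word length; spreads across cells
    match the between-participant variation seen in megastudy fits.
    """
    family = Family.coerce(family)
    lengths = tuple(sorted(lengths))
    L = len(lengths)
    off = np.array(lengths, dtype=float) - lengths[0]

    def pair(mean, sd):
        mean, sd = np.broadcast_arrays(np.asarray(mean, float), np.asarray(sd, float))
        a = (mean / sd) ** 2
        return a, a / mean

    if family is Family.LOGNORMAL:
        a1, b1 = pair(5.45 + 0.03 * off, 0.25)  # mu: median x ~ 233-248 ms
        a2, b2 = pair(np.full(L, 0.16), 0.05)  # sigma^2
    elif family is Family.WALD:
        a1, b1 = pair(300.0 * (1.0 + 0.04 * off), 55.0)  # mean of x, ms
        a2, b2 = pair(np.full(L, 2700.0), 800.0)  # shape lambda, ms
    else:
        a1, b1 = pair(np.full(L, 4.0), 0.9)  # gamma shape
        a2, b2 = pair(0.0140 / (1.0 + 0.04 * off), 0.0035)  # gamma rate, 1/ms
    return HyperParams(
        lengths=lengths,
        alpha1=a1,
        beta1=b1,
        alpha2=a2,
        beta2=b2,
        alpha_theta=25.0,  # theta ~ Gamma(25, 0.1): mean 250 ms, sd 50 ms
        beta_theta=0.1,
    )


@dataclass(frozen=True)
class SimDesign:
    """Design of one synthetic dataset; the seed fixes every random choice."""

    n_participants: int = 20
    lengths: tuple[int, ...] = (4, 5, 6)
    n_words_per_length: int = 40
    zipf_exponent: float = 1.0
    family: str = "lognormal"
    n_bands: int = 4
    trials_per_cell: int = 50
    accuracy_rate: float = 0.95
    nonword_frac: float = 0.0
    rank_corr: float = 0.9
    band_gradient: float = 0.0  # relative drop of the cell mean, band 1 -> K
    theta_fixed: float | None = None
    measure: str = "WF"
    true_psi: HyperParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_words_per_length < 1 or self.trials_per_cell < 1:
            raise ValueError("all counts must be >= 1")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if not set(self.lengths) <= set(range(4, 11)):
            raise ValueError("lengths must be within 4..10")
        if not (0.0 <= self.nonword_frac < 1.0):
            raise ValueError("nonword_frac must be in [0, 1)")

    def resolved_psi(self) -> HyperParams:
        return self.true_psi or default_true_psi(self.family, self.lengths)


@dataclass
class SimTruth:
    """Everything needed to map generated trials back to their source."""

    design: SimDesign
    psi: HyperParams
    theta: pd.Series  # true shift per participant
    rho: pd.DataFrame  # participant_id, band, length, rho1, rho2
    band_spec: BandSpec
    lexicon: pd.DataFrame
    trial_cells: pd.DataFrame  # per generated word trial: participant_id, band, length


def _random_words(rng: np.random.Generator, length: int, n: int, prefix: str = "") -> list[str]:
    letters = np.array(list(string.ascii_lowercase))
    words: set[str] = set()
    body = length - len(prefix)
    while len(words) < n:
        w = prefix + "".join(rng.choice(letters, size=body))
        words.add(w)
    return sorted(words)


def gen_lexicon(design: SimDesign, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Zipf-distributed lexicon with three rank-correlated occurrence measures.

    Occurrence values follow ``value = C / rank^s`` over a random
    rank-to-word assignment; DCD and UCD are generated from WF through a
    Gaussian copula with rank correlation ``design.rank_corr`` (1.0 means
    identical ranks).
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence((design.seed, 1)))
    words, lens = [], []
    for l in design.lengths:
        ws = _random_words(rng, l, design.n_words_per_length)
        words += ws
        lens += [l] * len(ws)
    n = len(words)
    ranks = rng.permutation(n) + 1
    wf = 1e6 / ranks.astype(float) ** design.zipf_exponent

    logwf = np.log(wf)
    z = (logwf - logwf.mean()) / logwf.std()
    out = pd.DataFrame({"word": words, "length": lens, "pos": "Noun"})
    r = design.rank_corr
    for m, sub in zip(("DCD", "UCD"), (2, 3)):
        mrng = np.random.default_rng(np.random.SeedSequence((design.seed, sub)))
        eps = mrng.standard_normal(n)
        zm = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * eps
        out[m] = np.exp(logwf.mean() + logwf.std() * zm)
    out.insert(3, "WF", wf)
    return out


def _band_words(lexicon: pd.DataFrame, design: SimDesign, rng) -> tuple[BandSpec, pd.Series]:
    """Assign every word to a frequency band; all (band, length) groups occupied."""
    K = design.n_bands
    values = lexicon[design.measure].to_numpy(dtype=float)
    if K == 1:
        spec = BandSpec(measure=design.measure, boundaries=(), k=1, min_count=1)
        return spec, pd.Series(1, index=lexicon.index)
    bounds = tuple(np.quantile(values, np.arange(1, K) / K).tolist())
    spec = BandSpec(measure=design.measure, boundaries=bounds, k=K, min_count=1)
    bands = pd.Series(spec.assign(values), index=lexicon.index)
    occupancy = (
        pd.DataFrame({"band": bands, "length": lexicon["length"]})
        .groupby(["band", "length"])
        .size()
    )
    if len(occupancy) != K * len(design.lengths):
        raise ValueError(
            "empty (band, length) group; increase n_words_per_length or lower n_bands"
        )
    return spec, bands


def gen_trials(
    design: SimDesign, lexicon: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a trial table from the hierarchical model at known truth.

    ``theta_j*`` are drawn from the psi* shift prior (or fixed at
    ``design.theta_fixed``), each cell's ``rho_jkl*`` from the
    length-specific gamma priors, and RTs from the shifted family.
    Accuracy flags are Bernoulli at ``design.accuracy_rate``; an optional
    share of nonword filler trials exercises preprocessing.  Fully
    reproducible from the design's seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 0)))
    psi = design.resolved_psi()
    family = Family.coerce(design.family)
    if lexicon is None:
        lexicon = gen_lexicon(design)
    band_spec, word_band = _band_words(lexicon, design, rng)

    pids = [f"P{j:03d}" for j in range(1, design.n_participants + 1)]
    if design.theta_fixed is not None:
        theta = np.full(len(pids), float(design.theta_fixed))
    else:
        theta = rng.gamma(psi.alpha_theta, 1.0 / psi.beta_theta, size=len(pids))

    lengths = design.lengths
    len_pos = {l: i for i, l in enumerate(lengths)}
    groups = {
        (int(k), int(l)): lexicon.loc[idx, "word"].to_numpy()
        for (k, l), idx in pd.DataFrame(
            {"band": word_band, "length": lexicon["length"]}
        ).groupby(["band", "length"]).groups.items()
    }

    K = design.n_bands
    grad = np.ones(K)
    if K > 1 and design.band_gradient:
        grad = 1.0 - design.band_gradient * (np.arange(K) / (K - 1))

    rows_rho = []
    rec_pid, rec_item, rec_rt, rec_band, rec_len = [], [], [], [], []
    for j, pid in enumerate(pids):
        for k in range(1, K + 1):
            for l in lengths:
                li = len_pos[l]
                r1 = rng.gamma(psi.alpha1[li], 1.0 / psi.beta1[li])
                r2 = rng.gamma(psi.alpha2[li], 1.0 / psi.beta2[li])
                m = grad[k - 1]
                if m != 1.0:
                    if family is Family.LOGNORMAL:
                        r1 = r1 + np.log(m)
                    elif family is Family.WALD:
                        r1 = r1 * m
                    else:
                        r2 = r2 / m
                rows_rho.append((pid, k, l, r1, r2))
                n = design.trials_per_cell
                items = rng.choice(groups[(k, l)], size=n)
                rts = sample_arrays(rng, theta[j], r1, r2, family, size=n)
                rec_pid += [pid] * n
                rec_item += list(items)
                rec_rt += list(rts)
                rec_band += [k] * n
                rec_len += [l] * n

    n_word = len(rec_rt)
    trials = pd.DataFrame(
        {
            "participant_id": rec_pid,
            "item": rec_item,
            "rt": np.asarray(rec_rt, dtype=float),
            "accuracy": rng.binomial(1, design.accuracy_rate, size=n_word),
            "is_word": 1,
        }
    )
    trial_cells = pd.DataFrame(
        {"participant_id": rec_pid, "band": rec_band, "length": rec_len}
    )

    if design.nonword_frac > 0:
        f = design.nonword_frac
        n_nw_total = int(round(n_word * f / (1.0 - f)))
        per_p = n_nw_total // len(pids)
        nw_rows = []
        nw_words = _random_words(rng, max(lengths), per_p or 1, prefix="x")
        for j, pid in enumerate(pids):
            rts = theta[j] + rng.lognormal(5.6, 0.4, size=per_p)
            for i in range(per_p):
                nw_rows.append((pid, nw_words[i % len(nw_words)], rts[i]))
        if nw_rows:
            nw = pd.DataFrame(nw_rows, columns=["participant_id", "item", "rt"])
            nw["accuracy"] = rng.binomial(1, design.accuracy_rate, size=len(nw))
            nw["is_word"] = 0
            trials = pd.concat([trials, nw], ignore_index=True)

    truth = SimTruth(
        design=design,
        psi=psi,
        theta=pd.Series(theta, index=pd.Index(pids, name="participant_id")),
        rho=pd.DataFrame(rows_rho, columns=["participant_id", "band", "length", "rho1", "rho2"]),
        band_spec=band_spec,
        lexicon=lexicon,
        trial_cells=trial_cells,
    )
    return trials, truth


def gen_contaminated(
    design: SimDesign,
    fast_frac: float,
    slow_frac: float,
    n_low_accuracy: int = 0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Trials with predictable preprocessing exclusions injected.

    Exactly ``round(fast_frac * n)`` RTs per participant are replaced by
    values below 150 ms and ``round(slow_frac * n)`` by values above
    2000 ms; the first ``n_low_accuracy`` participants get exactly half
    their accuracy flags set to 0 (accuracy 0.5 < the 60% rule).  Returns
    the trials and the analytically expected exclusion report.
    """
    if not (0.0 <= fast_frac < 1.0 and 0.0 <= slow_frac < 1.0 and fast_frac + slow_frac < 1.0):
        raise ValueError("fractions must lie in [0, 1) and sum below 1")
    trials, _ = gen_trials(design)
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 9)))
    trials = trials.copy()
    # keep clean RTs inside the window so injected counts are exact
    trials["rt"] = trials["rt"].clip(150.0, 2000.0)
    pids = sorted(trials["participant_id"].unique().tolist())
    expected: list[dict] = []
    low_acc = set(pids[:n_low_accuracy])
    for pid in pids:
        idx = trials.index[trials["participant_id"] == pid]
        n = len(idx)
        if pid in low_acc:
            # exactly ceil(n/2) zeros -> accuracy <= 0.5 < 0.6
            k = n - n // 2
            trials.loc[idx[:k], "accuracy"] = 0
            trials.loc[idx[k:], "accuracy"] = 1
            expected.append({"participant_id": pid, "reason": "accuracy"})
            continue
        trials.loc[idx, "accuracy"] = 1
        n_fast = int(round(fast_frac * n))
        n_slow = int(round(slow_frac * n))
        if n_fast:
            trials.loc[idx[:n_fast], "rt"] = rng.uniform(50.0, 149.0, size=n_fast)
        if n_slow:
            trials.loc[idx[n_fast : n_fast + n_slow], "rt"] = rng.uniform(
                2001.0, 3000.0, size=n_slow
            )
        if (n_fast + n_slow) / n > 0.20:
            expected.append({"participant_id": pid, "reason": "rt_window"})
    return trials, expected


def expected_exclusions(design: SimDesign, fast_frac: float, slow_frac: float, n_low_accuracy: int = 0) -> int:
    """Analytic exclusion count for :func:`gen_contaminated` output under
    the 60% / 150-2000 ms / 20% rules."""
    n = design.n_bands * len(design.lengths) * design.trials_per_cell
    if design.nonword_frac > 0:
        total_nw = int(
            round(
                n * design.n_participants * design.nonword_frac / (1 - design.nonword_frac)
            )
        )
        n += total_nw // design.n_participants
    n_out = int(round(fast_frac * n)) + int(round(slow_frac * n))
    rest = design.n_participants - n_low_accuracy
    return n_low_accuracy + (rest if n_out / n > 0.20 else 0)


# ---------------------------------------------------------------------- #
# writers (round-trip with preprocessing.load_trials)
# ---------------------------------------------------------------------- #
def write_trials(trials: pd.DataFrame, path) -> None:
    """Write one combined trial table in the package's own dialect."""
    cols = ["participant_id", "item", "rt", "accuracy", "is_word"]
    trials[cols].to_csv(path, index=False)


def write_archive(trials: pd.DataFrame, directory, suffix: str = ".csv") -> list[str]:
    """Write one file per participant (megastudy-archive layout)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for pid, g in trials.groupby("participant_id", sort=True):
        name = f"{pid}{suffix}"
        write_trials(g, directory / name)
        names.append(name)
    return names


def write_lexicon(lexicon: pd.DataFrame, path) -> None:
    lexicon[["word", "length", "pos", "WF", "DCD", "UCD"]].to_csv(path, index=False)
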