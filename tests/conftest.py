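import warnings

import pytest

from sdart import SimDesign, StratifiedRTModel, gen_trials, merge_lexicon, stratify

warnings.filterwarnings("ignore", message=".*ArviZ.*")


def dataset_from_truth(trials, truth, measure="WF"):
    """Stratify generated trials using the generator's own band spec."""
    ann = merge_lexicon(
        trials, truth.lexicon, measure=measure, lengths=truth.design.lengths
    )
    return stratify(ann, truth.band_spec)


@pytest.fixture(scope="session")
def small_sim():
    """Desk-top instance: 6 participants x 2 bands x 2 lengths x 25 trials."""
    design = SimDesign(
        n_participants=6, lengths=(4, 5), n_bands=2, trials_per_cell=25, seed=42
    )
    trials, truth = gen_trials(design)
    return design, trials, truth, dataset_from_truth(trials, truth)


@pytest.fixture(scope="session")
def small_fit(small_sim):
    _, _, _, ds = small_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return StratifiedRTModel(ds, "lognormal").fit(
            draws=400, warmup=600, chains=2, seed=7
        )


@pytest.fixture(scope="session")
def toy_quadrature():
    """Gamma toy instance (1 participant, 2 cells, 20 trials): dense-grid
    oracle moments plus a long posterior run with fixed hyperparameters."""
    import numpy as np
    import pandas as pd

    from sdart import HyperParams
    from sdart.preprocessing import BandSpec, StratifiedDataset

    from oracles import gamma_toy_posterior_moments

    rng = np.random.default_rng(42)
    y1 = 200.0 + rng.gamma(4.0, 1 / 0.02, 10)
    y2 = 200.0 + rng.gamma(4.0, 1 / 0.02, 10)
    oracle = gamma_toy_posterior_moments([y1, y2])
    df = pd.DataFrame(
        {
            "participant_id": "P1",
            "item": "w",
            "rt": np.r_[y1, y2],
            "freq": 1.0,
            "length": np.r_[[4] * 10, [5] * 10],
            "band": 1,
        }
    )
    ds = StratifiedDataset(
        df=df, band_spec=BandSpec(measure="WF", boundaries=(), k=1, min_count=1), lengths=(4, 5)
    )
    psi = HyperParams((4, 5), [4.0, 4.0], [1.0, 1.0], [2.0, 2.0], [100.0, 100.0], 10.0, 0.05)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = StratifiedRTModel(ds, "gamma").fit(
            draws=4000, warmup=2000, chains=4, seed=3, fix_psi=psi
        )
    return oracle, res


@pytest.fixture(scope="session")
def recovery_fit():
    """The full recovery-scale run: 20 x 4 x 3 x 50, generating family fitted."""
    design = SimDesign(seed=11)
    trials, truth = gen_trials(design)
    ds = dataset_from_truth(trials, truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = StratifiedRTModel(ds, design.family).fit(
            draws=1250, warmup=1500, chains=2, seed=5
        )
    return design, truth, ds, res
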