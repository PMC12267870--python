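"""Trial filtering, lexicon merging, quantile banding and stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sdart import (
    SimDesign,
    filter_participants,
    gen_trials,
    load_trials,
    make_frequency_bands,
    merge_lexicon,
    stratify,
)
from sdart.preprocessing import BandSpec
from sdart.simulate import write_archive, write_trials

from conftest import dataset_from_truth


# ---------------------------------------------------------------------- #
# loading
# ---------------------------------------------------------------------- #
def _write(path, text):
    path.write_text(text)
    return path


def test_load_trials_skips_excluded_files(tmp_path):
    header = "participant_id,item,rt,accuracy,is_word\n"
    for name in ("a.csv", "b.csv", "9999.LDT"):
        _write(tmp_path / name, header + f"{name},word,500,1,1\n")
    df = load_trials(tmp_path, exclude_files=["9999.LDT"])
    assert sorted(df["source_file"].unique()) == ["a.csv", "b.csv"]
    assert len(df) == 2


def test_load_trials_drops_malformed_rows(tmp_path):
    rows = ["P1,word%d,%d,1,1" % (i, 400 + i) for i in range(9)]
    rows.insert(4, "P1,badword,not_a_number,1,1")  # malformed RT
    f = _write(tmp_path / "p1.csv", "participant_id,item,rt,accuracy,is_word\n" + "\n".join(rows) + "\n")
    df = load_trials(f)
    assert len(df) == 9
    assert df.attrs["n_malformed"] == 1


def test_load_trials_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_trials(tmp_path / "missing.csv")
    f = _write(tmp_path / "empty.csv", "participant_id,item,rt,accuracy,is_word\n")
    with pytest.raises(ValueError):
        load_trials(f)


def test_load_trials_counts_generator_output(tmp_path):
    design = SimDesign(n_participants=3, lengths=(4,), n_bands=2, trials_per_cell=10, seed=1)
    trials, _ = gen_trials(design)
    write_trials(trials, tmp_path / "t.csv")
    df = load_trials(tmp_path / "t.csv")
    assert len(df) == len(trials)
    names = write_archive(trials, tmp_path / "arch")
    assert len(names) == 3
    df2 = load_trials(tmp_path / "arch")
    assert len(df2) == len(trials)


# ---------------------------------------------------------------------- #
# participant filters
# ---------------------------------------------------------------------- #
def _participant(pid, n, acc=1.0, out_frac=0.0):
    n_bad = int(round(n * (1 - acc)))
    n_out = int(round(n * out_frac))
    return pd.DataFrame(
        {
            "participant_id": pid,
            "item": "w",
            "rt": [2500.0] * n_out + [500.0] * (n - n_out),
            "accuracy": [0] * n_bad + [1] * (n - n_bad),
            "is_word": 1,
        }
    )


def test_accuracy_rule_boundary_inclusive():
    """Accuracy exactly at 60% is retained; below is excluded."""
    trials = pd.concat(
        [_participant("lo", 100, acc=0.50), _participant("edge", 100, acc=0.60), _participant("hi", 100, acc=0.9)]
    )
    kept, report = filter_participants(trials)
    assert {r["participant_id"] for r in report} == {"lo"}
    assert report[0]["reason"] == "accuracy"
    assert set(kept["participant_id"]) == {"edge", "hi"}


def test_rt_window_rule_boundary_strict():
    """Out-of-window share exactly at 20% is retained; above is excluded."""
    trials = pd.concat(
        [_participant("edge", 100, out_frac=0.20), _participant("bad", 100, out_frac=0.25)]
    )
    kept, report = filter_participants(trials)
    assert [r["participant_id"] for r in report] == ["bad"]
    assert report[0]["reason"] == "rt_window"
    assert set(kept["participant_id"]) == {"edge"}
    # out-of-window trials of retained participants are kept, not trimmed
    assert (kept.loc[kept["participant_id"] == "edge", "rt"] > 2000).sum() == 20


def test_filter_order_and_idempotence():
    trials = pd.concat(
        [
            _participant("acc_and_rt", 100, acc=0.4, out_frac=0.5),  # accuracy fires first
            _participant("ok", 100),
        ]
    )
    kept, report = filter_participants(trials)
    assert [r["reason"] for r in report] == ["accuracy"]
    kept2, report2 = filter_participants(kept)
    assert report2 == []
    pd.testing.assert_frame_equal(kept.reset_index(drop=True), kept2)


# ---------------------------------------------------------------------- #
# lexicon merge
# ---------------------------------------------------------------------- #
def test_merge_lexicon_filters():
    trials = pd.DataFrame(
        {
            "participant_id": "P1",
            "item": ["cat", "door", "minorpos", "unknown", "nonw"],
            "rt": 500.0,
            "accuracy": 1,
            "is_word": [1, 1, 1, 1, 0],
        }
    )
    lexicon = pd.DataFrame(
        {
            "word": ["cat", "door", "minorpos"],
            "length": [3, 4, 8],
            "pos": ["Noun", "Noun", "minor"],
            "WF": [10.0, 5.0, 2.0],
        }
    )
    ann = merge_lexicon(trials, lexicon, measure="WF", pos_exclude=["minor"])
    # 3-char word out of range, excluded POS dropped, unknown word dropped,
    # nonword dropped -> only "door" survives
    assert ann["item"].tolist() == ["door"]
    assert ann["length"].tolist() == [4]
    with pytest.raises(KeyError):
        merge_lexicon(trials, lexicon, measure="nope")


# ---------------------------------------------------------------------- #
# frequency banding
# ---------------------------------------------------------------------- #
def _annotated(values):
    df = pd.DataFrame(
        {"participant_id": "P1", "item": "w", "rt": 500.0, "freq": values, "length": 4}
    )
    df.attrs["measure"] = "WF"
    return df


def test_banding_distinct_values_exact_quartiles():
    """100 distinct occurrence values, floor 25 -> 4 bands of exactly 25."""
    ann = _annotated(np.arange(1.0, 101.0))
    spec = make_frequency_bands(ann, "WF", min_count=25)
    assert spec.k == 4
    bands = spec.assign(ann["freq"])
    assert np.bincount(bands)[1:].tolist() == [25, 25, 25, 25]


def test_banding_all_tied_collapses():
    ann = _annotated(np.full(200, 7.0))
    spec = make_frequency_bands(ann, "WF", min_count=10)
    assert spec.k == 1


def test_banding_floor_above_total_single_band():
    ann = _annotated(np.arange(50.0))
    spec = make_frequency_bands(ann, "WF", min_count=100)
    assert spec.k == 1


def test_banding_brute_force_choice():
    """k is the largest band count keeping every band at the floor."""
    values = np.r_[np.full(60, 1.0), np.arange(2.0, 42.0)]  # heavy tie at 1
    ann = _annotated(values)
    min_count = 20
    spec = make_frequency_bands(ann, "WF", min_count=min_count)

    def feasible(k):
        if k == 1:
            return True
        qs = np.quantile(values, np.arange(1, k) / k)
        if len(set(qs.tolist())) != k - 1:
            return False
        b = np.searchsorted(np.asarray(sorted(set(qs.tolist()))), values, side="left")
        counts = np.bincount(b, minlength=k)
        return counts.min() >= min_count

    best = max(k for k in range(1, len(values) // min_count + 1) if feasible(k))
    assert spec.k == best
    counts = np.bincount(spec.assign(values))[1:]
    assert counts.min() >= min_count and counts.sum() == len(values)


@settings(max_examples=40, derandomize=True)
@given(
    values=st.lists(st.sampled_from([1.0, 2.0, 5.0, 5.0, 9.0, 20.0, 20.0, 50.0]), min_size=30, max_size=120),
    min_count=st.integers(5, 30),
)
def test_banding_is_partition_and_tie_safe(values, min_count):
    ann = _annotated(np.array(values))
    spec = make_frequency_bands(ann, "WF", min_count=min_count)
    bands = spec.assign(values)
    assert bands.min() >= 1 and bands.max() <= spec.k
    # the band map is a function of the occurrence value
    mapping = {}
    for v, b in zip(values, bands):
        assert mapping.setdefault(v, b) == b
    if spec.k > 1:
        assert np.bincount(bands)[1:].min() >= min_count


# ---------------------------------------------------------------------- #
# stratification
# ---------------------------------------------------------------------- #
def test_stratify_partitions_trials(small_sim):
    _, _, truth, ds = small_sim
    sizes = ds.cell_sizes()
    assert sizes.sum() == ds.n_trials
    # generator bookkeeping: every cell holds exactly the designed trials
    assert (sizes == truth.design.trials_per_cell).all()
    assert len(sizes) == 6 * 2 * 2


def test_stratify_single_trial():
    ann = pd.DataFrame(
        {"participant_id": ["P1"], "item": ["wxyz"], "rt": [432.0], "freq": [3.0], "length": [4]}
    )
    spec = BandSpec(measure="WF", boundaries=(), k=1, min_count=1)
    ds = stratify(ann, spec)
    assert ds.n_trials == 1
    assert list(ds.cells()) == [("P1", 1, 4)]


def test_stratification_matches_generator_cells():
    design = SimDesign(n_participants=3, lengths=(4, 6), n_bands=3, trials_per_cell=8, seed=9)
    trials, truth = gen_trials(design)
    ds = dataset_from_truth(trials, truth)
    got = ds.df[["participant_id", "band", "length"]].reset_index(drop=True)
    pd.testing.assert_frame_equal(got, truth.trial_cells.astype(got.dtypes.to_dict()))
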