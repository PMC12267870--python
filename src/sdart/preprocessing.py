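"""Trial-level preprocessing for lexical-decision megastudy archives.

The pipeline mirrors the standard preparation of single-trial RT archives
(ELP/BLP style): read per-participant trial files, drop known-bad files,
exclude participants by accuracy and by the share of implausibly fast/slow
responses, merge word trials with a lexicon carrying occurrence measures
(word-form frequency WF, discourse/user contextual diversity DCD/UCD),
restrict to 4-10 character words outside excluded part-of-speech classes,
band the occurrence values by quantiles, and stratify retained trials into
(participant, frequency band, word length) cells.

Filter order matters and is preserved: the accuracy rule runs on the raw
archive (words and nonwords), the RT-window rule runs on its survivors, and
only then are nonword trials discarded.  Out-of-window trials of retained
participants are kept: the rules exclude participants, not trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TableDialect",
    "DIALECTS",
    "BandSpec",
    "StratifiedDataset",
    "load_trials",
    "filter_participants",
    "merge_lexicon",
    "make_frequency_bands",
    "stratify",
]

#: Files the ELP archive documentation flags as unusable.
ELP_EXCLUDE_FILES = (
    "9999.LDT",
    "793DATA.LDT",
    "Data999.LDT",
    "Data1000.LDT",
    "Data1010.LDT",
    "Data1016.LDT",
)

CANONICAL_COLUMNS = ("participant_id", "item", "rt", "accuracy", "is_word")


@dataclass(frozen=True)
class TableDialect:
    """Delimited-text dialect of a trial archive.

    ``columns`` maps canonical column names to the names used in the files.
    A missing ``is_word`` mapping means the archive marks lexicality some
    other way; rows then default to word trials.
    """

    delimiter: str = ","
    columns: Mapping[str, str] = field(
        default_factory=lambda: {c: c for c in CANONICAL_COLUMNS}
    )
    encoding: str = "utf-8"
    comment: str | None = None


DIALECTS: dict[str, TableDialect] = {
    "sdart": TableDialect(),
    "elp": TableDialect(
        delimiter=",",
        columns={
            "participant_id": "Sub_ID",
            "item": "D_Word",
            "rt": "D_RT",
            "accuracy": "D_Accuracy",
            "is_word": "D_Lexicality",
        },
    ),
    "blp": TableDialect(
        delimiter="\t",
        columns={
            "participant_id": "participant",
            "item": "spelling",
            "rt": "rt.raw",
            "accuracy": "accuracy",
            "is_word": "lexicality",
        },
    ),
}


def _resolve_dialect(dialect) -> TableDialect:
    if isinstance(dialect, TableDialect):
        return dialect
    return DIALECTS[str(dialect)]


def _iter_paths(path, exclude: set[str]) -> list[Path]:
    if isinstance(path, (str, Path)):
        p = Path(path)
        paths = sorted(q for q in p.iterdir() if q.is_file()) if p.is_dir() else [p]
    else:
        paths = [Path(q) for q in path]
    return [q for q in paths if q.name not in exclude]


def load_trials(path, exclude_files: Iterable[str] = (), dialect="sdart") -> pd.DataFrame:
    """Read one file, a directory, or a list of trial files into one table.

    Files named in ``exclude_files`` are skipped.  Malformed rows (wrong
    field count, non-numeric or non-positive RT, accuracy outside {0, 1})
    are dropped and counted; the count is logged and stored under
    ``df.attrs["n_malformed"]``.

    Raises ``FileNotFoundError`` for unreadable paths and ``ValueError``
    when no parseable rows remain.
    """
    dia = _resolve_dialect(dialect)
    paths = _iter_paths(path, set(exclude_files))
    if not paths:
        raise FileNotFoundError(f"no trial files found under {path!r}")

    n_bad = 0
    frames = []
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
        bad_lines: list = []
        raw = pd.read_csv(
            p,
            sep=dia.delimiter,
            encoding=dia.encoding,
            comment=dia.comment,
            engine="python",
            on_bad_lines=lambda line: bad_lines.append(line),  # noqa: B023
        )
        n_bad += len(bad_lines)
        df = pd.DataFrame()
        for canon, col in dia.columns.items():
            if col in raw.columns:
                df[canon] = raw[col]
        if "participant_id" not in df.columns or "rt" not in df.columns:
            n_bad += len(raw)
            continue
        if "is_word" not in df.columns:
            df["is_word"] = 1
        df["source_file"] = p.name
        frames.append(df)

    if not frames:
        raise ValueError("no parseable rows in any input file")
    out = pd.concat(frames, ignore_index=True)

    n0 = len(out)
    out["rt"] = pd.to_numeric(out["rt"], errors="coerce")
    out["accuracy"] = pd.to_numeric(out["accuracy"], errors="coerce")
    out["is_word"] = pd.to_numeric(out["is_word"], errors="coerce")
    ok = (
        out["rt"].notna()
        & (out["rt"] > 0)
        & out["accuracy"].isin([0, 1])
        & out["is_word"].isin([0, 1])
        & out["item"].notna()
    )
    n_bad += int((~ok).sum())
    out = out.loc[ok].reset_index(drop=True)
    if out.empty:
        raise ValueError("no parseable rows after cleaning")
    out["accuracy"] = out["accuracy"].astype(int)
    out["is_word"] = out["is_word"].astype(int)
    out["item"] = out["item"].astype(str)
    if n_bad:
        logger.warning("load_trials: dropped %d malformed rows (of %d)", n_bad, n0)
    out.attrs["n_malformed"] = n_bad
    return out


def filter_participants(
    trials: pd.DataFrame,
    min_accuracy: float = 0.60,
    rt_low: float = 150.0,
    rt_high: float = 2000.0,
    max_out_fraction: float = 0.20,
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the two participant-level exclusion rules, in order.

    1. participants with overall accuracy below ``min_accuracy`` are removed
       (accuracy exactly at the threshold is kept: "at least 60%");
    2. of the survivors, participants whose fraction of RTs outside
       ``[rt_low, rt_high]`` strictly exceeds ``max_out_fraction`` are
       removed (a fraction exactly at the threshold is kept).

    Accuracy and the out-of-window fraction are computed over *all* trials
    (words and nonwords); out-of-window trials of retained participants are
    not dropped.  Returns the retained trials and an exclusion report, one
    entry per excluded participant in order of rule application.
    """
    if not (0.0 < min_accuracy <= 1.0):
        raise ValueError("min_accuracy must be in (0, 1]")
    if not rt_low < rt_high:
        raise ValueError("rt_low must be below rt_high")

    report: list[dict] = []
    acc = trials.groupby("participant_id")["accuracy"].mean()
    bad_acc = acc.index[acc < min_accuracy]
    for pid in bad_acc:
        report.append(
            {"participant_id": pid, "reason": "accuracy", "value": float(acc[pid])}
        )
    kept = trials[~trials["participant_id"].isin(bad_acc)]

    out = (kept["rt"] < rt_low) | (kept["rt"] > rt_high)
    frac = out.groupby(kept["participant_id"]).mean()
    bad_rt = frac.index[frac > max_out_fraction]
    for pid in bad_rt:
        report.append(
            {"participant_id": pid, "reason": "rt_window", "value": float(frac[pid])}
        )
    kept = kept[~kept["participant_id"].isin(bad_rt)].reset_index(drop=True)
    if report:
        logger.info(
            "filter_participants: excluded %d participants (%s)",
            len(report),
            ", ".join(f"{r['participant_id']}:{r['reason']}" for r in report),
        )
    return kept, report


def merge_lexicon(
    trials: pd.DataFrame,
    lexicon: pd.DataFrame,
    measure: str = "WF",
    lengths: Iterable[int] = range(4, 11),
    pos_exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Annotate word trials with length and occurrence value; drop the rest.

    Keeps only word trials (``is_word == 1``) whose item appears in the
    lexicon with a positive value of ``measure``, whose length is in
    ``lengths`` and whose part of speech is not excluded.  The retained
    table gains ``length`` and ``freq`` columns; the measure name is kept
    in ``df.attrs["measure"]``.
    """
    if measure not in lexicon.columns:
        raise KeyError(f"measure {measure!r} not in lexicon columns {list(lexicon.columns)}")
    lex = lexicon[["word", "length", "pos", measure]].rename(columns={measure: "freq"})
    lex = lex[lex["freq"].notna() & (lex["freq"] > 0)]
    lex = lex[lex["length"].isin(set(lengths))]
    if pos_exclude:
        lex = lex[~lex["pos"].isin(set(pos_exclude))]
    lex = lex.drop_duplicates(subset="word")

    words = trials[trials["is_word"] == 1]
    merged = words.merge(
        lex[["word", "length", "freq"]], left_on="item", right_on="word", how="inner"
    ).drop(columns="word")
    merged["length"] = merged["length"].astype(int)
    merged = merged.reset_index(drop=True)
    merged.attrs["measure"] = measure
    logger.info(
        "merge_lexicon: %d of %d word trials retained (measure=%s)",
        len(merged),
        len(words),
        measure,
    )
    return merged


@dataclass(frozen=True)
class BandSpec:
    """Quantile-derived frequency bands over trial-level occurrence values.

    ``boundaries`` are the k-1 inner quantile boundaries, strictly
    ascending.  A value equal to a boundary belongs to the lower band, so
    every occurrence value maps to exactly one band (1..k, ascending
    occurrence).
    """

    measure: str
    boundaries: tuple[float, ...]
    k: int
    min_count: int

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.size and not np.all(np.diff(b) > 0):
            raise ValueError("band boundaries must be strictly ascending")
        if self.k != len(self.boundaries) + 1:
            raise ValueError("k must equal len(boundaries) + 1")

    def assign(self, values) -> np.ndarray:
        """Band index (1-based) for each occurrence value."""
        b = np.asarray(self.boundaries, dtype=float)
        return np.searchsorted(b, np.asarray(values, dtype=float), side="left") + 1


def make_frequency_bands(
    annotated: pd.DataFrame, measure: str | None = None, min_count: int = 40_000
) -> BandSpec:
    """Choose the finest quantile banding leaving >= ``min_count`` trials per band.

    Boundaries are the (m/k)-quantiles (linear interpolation) of the
    *trial-level* occurrence values, so common words weigh in proportion to
    their observation counts.  Tied occurrence values fall wholly into one
    band (ties to the lower band); k is the largest band count for which
    every band still holds at least ``min_count`` observations after the
    tie rule.  Falls back to a single band, with a warning, when the data
    cannot support two.
    """
    measure = measure or annotated.attrs.get("measure", "freq")
    values = annotated["freq"].to_numpy(dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("no annotated trials to band")
    if n < min_count:
        logger.warning(
            "make_frequency_bands: %d observations < min_count=%d; single band", n, min_count
        )
        return BandSpec(measure=measure, boundaries=(), k=1, min_count=min_count)

    for k in range(n // min_count, 1, -1):
        qs = np.quantile(values, np.arange(1, k) / k)
        bounds = tuple(dict.fromkeys(qs.tolist()))  # dedupe heavy ties, keep order
        if len(bounds) != k - 1:
            continue
        spec = BandSpec(measure=measure, boundaries=bounds, k=k, min_count=min_count)
        counts = np.bincount(spec.assign(values), minlength=k + 1)[1:]
        if counts.min() >= min_count:
            return spec
    return BandSpec(measure=measure, boundaries=(), k=1, min_count=min_count)


@dataclass
class StratifiedDataset:
    """Retained word trials stratified into (participant, band, length) cells.

    ``df`` carries one row per trial with ``participant_id``, ``item``,
    ``rt``, ``freq``, ``length`` and the assigned ``band``.  The table is a
    partition: every retained trial sits in exactly one cell.
    """

    df: pd.DataFrame
    band_spec: BandSpec
    lengths: tuple[int, ...]

    @property
    def n_trials(self) -> int:
        return len(self.df)

    @property
    def participants(self) -> list:
        return sorted(self.df["participant_id"].unique().tolist())

    def cells(self) -> dict[tuple, np.ndarray]:
        """Map (participant, band, length) -> RT array (ms)."""
        return {
            key: g["rt"].to_numpy(dtype=float)
            for key, g in self.df.groupby(["participant_id", "band", "length"], sort=True)
        }

    def cell_sizes(self) -> pd.Series:
        return self.df.groupby(["participant_id", "band", "length"]).size()


def stratify(annotated: pd.DataFrame, band_spec: BandSpec) -> StratifiedDataset:
    """Assign each annotated trial to its (participant, band, length) cell."""
    df = annotated.copy()
    df["band"] = band_spec.assign(df["freq"].to_numpy(dtype=float))
    lengths = tuple(sorted(df["length"].unique().tolist()))
    return StratifiedDataset(df=df, band_spec=band_spec, lengths=lengths)
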