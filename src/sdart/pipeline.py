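"""End-to-end pipeline: simulate/load -> preprocess -> band -> fit -> assess
-> compare -> report, driven by one declarative config.

The config is a plain mapping (usually loaded from YAML).  Every stage
logs its in/out counts into a run manifest; all tabular outputs are
delimited text with JSON sidecars, and a fixed seed makes the whole run
reproducible (sub-seeds are spawned per fitted model).
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assessment, reporting
from .model import PriorConfig, StratifiedRTModel
from .preprocessing import (
    filter_participants,
    load_trials,
    make_frequency_bands,
    merge_lexicon,
    stratify,
)
from .simulate import SimDesign, gen_trials, write_lexicon, write_trials

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline", "report"]

STAGES = ("data", "preprocess", "band", "fit", "assess", "compare")


def default_config() -> dict:
    """A complete config with desk-scale defaults (simulation mode)."""
    return {
        "seed": 0,
        "output_dir": "sdart_out",
        "simulate": {
            "n_participants": 6,
            "lengths": [4, 5],
            "n_bands": 2,
            "trials_per_cell": 25,
            "family": "lognormal",
        },
        "input": None,  # {"trials": path-or-dir, "lexicon": path, "dialect": "sdart", "exclude_files": []}
        "measures": ["WF"],
        "families": ["lognormal"],
        "filters": {
            "min_accuracy": 0.60,
            "rt_low": 150.0,
            "rt_high": 2000.0,
            "max_out_fraction": 0.20,
        },
        "lengths": list(range(4, 11)),
        "pos_exclude": [],
        "band_min_count": 40_000,
        "prior": {"a": 0.1, "b": 0.1},
        "sampler": {"draws": 400, "warmup": 400, "chains": 2, "thin": 1},
        "assess": {"R": 200, "elpd_method": "loo", "ppp_by": "cell"},
        "save_draws": False,
    }


def _merge_config(user: dict | None) -> dict:
    cfg = default_config()
    for k, v in (user or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k] = {**cfg[k], **v}
        else:
            cfg[k] = v
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict | None, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis for every requested family x measure model.

    Returns the run manifest (also written to ``manifest.json`` in the
    output directory).  On a stage failure the manifest records partial
    completion and the error, and the exception propagates.
    """
    cfg = _merge_config(config)
    out = Path(out_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "versions": {
            "sdart": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "stages": [],
        "models": [],
        "outputs": [],
    }

    def stage(name, **info):
        manifest["stages"].append({"name": name, "status": "complete", **info})

    try:
        # ---- data ------------------------------------------------------ #
        if cfg.get("input"):
            src = cfg["input"]
            trials = load_trials(
                src["trials"],
                exclude_files=src.get("exclude_files", ()),
                dialect=src.get("dialect", "sdart"),
            )
            lexicon = pd.read_csv(src["lexicon"])
            truth = None
        else:
            design = SimDesign(seed=cfg["seed"], **cfg["simulate"])
            trials, truth = gen_trials(design)
            lexicon = truth.lexicon
            write_trials(trials, out / "sim_trials.csv")
            write_lexicon(lexicon, out / "sim_lexicon.csv")
            manifest["outputs"] += ["sim_trials.csv", "sim_lexicon.csv"]
        stage("data", n_trials=int(len(trials)), n_words=int(len(lexicon)))

        # ---- participant filters --------------------------------------- #
        kept, excl = filter_participants(trials, **cfg["filters"])
        (out / "exclusions.json").write_text(json.dumps(excl, indent=2, default=str))
        manifest["outputs"].append("exclusions.json")
        stage(
            "preprocess",
            n_in=int(len(trials)),
            n_out=int(len(kept)),
            n_excluded_participants=len(excl),
        )

        # ---- per-measure banding + stratification ----------------------- #
        kept = kept.reset_index(drop=True)
        kept["uid"] = np.arange(len(kept))
        datasets = {}
        for measure in cfg["measures"]:
            ann = merge_lexicon(
                kept,
                lexicon,
                measure=measure,
                lengths=cfg["lengths"],
                pos_exclude=cfg["pos_exclude"],
            )
            spec = make_frequency_bands(ann, measure, min_count=cfg["band_min_count"])
            ds = stratify(ann, spec)
            ds.df = ds.df.sort_values("uid", kind="stable").reset_index(drop=True)
            datasets[measure] = ds
        stage(
            "band",
            bands={m: ds.band_spec.k for m, ds in datasets.items()},
            cells={m: int(ds.cell_sizes().size) for m, ds in datasets.items()},
        )

        # ---- fit + assess every family x measure ------------------------ #
        n_models = len(cfg["families"]) * len(cfg["measures"])
        seeds = np.random.SeedSequence(cfg["seed"]).generate_state(n_models) % (2**31)
        s = cfg["sampler"]
        elpds: dict[str, tuple] = {}
        i = 0
        for measure, ds in datasets.items():
            for family in cfg["families"]:
                label = f"{measure}_{family}"
                prior = PriorConfig.default(ds.lengths, **cfg["prior"])
                model = StratifiedRTModel(ds, family, prior=prior)
                res = model.fit(
                    draws=s["draws"],
                    warmup=s["warmup"],
                    chains=s["chains"],
                    thin=s.get("thin", 1),
                    seed=int(seeds[i]),
                )
                i += 1
                mdir = out / label
                mdir.mkdir(exist_ok=True)
                reporting.theta_median_table(res).to_csv(mdir / "theta_medians.csv", index=False)
                reporting.cell_mean_table(res).to_csv(mdir / "cell_means.csv", index=False)
                if cfg.get("save_draws"):
                    res.draws.save(mdir / "draws.csv")
                ppp = res.ppp(
                    R=cfg["assess"]["R"], seed=int(seeds[i - 1]), by=cfg["assess"].get("ppp_by", "cell")
                )
                reporting.ppp_table(ppp).to_csv(mdir / "ppp.csv", index=False)
                er = res.elpd(method=cfg["assess"].get("elpd_method", "loo"), label=label)
                (mdir / "elpd.json").write_text(
                    json.dumps(
                        {
                            "label": label,
                            "method": er.method,
                            "elpd": er.elpd,
                            "se": er.se,
                            "n": er.n,
                            "n_flagged": int(er.flags.sum()),
                            "rhat_max": res.draws.metadata.get("rhat_max"),
                        },
                        indent=2,
                    )
                )
                uid_key = hashlib.sha256(ds.df["uid"].to_numpy().tobytes()).hexdigest()
                elpds[label] = (er, uid_key)
                manifest["models"].append(
                    {
                        "label": label,
                        "family": family,
                        "measure": measure,
                        "n_trials": ds.n_trials,
                        "bands": ds.band_spec.k,
                        "elpd": er.elpd,
                        "ppp_mean": float(np.mean(ppp.values)),
                        "rhat_max": res.draws.metadata.get("rhat_max"),
                    }
                )
        stage("fit", n_models=n_models)
        stage("assess", n_models=n_models)

        # ---- comparison (models sharing an identical trial set) --------- #
        groups: dict[str, list] = {}
        for label, (er, key) in elpds.items():
            groups.setdefault(key, []).append(er)
        tables = []
        for ers in groups.values():
            comp = assessment.compare_models(ers)
            tables.append(reporting.comparison_table(comp))
        comparison = pd.concat(tables, ignore_index=True)
        comparison.to_csv(out / "comparison.csv", index=False)
        manifest["outputs"].append("comparison.csv")
        stage("compare", n_groups=len(groups))
    except Exception as e:  # partial completion is recorded, then re-raised
        manifest["stages"].append({"name": "error", "status": "failed", "error": repr(e)})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def report(out_dir: str | Path) -> dict:
    """Aggregate per-model outputs of a finished run into summary artifacts.

    Emits, per model: the shift-median table (already present), the cell
    means amalgamated over length (frequency profile) and over frequency
    (length profile), and pools the ppp tables and the comparison table at
    the run level.  Returns the paths written.
    """
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    written = []
    ppp_all = []
    for m in manifest["models"]:
        mdir = out / m["label"]
        if not (mdir / "cell_means.csv").exists():
            raise FileNotFoundError(f"missing draws-derived outputs for model {m['label']}")
        cells = pd.read_csv(mdir / "cell_means.csv")
        for over, name in (("length", "frequency_profile"), ("band", "length_profile")):
            tab = reporting.amalgamate(cells, over=over)
            tab.insert(0, "model", m["label"])
            p = mdir / f"{name}.csv"
            tab.to_csv(p, index=False)
            written.append(str(p))
        ppp = pd.read_csv(mdir / "ppp.csv")
        ppp.insert(0, "model", m["label"])
        ppp_all.append(ppp)
    pd.concat(ppp_all, ignore_index=True).to_csv(out / "ppp_all_models.csv", index=False)
    written.append(str(out / "ppp_all_models.csv"))
    return {"written": written}
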