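"""End-to-end analysis pipeline and run manifests.

``run_pipeline`` wires the stages together: impute missed surveys, run the
two-step structure selection per focal species, classify per-month trend
labels, optionally fit the community-level model, and write all artifacts
plus a JSON manifest (config hash, seed, package versions, per-stage status
and timings).  Species-level failures are isolated: the pipeline records
them and continues.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .hmm import impute_panel
from .panel import PhenologyPanel
from .selection import two_step_select, fit_structure
from .synthetic import default_bwindi_profiles, generate_panel
from .trends import TrendLabels, classify_trend, sort_species_by_trend

DEFAULT_CONFIG = {
    "seed": 0,
    "n_months": 95,
    "missing_rate": 0.06,
    "alpha": 0.05,
    "mixed": True,
    "k_trend": 10,
    "k_seasonal": 8,
    "s1_month_threshold": 10,
    "s2_month_threshold": 2,
    "min_species_n": 5,
    "community_fit": False,
    "panel_csv": None,          # None -> synthetic default community
}


def validate_config(config: dict | None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    if not 0 < cfg["alpha"] < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 <= cfg["missing_rate"] < 0.5:
        raise ValueError("missing_rate must be in [0, 0.5)")
    for key in ("k_trend", "k_seasonal"):
        if cfg[key] < 3:
            raise ValueError(f"{key} must be >= 3")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict | None, outdir) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "versions": {"phenogamm": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
    }

    def stage(name):
        manifest["stages"][name] = {"status": "running", "seconds": None}
        return time.time()

    def done(name, t0, **extra):
        manifest["stages"][name].update(
            status="ok", seconds=round(time.time() - t0, 2), **extra)

    # ---- panel -------------------------------------------------------------
    t0 = stage("panel")
    if cfg["panel_csv"]:
        panel = PhenologyPanel.from_csv(cfg["panel_csv"])
    else:
        panel = generate_panel(
            default_bwindi_profiles(seed=cfg["seed"]),
            n_months=cfg["n_months"], missing_rate=cfg["missing_rate"],
            seed=cfg["seed"],
        )
    panel.to_csv(outdir / "panel.csv")
    done("panel", t0, n_rows=len(panel), n_plants=panel.n_plants,
         n_species=panel.n_species,
         missing_fraction=round(panel.missing_fraction, 4))

    # ---- imputation --------------------------------------------------------
    t0 = stage("impute")
    completed, mask = impute_panel(panel)
    completed.to_csv(outdir / "panel_completed.csv")
    mask.to_csv(outdir / "imputation_mask.csv", index=False)
    done("impute", t0, n_imputed=len(mask))

    # ---- per-species selection --------------------------------------------
    t0 = stage("select")
    counts = (completed.frame.groupby("species")["plant_id"]
              .nunique().sort_values(ascending=False))
    focal = [s for s, n in counts.items() if n >= cfg["min_species_n"]]
    decisions, final_fits, failures = {}, {}, {}
    for sp in focal:
        try:
            dec, fits = two_step_select(
                completed.species_panel(sp), alpha=cfg["alpha"],
                mixed=cfg["mixed"], k_trend=cfg["k_trend"],
                k_seasonal=cfg["k_seasonal"],
                s1_month_threshold=cfg["s1_month_threshold"],
                s2_month_threshold=cfg["s2_month_threshold"],
            )
            decisions[sp] = dec
            final_fits[sp] = fits[dec.chosen]
        except Exception as exc:  # isolate per-species failures
            failures[sp] = repr(exc)
    with open(outdir / "decisions.json", "w") as fh:
        json.dump({sp: d.to_dict() for sp, d in decisions.items()}, fh,
                  indent=2, default=float)
    model_counts = pd.Series(
        [d.chosen for d in decisions.values()]
    ).value_counts().reindex(["M1", "M2", "M3", "M4", "M5"], fill_value=0)
    model_counts.rename("n_species").to_csv(outdir / "model_counts.csv")
    done("select", t0, n_focal=len(focal), n_failed=len(failures),
         model_counts=model_counts.to_dict(), failures=failures)

    # ---- trend classification ---------------------------------------------
    t0 = stage("classify")
    months = np.sort(completed.frame["month_index"].unique())
    label_rows = {}
    for sp, dec in decisions.items():
        label_rows[sp] = classify_trend(dec, final_fits[sp], months)
    labels = TrendLabels(
        frame=pd.DataFrame(label_rows, index=months).T,
        chosen_models={sp: d.chosen for sp, d in decisions.items()},
    )
    labels = sort_species_by_trend(labels)
    labels.to_long().to_csv(outdir / "trend_labels.csv", index=False)
    done("classify", t0)

    # ---- community-level fit (optional; heavy at full size) ----------------
    if cfg["community_fit"]:
        t0 = stage("community_fit")
        res = fit_structure(completed, "M1", mixed=cfg["mixed"],
                            k_trend=cfg["k_trend"],
                            k_seasonal=cfg["k_seasonal"])
        res.to_json(outdir / "community_fit.json")
        for term in res.design.smooth_names:
            res.credible_band(term).to_frame().to_csv(
                outdir / f"community_band_{term}.csv", index=False)
        done("community_fit", t0, converged=bool(res.converged))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
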