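"""End-to-end orchestration: simulate -> fit -> compare -> analyze.

A single YAML/dict config drives the run; all randomness flows from one
master seed through named substreams, so a rerun with the same config is
bit-identical. Each stage writes CSV outputs into the output directory and a
``manifest.json`` records the config hash, seeds, and output digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, latent, models
from .cohort import CohortSpec, generate_cohort, trials_by_subject
from .fitting import compare_models, fit_sessions, fits_to_frame
from .hierarchical import MCMCConfig, fit_hierarchical
from .models import MODEL_IDS, compute_latents, params_from_vector
from .task import TaskConfig, write_trials_csv

log = logging.getLogger("dynaprl.pipeline")

DEFAULT_CONFIG = {
    "seed": 0,
    "cohort": {
        "model_id": "asym5",
        "n_subjects_a": 3,
        "n_subjects_b": 3,
        "sessions_per_subject": 2,
        "trials_per_session": 250,
        "deltas": {},
        "invalid_rate": 0.005,
    },
    "fit": {"models": ["standard", "avgrpe"], "n_restarts": 10},
    "latent": {"run_ksweep": True, "run_correlation": True, "run_median_split": True},
    "hierarchical": {"enabled": False, "n_steps": 700, "n_warmup": 400},
}


def _substream(master_seed: int, name: str) -> int:
    h = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict) -> dict:
    cfg = _merge(DEFAULT_CONFIG, config or {})
    errors = []
    if cfg["cohort"]["model_id"] not in MODEL_IDS:
        errors.append(f"cohort.model_id: unknown model {cfg['cohort']['model_id']!r}")
    for m in cfg["fit"]["models"]:
        if m not in MODEL_IDS:
            errors.append(f"fit.models: unknown model {m!r}")
    if not isinstance(cfg["seed"], int):
        errors.append("seed: must be an integer")
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return cfg


def run_pipeline(config: dict, out_dir) -> Path:
    """Run every enabled stage; returns the output directory."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
        "outputs": {},
    }

    def finish(stage: str, t0: float, files: dict):
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
        for name, path in files.items():
            digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
            manifest["outputs"][name] = {"path": str(path), "sha256": digest}
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    # --- simulate -----------------------------------------------------------
    t0 = time.perf_counter()
    spec = CohortSpec(seed=_substream(seed, "cohort"), **cfg["cohort"])
    trials, groups, truth = generate_cohort(spec)
    write_trials_csv(trials, out / "trials.csv")
    groups.to_csv(out / "groups.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    finish(
        "simulate",
        t0,
        {
            "trials": out / "trials.csv",
            "groups": out / "groups.csv",
            "truth": out / "truth.csv",
        },
    )

    # --- fit & compare ------------------------------------------------------
    t0 = time.perf_counter()
    fit_models = cfg["fit"]["models"]
    comparison = compare_models(
        trials,
        fit_models,
        n_restarts=cfg["fit"]["n_restarts"],
        seed=_substream(seed, "fit"),
    )
    comparison["bic_by_session"].to_csv(out / "bic.csv")
    std_fits = fit_sessions(
        trials, "standard", n_restarts=cfg["fit"]["n_restarts"], seed=_substream(seed, "fit")
    )
    fits_to_frame(std_fits).to_csv(out / "fits_standard.csv", index=False)
    finish("fit", t0, {"bic": out / "bic.csv", "fits_standard": out / "fits_standard.csv"})

    # --- behavior -----------------------------------------------------------
    t0 = time.perf_counter()
    events = behavior.classify_events(trials)
    summary = behavior.summarize(events)
    summary.table.to_csv(out / "behavior_summary.csv", index=False)
    curve = behavior.perseveration_curve(
        trials, rng=np.random.default_rng(_substream(seed, "perseveration"))
    )
    curve.to_csv(out / "perseveration.csv", index=False)
    finish(
        "behavior",
        t0,
        {"behavior_summary": out / "behavior_summary.csv", "perseveration": out / "perseveration.csv"},
    )

    # --- latent analyses ----------------------------------------------------
    # Per the analysis design: RPEs from the standard fit, |avgRPE| from the
    # avgRPE fit, GRS from the GRS fit — pooled at the session level.
    t0 = time.perf_counter()
    lat_files = {}
    lat_cfg = cfg["latent"]
    fit_seed = _substream(seed, "latent_fit")
    merged_parts = []
    for _, sess in trials.groupby("session_id", sort=False):
        part = None
        for model_id, cols in (
            ("standard", ["rpe"]),
            ("avgrpe", ["abs_avg_rpe"]),
            ("grs", ["r_trace"]),
        ):
            from .fitting import fit_session

            f = fit_session(sess, model_id, n_restarts=3, seed=fit_seed)
            lat_df = compute_latents(sess, model_id, params_from_vector(model_id, f.vector))
            if part is None:
                part = lat_df.drop(columns=[c for c in models.LATENT_COLUMNS if c not in cols])
            else:
                part[cols] = lat_df[cols]
        merged_parts.append(part)
    merged = pd.concat(merged_parts, ignore_index=True)

    if lat_cfg["run_ksweep"]:
        ks = latent.k_sweep(merged)
        pd.DataFrame(
            {"k": ks.k_grid, "coef_ws": ks.coef_ws, "coef_ls": ks.coef_ls}
        ).to_csv(out / "ksweep.csv", index=False)
        lat_files["ksweep"] = out / "ksweep.csv"
    if lat_cfg["run_correlation"]:
        rows = []
        for pred in ("abs_avg_rpe", "r_trace"):
            for oc in ("WS", "LS"):
                rows.append(latent.latent_choice_correlation(merged, pred, oc))
        pd.concat(rows, ignore_index=True).to_csv(out / "latent_correlation.csv", index=False)
        lat_files["latent_correlation"] = out / "latent_correlation.csv"
    if lat_cfg["run_median_split"]:
        latent.median_split_interaction(merged).to_csv(out / "median_split.csv", index=False)
        lat_files["median_split"] = out / "median_split.csv"
    finish("latent", t0, lat_files)

    # --- hierarchical -------------------------------------------------------
    if cfg["hierarchical"]["enabled"]:
        t0 = time.perf_counter()
        res = fit_hierarchical(
            trials_by_subject(trials),
            dict(zip(groups["subject_id"], groups["group"])),
            MCMCConfig(
                n_steps=cfg["hierarchical"]["n_steps"],
                n_warmup=cfg["hierarchical"]["n_warmup"],
                seed=_substream(seed, "hier"),
            ),
        )
        res.summary().to_csv(out / "hierarchical_summary.csv", index=False)
        finish("hierarchical", t0, {"hierarchical_summary": out / "hierarchical_summary.csv"})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
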