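"""End-to-end simulation runs from a validated configuration.

A run loops over population correlations and models, generates one shared
trajectory batch per rho (so model comparisons are paired), estimates
every (replication, n) cell, aggregates the four proportion curves, and
extracts required-sample-size tables.  Outputs are written as CSV and JSON
plus a reproducibility manifest; everything is deterministic given the
configuration and master seed.
"""

from __future__ import annotations

import json
import logging
import time
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import PriorSpec, estimate_batch_bayes, make_prior
from .datagen import PopulationSpec, generate_batch
from .frequentist import estimate_batch_frequentist
from .stability import build_tables, cos_bounds, curves_to_frame, proportion_curve

logger = logging.getLogger("corstab")

__all__ = ["RunConfig", "validate_config", "run", "default_bayes_grid", "PRESETS"]

KNOWN_MODELS = ("frequentist", "weak", "moderate", "high")


def default_bayes_grid(n_min: int = 10, n_max: int = 500) -> list[int]:
    """Coarsened n grid for Bayesian fits: every n to 100, every 5th to 250,
    every 10th to 500 (clipped to [n_min, n_max])."""
    grid = list(range(10, 101)) + list(range(105, 251, 5)) + list(range(260, 501, 10))
    return [n for n in grid if n_min <= n <= n_max]


@dataclass
class RunConfig:
    """Validated configuration of one simulation run."""

    rho_list: list[float] = field(default_factory=lambda: [0.1, 0.2, 0.3, 0.4])
    models: list[str] = field(default_factory=lambda: ["frequentist"])
    n_reps: int = 10_000
    bayes_n_reps: int | None = None
    n_min: int = 10
    n_max: int = 500
    bayes_n_grid: list[int] | None = None
    levels: list[float] = field(default_factory=lambda: [0.66, 0.90, 0.95])
    p_list: list[float] = field(default_factory=lambda: [0.80, 0.90, 0.95])
    w_list: list[float] = field(default_factory=lambda: [0.1, 0.15, 0.2])
    master_seed: int = 0
    mode: str = "iid"
    cos_scale: str = "raw"
    rule: str = "first"
    kappa_moderate: float = 10.0
    kappa_high: float = 50.0
    n_jobs: int = 1
    out_dir: str = "corstab-out"


_DEFAULTS = RunConfig()
_KNOWN_KEYS = set(asdict(_DEFAULTS))


def validate_config(raw) -> tuple[RunConfig | None, list[str]]:
    """Validate a raw config (dict, YAML/JSON text, or path) into a RunConfig.

    Returns ``(config, [])`` on success or ``(None, errors)`` with every
    violation named by field; unknown keys are rejected.
    """
    if isinstance(raw, (str, Path)):
        text = Path(raw).read_text() if Path(str(raw)).exists() else str(raw)
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        return None, ["config root must be a mapping"]
    errors: list[str] = []
    for key in raw:
        if key not in _KNOWN_KEYS:
            errors.append(f"{key}: unknown configuration key")
    merged = {**asdict(_DEFAULTS), **{k: v for k, v in raw.items() if k in _KNOWN_KEYS}}

    def check(cond: bool, msg: str) -> None:
        if not cond:
            errors.append(msg)

    rhos = merged["rho_list"]
    check(
        isinstance(rhos, (list, tuple)) and len(rhos) > 0,
        "rho_list: must be a non-empty list",
    )
    if isinstance(rhos, (list, tuple)):
        for r in rhos:
            check(
                isinstance(r, (int, float)) and -1 < r < 1,
                f"rho_list: rho={r} outside (-1, 1)",
            )
    models = merged["models"]
    check(
        isinstance(models, (list, tuple)) and len(models) > 0,
        "models: must be a non-empty list",
    )
    if isinstance(models, (list, tuple)):
        for m in models:
            check(m in KNOWN_MODELS, f"models: unknown model {m!r}")
    check(isinstance(merged["n_reps"], int) and merged["n_reps"] >= 1, "n_reps: must be >= 1")
    if merged["bayes_n_reps"] is not None:
        check(
            isinstance(merged["bayes_n_reps"], int)
            and 1 <= merged["bayes_n_reps"] <= merged["n_reps"],
            "bayes_n_reps: must be in [1, n_reps]",
        )
    check(
        isinstance(merged["n_min"], int) and merged["n_min"] >= 3,
        "n_min: must be an integer >= 3",
    )
    check(
        isinstance(merged["n_max"], int) and merged["n_max"] >= merged["n_min"],
        "n_max: must be an integer >= n_min",
    )
    if merged["bayes_n_grid"] is not None:
        grid = merged["bayes_n_grid"]
        ok = isinstance(grid, (list, tuple)) and len(grid) > 0
        check(ok, "bayes_n_grid: must be a non-empty list of integers")
        if ok:
            for n in grid:
                check(
                    isinstance(n, int) and merged["n_min"] <= n <= merged["n_max"],
                    f"bayes_n_grid: n={n} outside [n_min, n_max]",
                )
    for lvl in merged["levels"]:
        check(0 < lvl < 1, f"levels: level={lvl} outside (0, 1)")
    for P in merged["p_list"]:
        check(0 < P < 1, f"p_list: P={P} outside (0, 1)")
    check(
        isinstance(merged["w_list"], (list, tuple)),
        "w_list: must be a list",
    )
    for w in merged["w_list"]:
        check(isinstance(w, (int, float)) and w > 0, f"w_list: w={w} must be positive")
    if len(merged["w_list"]) == 0:
        errors.append(
            "w_list: empty, but estimate_in_cos/interval_in_cos criteria need "
            "at least one corridor width"
        )
    check(merged["mode"] in ("iid", "finite_population"), "mode: must be iid or finite_population")
    check(merged["cos_scale"] in ("z", "raw"), "cos_scale: must be z or raw")
    check(merged["rule"] in ("first", "sustained"), "rule: must be first or sustained")
    check(merged["kappa_moderate"] > 2, "kappa_moderate: must exceed 2")
    check(merged["kappa_high"] > 2, "kappa_high: must exceed 2")
    check(isinstance(merged["master_seed"], int) and merged["master_seed"] >= 0, "master_seed: must be a non-negative integer")
    check(isinstance(merged["n_jobs"], int) and merged["n_jobs"] != 0, "n_jobs: must be a non-zero integer")
    if errors:
        return None, errors
    cfg = RunConfig(**merged)
    cfg.rho_list = [float(r) for r in cfg.rho_list]
    cfg.models = list(cfg.models)
    cfg.levels = sorted(float(l) for l in cfg.levels)
    cfg.p_list = [float(p) for p in cfg.p_list]
    cfg.w_list = [float(w) for w in cfg.w_list]
    return cfg, []


PRESETS: dict[str, dict] = {
    # tiny end-to-end exercise
    "smoke": {
        "rho_list": [0.3],
        "models": ["frequentist"],
        "n_reps": 50,
        "n_max": 120,
        "master_seed": 7,
    },
    # full frequentist roster: 4 rho x 10,000 replications x n = 10..500
    "study-frequentist": {
        "rho_list": [0.1, 0.2, 0.3, 0.4],
        "models": ["frequentist"],
        "n_reps": 10_000,
    },
    # scaled-down weak-prior comparison at the reference effect size
    "study-weak-scaled": {
        "rho_list": [0.2],
        "models": ["frequentist", "weak"],
        "n_reps": 10_000,
        "bayes_n_reps": 1_000,
    },
}


def _prior_for(model: str, rho: float, cfg: RunConfig) -> PriorSpec:
    if model == "weak":
        return make_prior("weak")
    if model == "moderate":
        return make_prior("moderate", rho_center=rho, concentration=cfg.kappa_moderate)
    return make_prior("high", rho_center=rho, concentration=cfg.kappa_high)


def _curves_for_cell(estimates, cfg: RunConfig):
    """All proportion curves (4 criteria x levels x widths) for one cell."""
    curves = [proportion_curve(estimates, "sign_correct")]
    for lvl in cfg.levels:
        curves.append(proportion_curve(estimates, "robust_nonzero", level=lvl))
    for w in cfg.w_list:
        cos = cos_bounds(estimates.rho, w, scale=cfg.cos_scale)
        curves.append(proportion_curve(estimates, "estimate_in_cos", cos=cos))
        for lvl in cfg.levels:
            curves.append(
                proportion_curve(estimates, "interval_in_cos", level=lvl, cos=cos)
            )
    return curves


def run(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute a full simulation run and write the output bundle.

    Returns a summary dict with output paths and the manifest.  Failures
    are isolated per (rho, model) cell: a failing cell is recorded in the
    manifest's ``errors`` and the remaining cells still complete.
    """
    t0 = time.time()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curves = []
    errors: list[dict] = []
    cell_timings: dict[str, float] = {}
    seed_digests: dict[str, str] = {}
    bayes_grid = config.bayes_n_grid or default_bayes_grid(config.n_min, config.n_max)
    bayes_reps = config.bayes_n_reps or config.n_reps
    for rho in config.rho_list:
        spec = PopulationSpec(rho=rho)
        batch = generate_batch(
            spec,
            config.n_reps,
            config.n_min,
            config.n_max,
            mode=config.mode,
            master_seed=config.master_seed,
        )
        seed_digests[str(rho)] = batch.seed_ledger.digest()
        for model in config.models:
            t_cell = time.time()
            try:
                if model == "frequentist":
                    est = estimate_batch_frequentist(batch, levels=config.levels)
                else:
                    prior = _prior_for(model, rho, config)
                    est = estimate_batch_bayes(
                        batch.subset(bayes_reps),
                        prior,
                        n_grid=bayes_grid,
                        levels=config.levels,
                        n_jobs=config.n_jobs,
                    )
                curves.extend(_curves_for_cell(est, config))
                logger.info(
                    "cell rho=%.2f model=%s done in %.1fs (%d replications)",
                    rho,
                    model,
                    time.time() - t_cell,
                    est.n_reps,
                )
            except Exception as exc:  # isolate per-cell failures
                logger.exception("cell rho=%.2f model=%s failed", rho, model)
                errors.append(
                    {
                        "rho": rho,
                        "model": model,
                        "error": repr(exc),
                        "traceback": traceback.format_exc(),
                    }
                )
            cell_timings[f"rho={rho},model={model}"] = round(time.time() - t_cell, 3)
    curves_df = curves_to_frame(curves)
    tables_df = build_tables(curves, p_list=config.p_list, rule=config.rule)
    curves_path = out / "curves.csv"
    tables_path = out / "tables.csv"
    curves_df.to_csv(curves_path, index=False)
    tables_df.to_csv(tables_path, index=False)
    (out / "curves.json").write_text(curves_df.to_json(orient="records"))
    (out / "tables.json").write_text(tables_df.to_json(orient="records"))
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "bayes_n_grid_used": list(bayes_grid),
        "seed_digests": seed_digests,
        "wall_clock_s": round(time.time() - t0, 3),
        "cell_timings_s": cell_timings,
        "errors": errors,
        "n_curves": len(curves),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "out_dir": str(out),
        "curves": str(curves_path),
        "tables": str(tables_path),
        "manifest": manifest,
    }
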