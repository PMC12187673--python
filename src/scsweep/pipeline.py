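"""End-to-end orchestration: simulate -> subsample -> sweep -> analyze.

One run configuration (a plain dict, usually loaded from YAML) drives all
stages; every stage's randomness derives from a single master seed, so a
rerun with the same configuration reproduces all outputs byte-identically.

Output files (all plain text) per run directory:

- ``sweep_records.csv`` - one row per (dataset, replicate, configuration)
- ``effects_coefficients.csv``, ``effects_diagnostics.json``,
  ``extreme_configs.json``, ``dataset_comparison.json``
- ``predictor_coefficients.csv``, ``validation_report.json``,
  ``metric_correlations.csv``, ``linearity_deviation.csv``,
  ``feature_ranking.csv``
- ``manifest.json`` - config hash, seeds, stage wall times, record counts
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .effects import (
    compare_groups,
    extract_extreme_configs,
    fit_effects_for_records,
    residual_normality,
)
from .predictor import (
    clean_feature_table,
    linearity_deviation,
    metric_association,
    rank_consistent_features,
    validate_cross,
    validate_intra,
)
from .sweep import SweepConfig, enumerate_grid, run_sweep
from .synthetic import (
    PopulationSpec,
    default_desk_specs,
    generate_dataset,
    stratified_subsample,
)

logger = logging.getLogger(__name__)

__all__ = ["run_all", "load_config", "derive_seed"]

DESK_DEFAULTS = {
    "subsample_fraction": 0.2,
    "n_replicates": 10,
    "preprocess": {"min_cells": 3, "target_sum": 1e4, "n_hvg": 2000},
}


def derive_seed(master: int, *key: int) -> int:
    """Deterministic sub-seed below 2^31 from a master seed and an int key."""
    return int(np.random.SeedSequence(master, spawn_key=key).generate_state(1)[0] % (2**31))


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def _population_specs(cfg: dict, master_seed: int) -> dict[str, PopulationSpec]:
    sims = cfg.get("simulation")
    if not sims:
        return default_desk_specs(derive_seed(master_seed, 0))
    specs = {}
    for i, block in enumerate(sims):
        block = dict(block)
        ds_id = str(block.pop("id", f"dataset{i}"))
        block.setdefault("seed", derive_seed(master_seed, 0, i))
        block["n_cells_per_cluster"] = tuple(block["n_cells_per_cluster"])
        specs[ds_id] = PopulationSpec(**block)
    return specs


def _sweep_config(cfg: dict, master_seed: int) -> SweepConfig:
    block = dict(cfg.get("sweep", {}))
    kwargs = {}
    for src, dst in [
        ("pcs", "pcs"),
        ("neighbors", "neighbors"),
        ("resolutions", "resolutions"),
        ("methods", "methods"),
        ("metrics", "metrics"),
    ]:
        if src in block:
            kwargs[dst] = tuple(block[src])
    return SweepConfig(seed=derive_seed(master_seed, 2), **kwargs)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def run_all(cfg: dict, out_dir: str | Path | None = None, seed: int | None = None) -> dict:
    """Execute every stage of the pipeline; returns the manifest."""
    master_seed = int(seed if seed is not None else cfg.get("master_seed", 0))
    out = Path(out_dir or cfg.get("output_dir", "scsweep_run"))
    out.mkdir(parents=True, exist_ok=True)
    pp = {**DESK_DEFAULTS["preprocess"], **cfg.get("preprocess", {})}
    fraction = float(cfg.get("subsample_fraction", DESK_DEFAULTS["subsample_fraction"]))
    n_replicates = int(cfg.get("n_replicates", DESK_DEFAULTS["n_replicates"]))
    analysis = cfg.get("analysis", {})
    manifest: dict = {
        "scsweep_version": __version__,
        "master_seed": master_seed,
        "config_hash": hashlib.sha256(
            json.dumps(_jsonable(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }

    t0 = time.perf_counter()
    specs = _population_specs(cfg, master_seed)
    datasets = {ds_id: generate_dataset(spec, dataset_id=ds_id) for ds_id, spec in specs.items()}
    manifest["stages"]["simulate"] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "datasets": {d: ds.counts.shape for d, ds in datasets.items()},
    }

    t0 = time.perf_counter()
    sweep_cfg = _sweep_config(cfg, master_seed)
    tables = []
    for i, (ds_id, ds) in enumerate(datasets.items()):
        subs = stratified_subsample(
            ds.labels, fraction, n_replicates, derive_seed(master_seed, 1, i), parent_id=ds_id
        )
        tables.append(
            run_sweep(
                ds,
                subs,
                sweep_cfg,
                min_cells=int(pp["min_cells"]),
                target_sum=float(pp["target_sum"]),
                n_hvg=int(pp["n_hvg"]),
            )
        )
    records = pd.concat(tables, ignore_index=True)
    records.to_csv(out / "sweep_records.csv", index=False)
    manifest["stages"]["sweep"] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "n_records": int(len(records)),
        "n_configurations": len(enumerate_grid(sweep_cfg)),
        "n_failed_records": int((records["error"] != "").sum()),
    }

    if analysis.get("effects", True):
        t0 = time.perf_counter()
        _run_effects(records, sweep_cfg, out)
        manifest["stages"]["effects"] = {"seconds": round(time.perf_counter() - t0, 3)}

    if analysis.get("predict", True):
        t0 = time.perf_counter()
        _run_predictor(records, out, master_seed, cross=analysis.get("cross_dataset", True))
        manifest["stages"]["predict"] = {"seconds": round(time.perf_counter() - t0, 3)}

    _write_json(out / "manifest.json", manifest)
    return manifest


def _run_effects(records: pd.DataFrame, sweep_cfg: SweepConfig, out: Path) -> None:
    grid = enumerate_grid(sweep_cfg)
    coef_rows, diagnostics, extremes = [], {}, {}
    for ds_id, sub in records.groupby("dataset_id", sort=True):
        fit, spec = fit_effects_for_records(sub)
        for term in fit.coefficients.index:
            coef_rows.append(
                {
                    "dataset_id": ds_id,
                    "term": term,
                    "estimate": fit.coefficients[term],
                    "robust_se": fit.std_errors[term],
                    "p": fit.p_values[term],
                }
            )
        diagnostics[ds_id] = {
            "bias": fit.bias,
            "rmse": fit.rmse,
            "r2": fit.r2,
            "converged": fit.converged,
            "n_iter": fit.n_iter,
            **residual_normality(fit.residuals),
        }
        ext = extract_extreme_configs(fit, grid, spec)
        extremes[ds_id] = {
            "best": {
                "configuration": ext["best"]["configuration"],
                "predicted": ext["best"]["predicted"],
                "sd": ext["best"]["sd"],
            },
            "worst": {
                "configuration": ext["worst"]["configuration"],
                "predicted": ext["worst"]["predicted"],
                "sd": ext["worst"]["sd"],
            },
        }
    pd.DataFrame(coef_rows).to_csv(out / "effects_coefficients.csv", index=False)
    _write_json(out / "effects_diagnostics.json", diagnostics)
    _write_json(out / "extreme_configs.json", extremes)
    by_dataset = {
        ds_id: sub.loc[np.isfinite(sub["accuracy"].astype(float)), "accuracy"].to_numpy()
        for ds_id, sub in records.groupby("dataset_id", sort=True)
    }
    if len(by_dataset) >= 2 and all(len(v) >= 2 for v in by_dataset.values()):
        report = compare_groups(by_dataset)
        _write_json(
            out / "dataset_comparison.json",
            {
                "kw_statistic": report.kw_statistic,
                "kw_p": report.kw_p,
                "pairwise": [
                    {"pair": list(pair), "z": z, "p_unadj": pu, "p_adj": pa}
                    for pair, z, pu, pa in report.pairwise
                ],
            },
        )


def _run_predictor(records: pd.DataFrame, out: Path, master_seed: int, cross: bool = True) -> None:
    table = clean_feature_table(records)
    coef_rows, validation = [], {}
    intra = {}
    for ds_id, sub in table.groupby("dataset_id", sort=True):
        rep = validate_intra(sub, seed=derive_seed(master_seed, 3))
        intra[ds_id] = {
            "r2_mean": rep.r2_mean,
            "r2_sd": rep.r2_sd,
            "rmse_mean": rep.rmse_mean,
            "rmse_sd": rep.rmse_sd,
        }
    validation["intra_loo"] = intra
    fits = []
    if cross and table["dataset_id"].nunique() >= 2:
        reports, cross_fits = validate_cross(table, seed=derive_seed(master_seed, 4))
        validation["cross_dataset"] = {
            r.per_unit["unit"].iloc[0]: {"r2": r.r2_mean, "rmse": r.rmse_mean} for r in reports
        }
        for held_out, fit in cross_fits.items():
            fits.append(fit)
            for feat, c in fit.coefficients.items():
                coef_rows.append(
                    {"scheme": "cross_dataset", "held_out": held_out, "feature": feat, "coefficient": c}
                )
    _write_json(out / "validation_report.json", validation)
    if coef_rows:
        pd.DataFrame(coef_rows).to_csv(out / "predictor_coefficients.csv", index=False)
    if len(fits) >= 2:
        rank_consistent_features(fits).to_csv(out / "feature_ranking.csv", index=False)
    rho, _, _ = metric_association(table)
    rho.to_csv(out / "metric_correlations.csv")
    linearity_deviation(table).to_csv(out / "linearity_deviation.csv", index=False)
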