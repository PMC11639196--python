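"""End-to-end orchestration: simulate/read -> curate -> covariates -> fit ->
sensitivity outputs, with a manifest of content hashes for reproducibility.

Each stage consumes and produces files under the run directory so stages can
be re-run individually; within :func:`run_all` the in-memory objects are
passed through directly. All randomness flows from the single configured
seed, so a run is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis
from .config import load_config, save_config, validate_config
from .covariates import attach_covariates
from .design import ModelSpec, global_model_spec
from .grid import ClimateGrid
from .model import PhenologySensitivityModel
from .observations import (
    DEFAULT_EXCLUDED_REGIONS,
    filter_observations,
    read_observations,
    validate_observations,
    write_observations,
)
from .ols import aic_select, fit_aim1_climate, fit_aim1_phenology, fit_model
from .synthetic import (
    ClimateGradientParams,
    RegionSpec,
    SensitivityTruth,
    generate_climate_grid,
    generate_observations,
    save_truth,
)

log = logging.getLogger("phenosense")

STAGES = ("simulate", "prepare", "fit", "sensitivity", "report")

#: Named candidate structures for global-model AIC selection. "global" is the
#: final model; the others are simpler structures useful as baselines.
CANDIDATE_SPECS: dict[str, ModelSpec] = {
    "global": global_model_spec(),
    "no_species_interactions": ModelSpec(
        response="doy",
        products=(
            ("t_std", "mat", "ivt"),
            ("p_std", "mat", "ivt"),
            ("phenophase", "mat", "ivt"),
            ("species",),
        ),
    ),
    "additive": ModelSpec(
        response="doy",
        products=(("t_std",), ("p_std",), ("phenophase",), ("species",), ("mat",), ("ivt",)),
    ),
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def stage_simulate(cfg: dict, outdir: Path):
    """Generate the synthetic grid, observations and truth config."""
    synth = cfg["synthetic"]
    if synth is None:
        raise ValueError("stage 'simulate' requires a synthetic config block")
    region = RegionSpec(**{
        k: tuple(v) if k != "lon_bands" else {n: tuple(b) for n, b in v.items()}
        for k, v in (synth.get("region") or {}).items()
    })
    gradients = ClimateGradientParams(**(synth.get("gradients") or {}))
    truth = SensitivityTruth(**(synth.get("truth") or {}))
    seed = cfg["seed"]
    grid = generate_climate_grid(region, gradients, seed=seed)
    obs = generate_observations(
        grid,
        truth,
        n_per_species_continent=synth["n_per_species_continent"],
        seed=seed + 1,
        years=tuple(synth.get("years", (2017, 2019))),
        continent_weights=synth.get("continent_weights"),
        vegetative_fraction=synth.get("vegetative_fraction", 0.0),
    )
    grid.to_netcdf(outdir / "climate.nc")
    write_observations(obs, outdir / "observations.csv")
    save_truth(truth, outdir / "truth.yaml")
    log.info("simulated %d observations on a %dx%d-cell grid",
             len(obs), grid.lats.size, grid.lons.size)
    return grid, obs


def _load_grid_obs(cfg: dict, outdir: Path):
    if cfg["synthetic"] is not None:
        grid_path = outdir / "climate.nc"
        obs_path = outdir / "observations.csv"
        if not grid_path.exists():
            raise FileNotFoundError(f"missing climate file {grid_path}; run 'simulate' first")
    else:
        grid_path = Path(cfg["inputs"]["climate"])
        obs_path = Path(cfg["inputs"]["observations"])
        if not grid_path.exists():
            raise FileNotFoundError(f"missing climate file {grid_path}")
        if not obs_path.exists():
            raise FileNotFoundError(f"missing observation file {obs_path}")
    return ClimateGrid.from_netcdf(grid_path), read_observations(obs_path)


def stage_prepare(cfg: dict, outdir: Path, grid=None, obs=None):
    """Curate observations and attach climate covariates."""
    if grid is None or obs is None:
        grid, obs = _load_grid_obs(cfg, outdir)
    else:
        obs = validate_observations(obs)
    regions = cfg["excluded_regions"]
    if regions is not None:
        regions = {k: tuple(v) for k, v in regions.items()}
    else:
        regions = DEFAULT_EXCLUDED_REGIONS
    curated, report = filter_observations(obs, regions)
    for line in str(report).splitlines():
        log.info("%s", line)
    cov = attach_covariates(curated, grid, grouping=cfg["standardization"])
    log.info("standardization grouping: %s", cfg["standardization"])

    report.to_frame().to_csv(outdir / "exclusion_report.csv", index=False)
    (outdir / "exclusion_report.txt").write_text(str(report) + "\n")
    cov.to_csv(outdir / "covariates.csv", index=False)
    return grid, cov


def stage_fit(cfg: dict, outdir: Path, cov: pd.DataFrame | None = None):
    """Fit Aim-1 models and the global model (with AIC selection if asked)."""
    if cov is None:
        path = outdir / "covariates.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing covariate table {path}; run 'prepare' first")
        cov = pd.read_csv(path)

    aim1 = fit_aim1_climate(cov)
    aim1["phenology"] = fit_aim1_phenology(cov)
    aim1_rows = []
    for name, fm in aim1.items():
        tab = fm.coef_table()
        tab.insert(0, "model", name)
        aim1_rows.append(tab)
    pd.concat(aim1_rows, ignore_index=True).to_csv(outdir / "aim1_coefficients.csv", index=False)

    names = cfg["model"]["candidates"]
    unknown = [n for n in names if n not in CANDIDATE_SPECS]
    if unknown:
        raise ValueError(f"unknown candidate model(s) {unknown}; known: {sorted(CANDIDATE_SPECS)}")
    if len(names) >= 2:
        table, best = aic_select(cov, {n: CANDIDATE_SPECS[n] for n in names})
        table.to_csv(outdir / "aic_table.csv", index=False)
        for _, r in table.iterrows():
            log.info("AIC %-28s %12.2f (delta %.2f)", r["model"], r["aic"], r["delta_aic"])
    else:
        best = fit_model(cov, CANDIDATE_SPECS[names[0]])
        pd.DataFrame(
            {"model": names, "k": [len(best.params)], "aic": [best.aic],
             "r_squared_adj": [best.r_squared_adj], "delta_aic": [0.0]}
        ).to_csv(outdir / "aic_table.csv", index=False)

    best.coef_table().to_csv(outdir / "coefficients.csv", index=False)
    _write_json(best.fit_stats(), outdir / "fit_stats.json")
    log.info("global fit: n=%d df=%d adjR2=%.3f AIC=%.1f",
             best.nobs, best.df_resid, best.r_squared_adj, best.aic)

    est = PhenologySensitivityModel()
    est.result_ = best
    est.coef_, est.aic_ = best.params, best.aic
    est.r_squared_adj_, est.df_resid_, est.n_obs_ = (
        best.r_squared_adj, best.df_resid, best.nobs,
    )
    return est, cov


def stage_sensitivity(cfg: dict, outdir: Path, est=None, cov=None):
    """Aim-2/Aim-3 outputs: surfaces, map, ranges, trends, precipitation."""
    if est is None or cov is None:
        est, cov = stage_fit(cfg, outdir, cov)
    g = cfg["grids"]

    surface = est.sensitivity_surface(
        mat_range=tuple(g["surface"]["mat_range"]), mat_step=g["surface"]["mat_step"],
        ivt_range=tuple(g["surface"]["ivt_range"]), ivt_step=g["surface"]["ivt_step"],
    )
    surface.to_csv(outdir / "surface.csv")
    by_sp = est.sensitivity_surface(
        mat_range=tuple(g["summary"]["mat_range"]), mat_step=g["summary"]["mat_step"],
        ivt_range=tuple(g["summary"]["ivt_range"]), ivt_step=g["summary"]["ivt_step"],
        by_species=True,
    )
    by_sp.to_csv(outdir / "surface_by_species.csv")

    est.map_sensitivity(cov).to_csv(outdir / "sensitivity_map.csv", index=False)

    intra = est.intraspecific_range(
        mat_range=tuple(g["summary"]["mat_range"]), mat_step=g["summary"]["mat_step"],
        ivt_range=tuple(g["summary"]["ivt_range"]), ivt_step=g["summary"]["ivt_step"],
    )
    intra["surface"].to_csv(outdir / "summary_surface.csv")
    sp_table, inter, sp_pairs = est.interspecific_range()
    sp_table.to_csv(outdir / "interspecific.csv", index=False)
    sp_pairs.to_csv(outdir / "interspecific_contrasts.csv", index=False)

    baseline = est.baseline_sensitivity()
    trends = est.mat_trend_profile(ivt_levels=tuple(cfg["ivt_levels"]))
    trends.to_csv(outdir / "mat_trends.csv", index=False)
    precip = est.precipitation_sensitivity()

    ranges = {
        "baseline_sensitivity": {"slope": baseline.slope, "se": baseline.se, "p": baseline.p},
        "intraspecific": {k: v for k, v in intra.items() if k != "surface"},
        "interspecific": inter,
        "precipitation": {"slope": precip.slope, "se": precip.se, "p": precip.p},
        "provenance": analysis.model_hash(est.result_),
    }
    _write_json(ranges, outdir / "ranges.json")
    log.info("baseline sensitivity %.2f days/degC; intraspecific range %.2f; "
             "interspecific range %.2f", baseline.slope, intra["range"], inter["range"])
    return ranges


def stage_report(cfg: dict, outdir: Path) -> Path:
    """Assemble a human-readable run summary from stage outputs."""
    parts = [f"# phenosense run report\n\nseed: {cfg['seed']}\n"]
    excl = outdir / "exclusion_report.txt"
    if excl.exists():
        parts.append("## Curation\n\n```\n" + excl.read_text() + "```\n")
    aic = outdir / "aic_table.csv"
    if aic.exists():
        parts.append("## Model selection (AIC)\n\n" + pd.read_csv(aic).to_string(index=False) + "\n")
    stats = outdir / "fit_stats.json"
    if stats.exists():
        parts.append("## Global fit\n\n```json\n" + stats.read_text() + "```\n")
    ranges = outdir / "ranges.json"
    if ranges.exists():
        parts.append("## Sensitivity summaries\n\n```json\n" + ranges.read_text() + "```\n")
    path = outdir / "report.md"
    path.write_text("\n".join(parts))
    return path


def write_manifest(cfg: dict, outdir: Path) -> Path:
    entries = {}
    for p in sorted(outdir.iterdir()):
        # config.resolved.yaml embeds the output path itself; hashing it would
        # make otherwise-identical runs into different directories disagree.
        if p.name in ("manifest.json", "run.log", "config.resolved.yaml") or p.is_dir():
            continue
        entries[p.name] = {"sha256": _sha256(p), "bytes": p.stat().st_size}
    manifest = {"seed": cfg["seed"], "outputs": entries}
    _write_json(manifest, outdir / "manifest.json")
    return outdir / "manifest.json"


def run_all(config: dict | str | Path, outdir=None, seed: int | None = None,
            stage: str | None = None) -> Path:
    """Execute the pipeline (or one stage) and write the output manifest."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else validate_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(outdir if outdir is not None else cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    cfg["outdir"] = str(out)
    save_config(cfg, out / "config.resolved.yaml")
    if stage is not None and stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")

    current = stage or "simulate"
    try:
        if stage is None:
            grid = obs = None
            if cfg["synthetic"] is not None:
                grid, obs = stage_simulate(cfg, out)
            current = "prepare"
            grid, cov = stage_prepare(cfg, out, grid, obs)
            current = "fit"
            est, cov = stage_fit(cfg, out, cov)
            current = "sensitivity"
            stage_sensitivity(cfg, out, est, cov)
            current = "report"
            stage_report(cfg, out)
        elif stage == "simulate":
            stage_simulate(cfg, out)
        elif stage == "prepare":
            stage_prepare(cfg, out)
        elif stage == "fit":
            stage_fit(cfg, out)
        elif stage == "sensitivity":
            stage_sensitivity(cfg, out)
        elif stage == "report":
            stage_report(cfg, out)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc
    write_manifest(cfg, out)
    return out
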