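"""End-to-end orchestration: simulate -> kernel -> covariates -> fit -> rank.

One structured config drives the whole analysis.  A single top-level seed
fans out to per-stage child seeds by stable hashing of the stage name, so
inserting a stage never perturbs the randomness of earlier ones.  Stages
write headered CSVs plus JSON sidecars; a sidecar records a content hash of
the stage's inputs, and a re-run reuses the cached output only when that
hash matches.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov_mod
from . import kernel as kernel_mod
from . import model as model_mod
from . import simulate as sim_mod
from . import synchrony as sync_mod

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RankingReport", "run_pipeline", "validate_inputs",
           "child_seed", "DEFAULT_LADDER", "make_spec"]

#: Baseline-to-full model ladder: independent NB regression, smoothing-only
#: spatiotemporal model, spatiotemporal model with covariates, the same plus
#: coordinate covariates, and the RW1 temporal alternative.
DEFAULT_LADDER = ("independent", "st_no_covariates", "st_covariates",
                  "st_covariates_xy", "st_rw1_xy")


def make_spec(name: str, covariates=cov_mod.DEFAULT_COVARIATES) -> model_mod.ModelSpec:
    """Named entries of the model ladder."""
    covariates = tuple(covariates)
    xy = covariates + tuple(c for c in ("x", "y", "xy") if c not in covariates)
    table = {
        "independent": dict(covariates=covariates, spatial_process="none",
                            temporal_process="none"),
        "st_no_covariates": dict(covariates=(), spatial_process="matern",
                                 temporal_process="AR1"),
        "st_covariates": dict(covariates=covariates, spatial_process="matern",
                              temporal_process="AR1"),
        "st_covariates_xy": dict(covariates=xy, spatial_process="matern",
                                 temporal_process="AR1"),
        "st_rw1_xy": dict(covariates=xy, spatial_process="matern",
                          temporal_process="RW1"),
    }
    if name not in table:
        raise ValueError(f"unknown model name {name!r}; choose from {sorted(table)}")
    return model_mod.ModelSpec(name=name, **table[name])


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2 ** 31 - 1)


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    simulate: dict | None = None          # GenerativeConfig overrides (demo mode)
    inputs: dict | None = None            # paths: census, nests, cones
    kernel_grid: bool = True              # AIC-select the kernel shape
    kernel_params: dict | None = None     # fixed shape instead of the grid
    covariates: tuple = cov_mod.DEFAULT_COVARIATES
    models: tuple = ("independent", "st_no_covariates", "st_covariates")
    correlogram: dict = dc_field(default_factory=lambda: dict(
        bin_width_km=20.0, max_dist_km=750.0, min_pairs=10))
    fit_options: dict = dc_field(default_factory=dict)
    use_cache: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)


@dataclass
class RankingReport:
    waic_table: pd.DataFrame     # model, waic, n_covariates, ascending WAIC
    best_model: str
    coefficients: pd.DataFrame   # coefficient table of the best model
    range_km: float
    range_sd: float
    kernel_selection: pd.DataFrame | None
    correlogram_files: dict
    fits: dict


# --------------------------------------------------------------------- #
# validation

_CENSUS_COLUMNS = ("triangle_id", "triangle_type", "x_km", "y_km", "length_km",
                   "year", "censused")


def validate_inputs(tables: dict) -> dict:
    """Schema check of the input tables; returns a diagnostics report.

    Violations carry the offending table, row number and reason.  The report
    also counts valid censuses (the snow-condition validity rule is encoded
    upstream in the ``censused`` flag: only flagged rows are analysable).
    """
    violations = []

    def bad(table, idx, reason):
        violations.append({"table": table, "row": int(idx), "reason": reason})

    census = tables.get("census")
    if census is not None:
        for col in _CENSUS_COLUMNS:
            if col not in census.columns:
                violations.append({"table": "census", "row": -1,
                                   "reason": f"missing column {col}"})
        if not violations:
            type_len = {"wildlife": 12.0, "field": 6.0}
            for idx, row in census.iterrows():
                t = row["triangle_type"]
                if t not in type_len:
                    bad("census", idx, f"unknown triangle_type {t!r}")
                elif float(row["length_km"]) != type_len[t]:
                    bad("census", idx,
                        f"{t} triangle with length {row['length_km']} km")
                for col in ("squirrel_tracks", "marten_tracks"):
                    v = row.get(col)
                    if pd.notna(v) and (float(v) < 0 or float(v) != int(v)):
                        bad("census", idx, f"{col} is not a non-negative integer")
            fixed = census.groupby("triangle_id")[["x_km", "y_km"]].nunique()
            for tid in fixed.index[(fixed > 1).any(axis=1)]:
                bad("census", -1, f"triangle {tid} moves between years")
    nests = tables.get("nests")
    if nests is not None:
        for idx, row in nests.iterrows():
            if not np.isfinite(row["x_km"]) or not np.isfinite(row["y_km"]):
                bad("nests", idx, "non-finite coordinates")
    cones = tables.get("cones")
    if cones is not None:
        vals = cones["cones_per_tree"]
        for idx in cones.index[vals.notna() & (vals < 0)]:
            bad("cones", idx, "negative cone count")

    n_rows = len(census) if census is not None else 0
    n_valid = int(census["censused"].sum()) if census is not None and "censused" in census else 0
    return {"violations": violations, "n_census_rows": n_rows,
            "n_valid_censuses": n_valid, "ok": not violations}


# --------------------------------------------------------------------- #
# pipeline

def _hash_frames(*frames) -> str:
    h = hashlib.sha256()
    for f in frames:
        if isinstance(f, pd.DataFrame):
            h.update(pd.util.hash_pandas_object(f, index=False).to_numpy().tobytes())
        else:
            h.update(json.dumps(f, sort_keys=True, default=str).encode())
    return h.hexdigest()


def _cached(out: Path, stage: str, input_hash: str, use_cache: bool):
    sidecar = out / f"{stage}.hash.json"
    if use_cache and sidecar.exists():
        try:
            meta = json.loads(sidecar.read_text())
            if meta.get("input_hash") == input_hash:
                return sidecar, True
        except (json.JSONDecodeError, OSError):
            pass
    return sidecar, False


def _mark(sidecar: Path, input_hash: str):
    sidecar.write_text(json.dumps({"input_hash": input_hash}))


def run_pipeline(config: PipelineConfig) -> RankingReport:
    """Execute every stage in dependency order and rank the model ladder."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.models:
        raise ValueError("model list must be non-empty")

    # ---- stage: data (simulate or load) ------------------------------ #
    if config.simulate is not None:
        gen_kwargs = dict(config.simulate)
        region_kwargs = gen_kwargs.pop("region", {})
        if "kernel_params" in gen_kwargs:
            gen_kwargs["kernel_params"] = kernel_mod.KernelParams(**gen_kwargs["kernel_params"])
        if "failure_years" in gen_kwargs:
            gen_kwargs["failure_years"] = frozenset(gen_kwargs["failure_years"])
        gen_kwargs.setdefault("seed", child_seed(config.seed, "simulate"))
        gen = sim_mod.GenerativeConfig(**gen_kwargs)
        region = sim_mod.StudyRegion(**region_kwargs)
        ihash = _hash_frames(gen.to_json_dict(), dataclasses.asdict(region))
        sidecar, hit = _cached(out, "simulate", ihash, config.use_cache)
        if hit and all((out / f).exists() for f in ("census.csv", "nests.csv", "cones.csv")):
            logger.info("simulate: cache hit, reusing tables")
            census = pd.read_csv(out / "census.csv")
            nests = pd.read_csv(out / "nests.csv")
            cones = pd.read_csv(out / "cones.csv")
        else:
            logger.info("simulate: generating synthetic data (seed %d)", gen.seed)
            data = sim_mod.simulate_dataset(gen, region)
            census, nests, cones = data["census"], data["nests"], data["cones"]
            census.to_csv(out / "census.csv", index=False)
            nests.to_csv(out / "nests.csv", index=False)
            cones.to_csv(out / "cones.csv", index=False)
            (out / "truth.json").write_text(json.dumps(data["truth"], indent=1))
            _mark(sidecar, ihash)
        southern_cut = region.southern_cut_y_km
        failure_years = gen.failure_years
    elif config.inputs is not None:
        for key in ("census", "nests", "cones"):
            p = Path(config.inputs[key])
            if not p.exists():
                raise FileNotFoundError(f"input file for {key!r} not found: {p}")
        census = pd.read_csv(config.inputs["census"])
        nests = pd.read_csv(config.inputs["nests"])
        cones = pd.read_csv(config.inputs["cones"])
        southern_cut = float(config.inputs.get("southern_cut_y_km", 420.0))
        failure_years = sim_mod.DEFAULT_FAILURE_YEARS
    else:
        raise ValueError("config needs either 'simulate' or 'inputs'")

    report = validate_inputs({"census": census, "nests": nests, "cones": cones})
    (out / "validation.json").write_text(json.dumps(report, indent=1))
    if not report["ok"]:
        raise ValueError(
            f"input validation failed with {len(report['violations'])} violation(s); "
            f"see {out / 'validation.json'}")

    # ---- stage: kernel ------------------------------------------------ #
    kernel_selection = None
    if config.kernel_params is not None:
        best = kernel_mod.KernelParams(**config.kernel_params)
    elif config.kernel_grid:
        sel = kernel_mod.select_kernel_params(census, nests)
        kernel_selection = sel.table
        sel.table.to_csv(out / "kernel_selection.csv", index=False)
        best = sel.best
        logger.info("kernel: selected flat_top=%.1f km sd=%.1f km (dAIC=%.2f)",
                    best.flat_top_km, best.sd_km, sel.delta_to_second)
    else:
        best = kernel_mod.KernelParams()
    kcov = kernel_mod.kernel_covariate(census, nests, best)
    kcov.to_csv(out / "kernel_covariate.csv", index=False)

    # ---- stage: covariates -------------------------------------------- #
    design = cov_mod.assemble_design(
        census, kcov, cones, covariates=config.covariates,
        include_xy=any(m.endswith("xy") for m in config.models),
        southern_cut_y_km=southern_cut, failure_years=failure_years)
    design.data.to_csv(out / "design.csv", index=False)
    (out / "design_meta.json").write_text(json.dumps({
        "scaling": design.scaling,
        "n_rows": len(design.data),
        "dropped": design.drops.to_dict("records") if design.drops is not None else [],
    }, indent=1))

    # ---- stage: fits --------------------------------------------------- #
    fits = {}
    rows = []
    for name in config.models:
        spec = make_spec(name, config.covariates)
        logger.info("fit: %s", name)
        f = model_mod.fit(design, spec, seed=child_seed(config.seed, f"fit:{name}"),
                          **config.fit_options)
        fits[name] = f
        f.coefficient_table().to_csv(out / f"coefficients_{name}.csv", index=False)
        (out / f"hyper_{name}.json").write_text(json.dumps(
            dataclasses.asdict(f.hyper), indent=1))
        rows.append({"model": name, "waic": f.waic,
                     "n_covariates": len(f.spec.covariates)})
    waic_table = (pd.DataFrame(rows)
                  .sort_values(["waic", "n_covariates"], kind="stable")
                  .reset_index(drop=True))
    waic_table.to_csv(out / "waic_ranking.csv", index=False)
    best_name = waic_table.iloc[0]["model"]
    best_fit = fits[best_name]
    best_fit.fitted.to_csv(out / "fitted.csv", index=False)
    model_mod.spatial_residuals(best_fit).to_csv(out / "residuals.csv", index=False)

    if best_fit.spec.spatial_process == "matern":
        rng_km, rng_sd = model_mod.extract_range(best_fit)
    else:
        spatial = [n for n in fits if fits[n].spec.spatial_process == "matern"]
        rng_km, rng_sd = (model_mod.extract_range(fits[spatial[0]])
                          if spatial else (np.nan, np.nan))

    # ---- stage: correlograms ------------------------------------------- #
    cg_files = {}
    cens_rows = census[census["censused"].astype(bool)].copy()
    panels = {
        "squirrel_density": cens_rows.assign(
            value=cov_mod.track_density(
                cens_rows["squirrel_tracks"].to_numpy(dtype=float),
                cens_rows["length_km"])),
        "marten_density": cens_rows.assign(
            value=cov_mod.track_density(
                cens_rows["marten_tracks"].to_numpy(dtype=float),
                cens_rows["length_km"])),
        "cone_crop": cones.rename(columns={"cones_per_tree": "value"}),
        "goshawk_kernel": kcov.merge(
            census[["triangle_id", "year", "x_km", "y_km"]].drop_duplicates(),
            on=["triangle_id", "year"]).rename(columns={"kernel_value": "value"}),
    }
    cg_kwargs = dict(config.correlogram)
    for name, panel in panels.items():
        try:
            cg = sync_mod.correlogram(panel, **cg_kwargs)
        except ValueError as exc:
            logger.warning("correlogram %s skipped: %s", name, exc)
            continue
        path = out / f"correlogram_{name}.csv"
        cg.table.to_csv(path, index=False)
        cg_files[name] = str(path)

    report = RankingReport(
        waic_table=waic_table, best_model=best_name,
        coefficients=best_fit.coefficient_table(),
        range_km=float(rng_km), range_sd=float(rng_sd),
        kernel_selection=kernel_selection, correlogram_files=cg_files,
        fits=fits)
    summary = {
        "best_model": best_name,
        "waic": waic_table.to_dict("records"),
        "range_km": report.range_km,
        "range_sd": report.range_sd,
    }
    (out / "ranking.json").write_text(json.dumps(summary, indent=1))
    return report
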