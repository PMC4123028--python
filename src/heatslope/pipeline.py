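"""Configuration, file I/O and stage orchestration.

A run is described by a :class:`RunConfig` (serializable to YAML) and
executed stage by stage by :func:`run_pipeline`: ``simulate`` writes a
synthetic study (areas, weather, holiday calendar, admissions panel, ground
truth), ``design`` builds the exposure series and the temporal/spatial
design, ``fit1``/``fit2``/``fit3`` run the three models, and ``summarize``
writes the report tables (percent change per 10 degC, area slope table,
modifier table, Moran's I).  Each run leaves a manifest recording the
config hash, seed, package versions, per-stage row counts and any warnings,
so every output is reproducible from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import bayesfit, summarize, synthdata, tempdesign

__all__ = ["RunConfig", "McmcConfig", "run_pipeline", "read_inputs", "PipelineError"]

STAGES = ("simulate", "design", "fit1", "fit2", "fit3", "summarize")

logger = logging.getLogger("heatslope")
if not logger.handlers:
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(h)
    logger.setLevel(logging.INFO)


class PipelineError(RuntimeError):
    """A missing upstream artifact or invalid input file."""


class McmcConfig(BaseModel):
    burn_in: int = Field(2000, gt=0)
    samples: int = Field(2000, gt=0)
    chains: int = Field(4, gt=0)
    leapfrog_steps: int = Field(8, gt=0)

    def settings(self, seed: int) -> bayesfit.McmcSettings:
        return bayesfit.McmcSettings(
            burn_in=self.burn_in,
            samples=self.samples,
            chains=self.chains,
            leapfrog_steps=self.leapfrog_steps,
            seed=seed,
        )


class RunConfig(BaseModel):
    """Validated run configuration; round-trips through YAML."""

    outdir: str = "results/run"
    seed: int = 0
    # synthetic study dimensions
    n_areas: int = Field(158, ge=2)
    start_date: str = "2007-01-01"
    end_date: str = "2011-12-31"
    citywide_daily_mean: float = Field(193.0, gt=0)
    # optional external inputs (read instead of simulating)
    panel_path: str | None = None
    weather_path: str | None = None
    areas_path: str | None = None
    calendar_path: str | None = None
    # design choices
    lag: int = Field(1, ge=0)
    knots_per_season: int = Field(5, ge=1)
    spatial_df: int = Field(2, ge=1)
    # models
    mcmc_model1: McmcConfig = McmcConfig(burn_in=5000, samples=5000)
    mcmc_area: McmcConfig = McmcConfig(burn_in=2000, samples=2000)
    modifiers: list[str] = Field(default_factory=lambda: ["pop_density"])
    modifier_units: dict[str, float] = Field(
        default_factory=lambda: {"pop_density": 1000.0, "pct_high_income": 1.0}
    )
    weights_k: int = Field(5, ge=1)
    n_perm: int = Field(999, ge=1)
    missing_warn_threshold: float = Field(0.01, ge=0, le=1)

    @field_validator("start_date", "end_date")
    @classmethod
    def _parseable(cls, v):
        pd.Timestamp(v)
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _read_csv_dates(path, **kw) -> pd.DataFrame:
    df = pd.read_csv(path, **kw)
    if "date" in df.columns:
        try:
            df["date"] = pd.to_datetime(df["date"], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise PipelineError(f"{path}: unparseable dates ({exc})") from exc
    return df


def read_inputs(config: RunConfig, outdir: Path | None = None):
    """Read and validate the four input tables.

    Paths come from the config; for simulated runs they default to the
    files the ``simulate`` stage wrote under the output directory.  Returns
    ``(panel, weather, areas, calendar)``.
    """
    outdir = Path(outdir or config.outdir)

    def resolve(explicit, name):
        p = Path(explicit) if explicit else outdir / f"{name}.csv"
        if not p.exists():
            raise PipelineError(f"missing upstream artifact: {p} ({name})")
        return p

    panel = _read_csv_dates(resolve(config.panel_path, "panel"))
    weather = _read_csv_dates(resolve(config.weather_path, "weather"))
    areas = pd.read_csv(resolve(config.areas_path, "areas"))
    calendar = _read_csv_dates(resolve(config.calendar_path, "calendar"))

    for col in ("date", "area_id", "count"):
        if col not in panel.columns:
            raise PipelineError(f"panel is missing column {col!r}")
    dup = panel.duplicated(["date", "area_id"])
    if dup.any():
        bad = panel.loc[dup, ["date", "area_id"]].head(5).to_dict("records")
        raise PipelineError(f"panel has duplicate (date, area_id) rows: {bad}")
    counts = panel["count"].to_numpy()
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        bad = panel[(panel["count"] < 0)].head(5).to_dict("records")
        raise PipelineError(f"panel counts must be non-negative integers: {bad}")
    panel["count"] = panel["count"].astype(int)

    if areas["area_id"].duplicated().any():
        raise PipelineError("areas table has duplicate area_id values")
    if (areas["population"] <= 0).any():
        raise PipelineError("area populations must be positive")

    frac_missing = float(weather["tmax"].isna().mean())
    if frac_missing > config.missing_warn_threshold:
        warnings.warn(
            f"weather series is {100 * frac_missing:.1f}% missing "
            f"(threshold {100 * config.missing_warn_threshold:.1f}%)",
            UserWarning,
        )
        logger.warning("weather missingness %.2f%%", 100 * frac_missing)
    return panel, weather, areas, calendar


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, outdir: Path, manifest: dict):
    rng_seed = config.seed
    areas = synthdata.gen_area_frame(config.n_areas, seed=rng_seed)
    weather = synthdata.gen_weather(config.start_date, config.end_date, seed=rng_seed + 1)
    years = range(pd.Timestamp(config.start_date).year, pd.Timestamp(config.end_date).year + 1)
    calendar = synthdata.gen_holiday_calendar(list(years))
    truth = synthdata.calibrate_alpha(
        synthdata.SimulationTruth(), areas, weather, calendar,
        target_citywide_mean=config.citywide_daily_mean,
    )
    sim = synthdata.simulate_admissions(
        areas, weather, calendar, truth, seed=rng_seed + 2
    )
    areas.to_csv(outdir / "areas.csv", index=False)
    weather.assign(date=weather["date"].dt.date).to_csv(outdir / "weather.csv", index=False)
    calendar.assign(date=pd.to_datetime(calendar["date"]).dt.date).to_csv(
        outdir / "calendar.csv", index=False
    )
    sim.panel.assign(date=pd.to_datetime(sim.panel["date"]).dt.date).to_csv(
        outdir / "panel.csv", index=False
    )
    pd.DataFrame(
        {"area_id": sim.gamma_k.index, "gamma_k": sim.gamma_k.values, "pi_k": sim.pi_k.values}
    ).to_csv(outdir / "truth_area_effects.csv", index=False)
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "alpha": float(truth.alpha),
                "gamma_star": float(truth.gamma_star),
                "sigma_gamma": float(truth.sigma_gamma),
                "lambda": float(truth.lambda_),
                "sigma_pi": float(truth.sigma_pi),
                "holiday_effects": {k: float(v) for k, v in truth.holiday_effects.items()},
                "dow_effects": [float(v) for v in truth.dow_effects],
                "seasonal_amplitude": float(truth.seasonal_amplitude),
            },
            fh,
        )
    manifest["stages"]["simulate"] = {
        "areas": len(areas), "weather_days": len(weather), "panel_rows": len(sim.panel)
    }


def _stage_design(config: RunConfig, outdir: Path, manifest: dict):
    _, weather, areas, calendar = read_inputs(config, outdir)
    exposure = tempdesign.lagged_exposure(weather, lag=config.lag)
    design = tempdesign.temporal_design(
        weather["date"], calendar, interior_knots_per_season=config.knots_per_season
    )
    basis = tempdesign.spatial_basis(areas, df_per_direction=config.spatial_df)
    exposure.assign(date=exposure["date"].dt.date).to_csv(outdir / "exposure.csv", index=False)
    design.assign(date=design["date"].dt.date).to_csv(outdir / "design.csv", index=False)
    basis.to_csv(outdir / "spatial_basis.csv", index=False)
    manifest["stages"]["design"] = {
        "design_rows": len(design),
        "design_cols": len(tempdesign.design_columns(design)),
        "seasons": int(design["season_id"].nunique()),
    }


def _require(outdir: Path, names):
    for n in names:
        if not (outdir / n).exists():
            raise PipelineError(f"missing upstream artifact: {outdir / n}")


def _load_design(outdir: Path):
    design = _read_csv_dates(outdir / "design.csv")
    exposure = _read_csv_dates(outdir / "exposure.csv")
    basis = pd.read_csv(outdir / "spatial_basis.csv")
    return design, exposure, basis


def _stage_fit1(config: RunConfig, outdir: Path, manifest: dict):
    _require(outdir, ["design.csv", "exposure.csv"])
    panel, _, areas, _ = read_inputs(config, outdir)
    design, exposure, _ = _load_design(outdir)
    fit = bayesfit.fit_model1(
        panel, design, exposure,
        total_population=float(areas["population"].sum()),
        mcmc=config.mcmc_model1.settings(config.seed + 10),
    )
    fit.to_long_frame().to_csv(outdir / "draws_model1.csv", index=False)
    pct = summarize.percent_change(fit.stacked("gamma"))
    with open(outdir / "model1_summary.json", "w") as fh:
        json.dump(
            {
                "pct_per_10C": pct,
                "rhat_gamma": fit.rhat("gamma"),
                "accept_rate": fit.accept_rate,
            },
            fh, indent=2,
        )
    manifest["stages"]["fit1"] = {"draws": int(fit.stacked("gamma").shape[0])}


def _stage_fit2(config: RunConfig, outdir: Path, manifest: dict):
    _require(outdir, ["design.csv", "exposure.csv", "spatial_basis.csv"])
    panel, _, areas, _ = read_inputs(config, outdir)
    design, exposure, basis = _load_design(outdir)
    fit = bayesfit.fit_model2(
        panel, design, exposure, areas, basis,
        mcmc=config.mcmc_area.settings(config.seed + 20),
    )
    fit.to_long_frame().to_csv(outdir / "draws_model2.csv", index=False)
    manifest["stages"]["fit2"] = {
        "areas": len(fit.area_ids), "rhat_mu_gamma": fit.rhat("mu_gamma")
    }


def _stage_fit3(config: RunConfig, outdir: Path, manifest: dict):
    _require(outdir, ["design.csv", "exposure.csv", "spatial_basis.csv"])
    panel, _, areas, _ = read_inputs(config, outdir)
    design, exposure, basis = _load_design(outdir)
    for i, mod in enumerate(config.modifiers):
        fit = bayesfit.fit_model3(
            panel, design, exposure, areas, basis, modifier_name=mod,
            mcmc=config.mcmc_area.settings(config.seed + 30 + i),
        )
        fit.to_long_frame().to_csv(outdir / f"draws_model3_{mod}.csv", index=False)
    manifest["stages"]["fit3"] = {"modifiers": list(config.modifiers)}


def _stage_summarize(config: RunConfig, outdir: Path, manifest: dict):
    _require(outdir, ["model1_summary.json"])
    panel, _, areas, _ = read_inputs(config, outdir)
    with open(outdir / "model1_summary.json") as fh:
        m1 = json.load(fh)
    citywide = bayesfit.aggregate_citywide(panel)
    mean_rate = float(citywide["count"].mean())
    report = {
        "mean_daily_admissions": mean_rate,
        "pct_per_10C": m1["pct_per_10C"],
        "extra_admissions_per_day": round(
            summarize.extra_admissions(mean_rate, m1["pct_per_10C"]["median"]), 1
        ),
    }
    if (outdir / "draws_model2.csv").exists():
        draws2 = pd.read_csv(outdir / "draws_model2.csv")
        gk = draws2[draws2["parameter"].str.startswith("gamma_k[")]
        med = gk.groupby("parameter")["value"].median()
        ids = [p[len("gamma_k[") : -1] for p in med.index]
        by_area = pd.Series(med.values, index=ids)
        lo = gk.groupby("parameter")["value"].quantile(0.025).values
        hi = gk.groupby("parameter")["value"].quantile(0.975).values
        tab = pd.DataFrame(
            {
                "area_id": ids,
                "pct_per_10C": 100 * (np.exp(10 * by_area.values) - 1),
                "cri_low": 100 * (np.exp(10 * lo) - 1),
                "cri_high": 100 * (np.exp(10 * hi) - 1),
            }
        )
        tab["signif"] = np.where(
            tab["cri_low"] > 0, "positive", np.where(tab["cri_high"] < 0, "negative", "null")
        )
        tab.to_csv(outdir / "area_slope_table.csv", index=False)
        report["n_significant_positive"] = int((tab["signif"] == "positive").sum())
        report["n_significant_negative"] = int((tab["signif"] == "negative").sum())
        ordered = areas.set_index("area_id").loc[tab["area_id"]]
        W, spec = summarize.knn_weights(
            ordered[["centroid_ew", "centroid_ns"]].to_numpy(), k=config.weights_k
        )
        mres = summarize.morans_i(
            tab["pct_per_10C"].to_numpy(), W, n_perm=config.n_perm,
            seed=config.seed + 40, weights_spec=spec,
        )
        report["morans_I"] = {"I": mres.I, "p_value": mres.p_value, "weights": spec}
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(report, fh, indent=2)
    manifest["stages"]["summarize"] = {"report_keys": sorted(report)}


_STAGE_FN = {
    "simulate": _stage_simulate,
    "design": _stage_design,
    "fit1": _stage_fit1,
    "fit2": _stage_fit2,
    "fit3": _stage_fit3,
    "summarize": _stage_summarize,
}


def run_pipeline(config: RunConfig, stages=("simulate", "design", "fit1", "summarize")):
    """Execute the requested stages in canonical order; returns the manifest.

    Stage outputs land under ``config.outdir``; the manifest (config hash,
    seed, versions, per-stage row counts, timing) is written alongside them.
    Identical config + seed reproduce byte-identical tables.
    """
    bad = set(stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "timing_s": {},
    }
    config.to_yaml(outdir / "config.yaml")
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.time()
        logger.info("stage %s: starting", stage)
        _STAGE_FN[stage](config, outdir, manifest)
        manifest["timing_s"][stage] = round(time.time() - t0, 2)
        logger.info("stage %s: done in %.1fs", stage, manifest["timing_s"][stage])
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
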