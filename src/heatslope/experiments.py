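"""Canned simulation studies used by the analysis drivers and the
acceptance checks.

Each function wires the generator, the design builders and one of the model
fits into a single parameter-recovery experiment at a stated problem size,
so the same code path serves interactive scripts, tests and reproducibility
runs.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import bayesfit, summarize, synthdata, tempdesign

__all__ = [
    "citywide_model1_study",
    "headline_recovery",
    "area_study",
    "BRISBANE_POPULATION",
]

#: Total study-region population behind the citywide offset.
BRISBANE_POPULATION = 956_130.0


def _one_area_frame(population: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "area_id": ["CITY"],
            "population": [population],
            "centroid_ew": [0.5],
            "centroid_ns": [0.5],
            "pop_density": [1670.0],
            "pct_high_income": [5.95],
            "pct_over65": [13.0],
            "pct_low_income": [12.0],
        }
    )


def citywide_model1_study(
    seed: int,
    start: str = "2007-01-01",
    end: str = "2011-12-31",
    daily_mean: float = 193.0,
    gamma: float = synthdata.HEADLINE_SLOPE,
):
    """Simulate a citywide study from the model-1 generative process.

    Five calendar years of Brisbane-like weather; the warm seasons
    (October-March) carry roughly 910 usable days.  Counts follow a single
    Poisson series with holiday/day-of-week/seasonal effects at the
    generator defaults, a citywide baseline of ``daily_mean`` admissions per
    day and the given temperature slope; the area-level random effects are
    off, as model 1 assumes.
    """
    areas = _one_area_frame(BRISBANE_POPULATION)
    weather = synthdata.gen_weather(start, end, seed=seed)
    years = range(pd.Timestamp(start).year - 1, pd.Timestamp(end).year + 2)
    calendar = synthdata.gen_holiday_calendar(list(years))
    truth = replace(
        synthdata.SimulationTruth(gamma_star=gamma, sigma_gamma=0.0, sigma_pi=0.0),
        spatial_coeffs={"ew": (0.0, 0.0), "ns": (0.0, 0.0)},
    )
    truth = synthdata.calibrate_alpha(truth, areas, weather, calendar, daily_mean)
    sim = synthdata.simulate_admissions(areas, weather, calendar, truth, seed=seed + 1)
    design = tempdesign.temporal_design(weather["date"], calendar)
    exposure = tempdesign.lagged_exposure(weather)
    return {
        "sim": sim,
        "truth": truth,
        "areas": areas,
        "design": design,
        "exposure": exposure,
    }


def headline_recovery(seed: int, mcmc: bayesfit.McmcSettings | None = None) -> dict:
    """Recover the citywide percent change per 10 degC by refitting model 1
    to a synthetic panel whose true slope gives a 7.2 % rise.

    Returns the posterior summary of the percent change, the implied extra
    admissions per day at the observed mean rate, and the problem size.
    """
    study = citywide_model1_study(seed)
    mcmc = mcmc or bayesfit.McmcSettings(seed=seed + 2)
    fit = bayesfit.fit_model1(
        study["sim"].panel,
        study["design"],
        study["exposure"],
        total_population=BRISBANE_POPULATION,
        mcmc=mcmc,
    )
    pct = summarize.percent_change(fit.stacked("gamma"))
    rows = bayesfit.aggregate_citywide(study["sim"].panel).merge(
        study["design"][["date"]], on="date"
    )
    mean_rate = float(rows["count"].mean())
    return {
        "pct_per_10C": pct,
        "true_pct_per_10C": 100 * (np.exp(10 * study["truth"].gamma_star) - 1),
        "mean_daily_admissions": mean_rate,
        "extra_admissions_per_day": summarize.extra_admissions(mean_rate, pct["median"]),
        "n_days": int(len(rows)),
        "rhat_gamma": fit.rhat("gamma"),
        "fit": fit,
    }


def area_study(
    seed: int,
    n_areas: int = 20,
    lambda_: float = 0.0,
    modifier: str = "pop_density",
    start: str = "2007-06-01",
    end: str = "2009-05-31",
    daily_mean: float = 193.0,
    sigma_gamma: float | None = None,
):
    """Simulate a multi-area study (two full warm seasons by default) for
    the random-slope and cross-level modifier models."""
    areas = synthdata.gen_area_frame(n_areas, seed=seed)
    weather = synthdata.gen_weather(start, end, seed=seed + 1)
    years = range(pd.Timestamp(start).year - 1, pd.Timestamp(end).year + 2)
    calendar = synthdata.gen_holiday_calendar(list(years))
    truth = synthdata.SimulationTruth(lambda_=lambda_)
    if sigma_gamma is not None:
        truth = replace(truth, sigma_gamma=sigma_gamma)
    truth = synthdata.calibrate_alpha(
        truth, areas, weather, calendar, daily_mean, modifier_name=modifier
    )
    sim = synthdata.simulate_admissions(
        areas, weather, calendar, truth, modifier_name=modifier, seed=seed + 2
    )
    design = tempdesign.temporal_design(weather["date"], calendar)
    exposure = tempdesign.lagged_exposure(weather)
    basis = tempdesign.spatial_basis(areas)
    return {
        "sim": sim,
        "truth": truth,
        "areas": areas,
        "design": design,
        "exposure": exposure,
        "basis": basis,
    }
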