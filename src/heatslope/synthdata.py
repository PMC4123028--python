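"""Synthetic area-level admissions study generator.

Because geographically referenced hospital-admissions records are
confidential, every downstream stage of the pipeline is exercised against
synthetic data drawn from the same generative process the models assume:
daily counts per area are Poisson with a log rate composed of a baseline,
a log-population offset, holiday / day-of-week / seasonal terms, a linear
effect of the previous day's maximum temperature with an area-specific
slope, an area random intercept, and a smooth directional spatial trend.

Defaults emulate a Brisbane-like subtropical city: 158 areas totalling roughly
a million residents, ~193 admissions per day citywide, subtropical
temperature seasonality (annual mean 20.8 degC, January/February means above
25 degC, July near 15 degC), four holiday categories with multiplicative
effects near -15 % (standard), -25 % (Christmas Day) and a positive
2-January effect, and per-area slopes gamma_k scattered around a citywide
mean with an optional linear dependence on an area covariate.

The ground truth (drawn gamma_k, pi_k) is attached to the simulated panel so
parameter-recovery tests can compare posterior estimates against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .tempdesign import HOLIDAY_CATEGORIES

__all__ = [
    "SimulationTruth",
    "SimulatedPanel",
    "gen_area_frame",
    "gen_weather",
    "gen_holiday_calendar",
    "simulate_admissions",
    "calibrate_alpha",
    "HEADLINE_SLOPE",
]

#: Citywide temperature slope corresponding to a 7.2 % rise per 10 degC.
HEADLINE_SLOPE = float(np.log(1.072) / 10.0)

#: Day-of-year (0-based) at which the synthetic temperature cycle peaks.
_WEATHER_PEAK_DOY = 25.0
#: Day-of-year at which the (non-weather) seasonal admissions signal peaks;
#: mid-July, deliberately out of phase with temperature so the day-of-year
#: adjustment and the temperature slope are not conflated by construction.
_ADMIT_PEAK_DOY = 196.0

# Fixed-date public holidays marked "standard" (month, day); approximations
# of the Queensland calendar with movable feasts pinned to typical dates.
DEFAULT_STANDARD_HOLIDAYS = (
    (1, 1),   # New Year's Day
    (1, 26),  # Australia Day
    (4, 25),  # Anzac Day
    (5, 6),   # Labour Day (typical)
    (6, 10),  # Sovereign's birthday (typical)
    (8, 14),  # Exhibition day (typical)
    (10, 7),  # Queen's birthday, QLD (typical)
    (12, 26), # Boxing Day
)
# Quasi-holidays with a smaller impact on admissions.
DEFAULT_OTHER_HOLIDAYS = ((12, 24), (12, 31))


@dataclass
class SimulationTruth:
    """True parameter values behind a simulated admissions panel.

    Parameters
    ----------
    alpha
        Baseline log admission rate per person-day.
    gamma_star
        Citywide temperature slope per degC of ``tmax1``; the default is the
        slope giving a 7.2 % rise in admissions per 10 degC.
    sigma_gamma
        SD of the area slope deviations (per degC).  The default 0.018
        spreads the per-area percent change per 10 degC over roughly
        -25 % .. +55 % around the citywide mean.
    lambda_
        Effect of the (mean-centred) modifier covariate on the area slope,
        per covariate unit per degC; 0 means no cross-level modification.
    sigma_pi
        SD of the area random intercepts on the log scale.
    holiday_effects
        Multiplicative rate factor per holiday category.
    dow_effects
        Seven multiplicative factors, Monday first; Monday is the reference
        and must equal 1.
    seasonal_amplitude
        Log-scale amplitude of the smooth day-of-year signal (a low-order
        sinusoid peaking in mid-winter, so recovery tests are not circular
        with the fitting module's spline basis).
    spatial_coeffs
        ``{"ew": (a1, a2), "ns": (b1, b2)}`` coefficients of a quadratic
        trend in the centred centroid coordinates.
    """

    alpha: float = -8.0
    gamma_star: float = HEADLINE_SLOPE
    sigma_gamma: float = 0.018
    lambda_: float = 0.0
    sigma_pi: float = 0.25
    holiday_effects: dict = field(
        default_factory=lambda: {
            "standard": 0.85,
            "christmas": 0.75,
            "jan2": 1.15,
            "other": 0.95,
        }
    )
    dow_effects: tuple = (1.0, 1.0, 1.0, 1.0, 0.97, 0.85, 0.80)
    seasonal_amplitude: float = 0.08
    spatial_coeffs: dict = field(
        default_factory=lambda: {"ew": (0.15, -0.10), "ns": (0.10, 0.05)}
    )

    def __post_init__(self):
        if self.sigma_gamma < 0 or self.sigma_pi < 0:
            raise ValueError("standard deviations must be >= 0")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Monday first)")
        if self.dow_effects[0] != 1.0:
            raise ValueError("Monday is the reference day; its factor must be 1")
        if any(f <= 0 for f in self.dow_effects):
            raise ValueError("dow factors must be positive")
        for cat in HOLIDAY_CATEGORIES:
            if cat not in self.holiday_effects:
                raise ValueError(f"holiday_effects missing category {cat!r}")
            if self.holiday_effects[cat] <= 0:
                raise ValueError("holiday factors must be positive")

    def null_effects(self) -> "SimulationTruth":
        """Copy with every effect switched off (pure baseline Poisson)."""
        return replace(
            self,
            gamma_star=0.0,
            sigma_gamma=0.0,
            lambda_=0.0,
            sigma_pi=0.0,
            holiday_effects={c: 1.0 for c in HOLIDAY_CATEGORIES},
            dow_effects=(1.0,) * 7,
            seasonal_amplitude=0.0,
            spatial_coeffs={"ew": (0.0, 0.0), "ns": (0.0, 0.0)},
        )


@dataclass
class SimulatedPanel:
    """A simulated admissions panel with its retrievable ground truth."""

    panel: pd.DataFrame          # columns: date, area_id, count
    gamma_k: pd.Series           # true per-area slope, indexed by area_id
    pi_k: pd.Series              # true per-area random intercept
    truth: SimulationTruth


# default cross-covariate correlation (density, high earners, >65, low income)
_DEFAULT_COV_CORR = np.array(
    [
        [1.0, -0.20, -0.25, 0.10],
        [-0.20, 1.0, 0.10, -0.40],
        [-0.25, 0.10, 1.0, 0.05],
        [0.10, -0.40, 0.05, 1.0],
    ]
)


def gen_area_frame(
    n_areas: int,
    seed: int,
    covariate_corr: np.ndarray | None = None,
    median_population: float = 6000.0,
) -> pd.DataFrame:
    """Generate an area attribute table.

    Populations are log-normal around ``median_population`` (158 areas at
    the default give a citywide population near one million); centroids are
    uniform on the unit square; covariates are drawn through a Gaussian
    copula so they are mutually correlated, with marginals calibrated to
    published Brisbane-area medians: population density gamma-distributed with median
    near 1,670 per km^2 and percent of high earners beta-distributed with
    median near 5.95 %.
    """
    if n_areas < 2:
        raise ValueError("n_areas must be >= 2 (the area model needs >= 2 areas)")
    rng = np.random.default_rng(seed)
    corr = _DEFAULT_COV_CORR if covariate_corr is None else np.asarray(covariate_corr)
    L = np.linalg.cholesky(corr)
    z = rng.standard_normal((n_areas, 4)) @ L.T
    u = stats.norm.cdf(z)
    density = stats.gamma.ppf(u[:, 0], a=2.0, scale=1000.0)
    pct_high_income = 100.0 * stats.beta.ppf(u[:, 1], 2.0, 27.0)
    pct_over65 = 100.0 * stats.beta.ppf(u[:, 2], 5.0, 30.0)
    pct_low_income = 100.0 * stats.beta.ppf(u[:, 3], 4.0, 25.0)
    population = np.exp(rng.normal(np.log(median_population), 0.7, size=n_areas))
    return pd.DataFrame(
        {
            "area_id": [f"SLA{i + 1:03d}" for i in range(n_areas)],
            "population": population,
            "centroid_ew": rng.uniform(0, 1, n_areas),
            "centroid_ns": rng.uniform(0, 1, n_areas),
            "pop_density": density,
            "pct_high_income": pct_high_income,
            "pct_over65": pct_over65,
            "pct_low_income": pct_low_income,
        }
    )


def gen_weather(
    start_date,
    end_date,
    seed: int,
    mean: float = 20.8,
    amplitude: float = 5.5,
    ar_coef: float = 0.6,
    marginal_sd: float = 4.3,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Generate a daily maximum-temperature series.

    A sinusoidal annual cycle (peak late January, trough July) around the
    long-run mean, plus stationary AR(1) day-to-day noise, clipped to the
    physically plausible band.  At the defaults a 5-year simulation has
    sample mean 20.8 +/- 1 degC, January/February means above 25 degC, a
    July mean near 15 degC, and 5-year extremes near 2.5 / 39.9 degC (the
    ``marginal_sd`` default is calibrated to those extremes).
    """
    start = pd.Timestamp(start_date)
    end = pd.Timestamp(end_date)
    if end < start:
        raise ValueError("end_date must be >= start_date")
    if not 0 <= ar_coef < 1:
        raise ValueError("ar_coef must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float) - 1.0
    seasonal = mean + amplitude * np.cos(
        2 * np.pi * (doy - _WEATHER_PEAK_DOY) / 365.25
    )
    n = len(dates)
    innov_sd = marginal_sd * np.sqrt(1 - ar_coef**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    noise = np.empty(n)
    prev = rng.normal(0.0, marginal_sd)
    for i in range(n):
        prev = ar_coef * prev + eps[i]
        noise[i] = prev
    tmax = np.clip(seasonal + noise, 0.5, 44.5)
    if missing_rate > 0:
        tmax[rng.random(n) < missing_rate] = np.nan
    return pd.DataFrame({"date": dates, "tmax": tmax})


def gen_holiday_calendar(
    years,
    standard_dates=DEFAULT_STANDARD_HOLIDAYS,
    other_dates=DEFAULT_OTHER_HOLIDAYS,
) -> pd.DataFrame:
    """Holiday calendar covering whole calendar years.

    Marks 25 December as ``christmas``, 2 January as ``jan2``, a fixed
    configurable set of dates per year as ``standard``, a smaller set as
    ``other``, and everything else ``none``.
    """
    years = list(years)
    if not years:
        raise ValueError("years must be non-empty")
    dates = pd.date_range(f"{min(years)}-01-01", f"{max(years)}-12-31", freq="D")
    cat = pd.Series("none", index=dates)
    for y in years:
        for m, d in standard_dates:
            cat.loc[pd.Timestamp(y, m, d)] = "standard"
        for m, d in other_dates:
            cat.loc[pd.Timestamp(y, m, d)] = "other"
        cat.loc[pd.Timestamp(y, 12, 25)] = "christmas"
        cat.loc[pd.Timestamp(y, 1, 2)] = "jan2"
    return pd.DataFrame({"date": dates, "category": cat.to_numpy()})


def _time_signal(dates: pd.DatetimeIndex, calendar: pd.DataFrame, truth: SimulationTruth):
    """Log-scale holiday + day-of-week + seasonal signal per date."""
    cal = calendar.copy()
    cal["date"] = pd.to_datetime(cal["date"])
    cat = cal.set_index("date")["category"].reindex(dates)
    if cat.isna().any():
        raise ValueError("holiday calendar does not cover all panel dates")
    log_hols = np.array(
        [0.0 if c == "none" else np.log(truth.holiday_effects[c]) for c in cat]
    )
    log_dow = np.log(np.asarray(truth.dow_effects))[dates.dayofweek.to_numpy()]
    doy = dates.dayofyear.to_numpy(dtype=float) - 1.0
    seasonal = truth.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - _ADMIT_PEAK_DOY) / 365.25
    )
    return log_hols + log_dow + seasonal


def _spatial_trend(areas: pd.DataFrame, truth: SimulationTruth) -> np.ndarray:
    x = np.asarray(areas["centroid_ew"], dtype=float)
    y = np.asarray(areas["centroid_ns"], dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    a1, a2 = truth.spatial_coeffs["ew"]
    b1, b2 = truth.spatial_coeffs["ns"]
    return a1 * xc + a2 * xc**2 + b1 * yc + b2 * yc**2


def simulate_admissions(
    areas: pd.DataFrame,
    weather: pd.DataFrame,
    calendar: pd.DataFrame,
    truth: SimulationTruth,
    modifier_name: str | None = None,
    seed: int = 0,
) -> SimulatedPanel:
    """Draw an admissions panel from the generative model.

    Per area ``k`` the slope is ``gamma_k = gamma_star + lambda_ * x_k + u_k``
    with ``u_k ~ N(0, sigma_gamma^2)`` and ``x_k`` the mean-centred modifier
    covariate (``lambda_`` is ignored when no modifier is given); the random
    intercept is ``pi_k ~ N(0, sigma_pi^2)``.  Counts are then
    ``O_jk ~ Poisson(exp(alpha + log E_k + time_j + gamma_k * tmax1_j + pi_k
    + smooth_k))``.  The first date of the weather series receives no counts
    because its lagged exposure is undefined.
    """
    rng = np.random.default_rng(seed)
    widx = pd.DatetimeIndex(pd.to_datetime(weather["date"]))
    tmax = np.asarray(weather["tmax"], dtype=float)
    if len(widx) < 2:
        raise ValueError("weather must cover at least 2 days (lag-1 exposure)")
    dates = widx[1:]
    tmax1 = tmax[:-1]
    ok = ~np.isnan(tmax1)
    dates, tmax1 = dates[ok], tmax1[ok]

    if modifier_name is not None:
        if modifier_name not in areas.columns:
            raise ValueError(f"modifier {modifier_name!r} is not an area column")
        x = np.asarray(areas[modifier_name], dtype=float)
        x = x - x.mean()
    else:
        x = np.zeros(len(areas))

    K = len(areas)
    gamma_k = (
        truth.gamma_star
        + (truth.lambda_ if modifier_name is not None else 0.0) * x
        + rng.normal(0.0, truth.sigma_gamma, size=K)
    )
    pi_k = rng.normal(0.0, truth.sigma_pi, size=K)
    smooth_k = _spatial_trend(areas, truth)
    time_j = _time_signal(dates, calendar, truth)

    log_E = np.log(np.asarray(areas["population"], dtype=float))
    # (days, areas) log-rate
    eta = (
        truth.alpha
        + log_E[None, :]
        + time_j[:, None]
        + np.outer(tmax1, gamma_k)
        + pi_k[None, :]
        + smooth_k[None, :]
    )
    counts = rng.poisson(np.exp(eta))
    area_ids = areas["area_id"].to_numpy()
    panel = pd.DataFrame(
        {
            "date": np.repeat(dates, K),
            "area_id": np.tile(area_ids, len(dates)),
            "count": counts.ravel(),
        }
    )
    return SimulatedPanel(
        panel=panel,
        gamma_k=pd.Series(gamma_k, index=area_ids, name="gamma_k"),
        pi_k=pd.Series(pi_k, index=area_ids, name="pi_k"),
        truth=truth,
    )


def calibrate_alpha(
    truth: SimulationTruth,
    areas: pd.DataFrame,
    weather: pd.DataFrame,
    calendar: pd.DataFrame,
    target_citywide_mean: float,
    modifier_name: str | None = None,
) -> SimulationTruth:
    """Return a copy of ``truth`` with ``alpha`` set so the expected citywide
    daily admissions over the weather span equal ``target_citywide_mean``.

    The expectation is exact under the generative model: area random effects
    enter through ``E[exp(pi_k)] = exp(sigma_pi^2 / 2)`` and slope noise
    through ``E[exp(u_k t)] = exp(sigma_gamma^2 t^2 / 2)``.
    """
    if target_citywide_mean <= 0:
        raise ValueError("target mean must be positive")
    widx = pd.DatetimeIndex(pd.to_datetime(weather["date"]))
    tmax = np.asarray(weather["tmax"], dtype=float)
    dates, tmax1 = widx[1:], tmax[:-1]
    ok = ~np.isnan(tmax1)
    dates, tmax1 = dates[ok], tmax1[ok]
    if modifier_name is not None:
        x = np.asarray(areas[modifier_name], dtype=float)
        x = x - x.mean()
    else:
        x = np.zeros(len(areas))
    mean_slope = truth.gamma_star + truth.lambda_ * x  # per area
    time_j = _time_signal(dates, calendar, truth)
    log_E = np.log(np.asarray(areas["population"], dtype=float))
    smooth_k = _spatial_trend(areas, truth)
    eta0 = (
        log_E[None, :]
        + time_j[:, None]
        + np.outer(tmax1, mean_slope)
        + 0.5 * truth.sigma_gamma**2 * (tmax1**2)[:, None]
        + smooth_k[None, :]
        + 0.5 * truth.sigma_pi**2
    )
    mean0 = np.exp(eta0).sum(axis=1).mean()
    return replace(truth, alpha=float(np.log(target_citywide_mean / mean0)))
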