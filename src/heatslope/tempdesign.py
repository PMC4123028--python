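"""Exposure and design components shared by the citywide and area-level models.

The models regress daily admission counts on the previous day's maximum
temperature while adjusting for day of week, public holidays, and a smooth
day-of-year signal that absorbs seasonality and long-term trends.  Analyses
are restricted to the warm season (October-March).  This module builds those
regressors:

* :func:`combine_stations` merges two weather stations into one series,
* :func:`lagged_exposure` produces ``tmax1`` (1-day lagged maximum temperature),
* :func:`warm_season_subset` restricts a date grid to October-March and labels
  each retained date with its warm season,
* :func:`doy_spline_basis` builds the piecewise per-season natural cubic
  spline basis for the day-of-year signal,
* :func:`temporal_design` assembles day-of-week and holiday indicators plus
  the day-of-year basis into one design table,
* :func:`spatial_basis` builds the 2-df east-west / north-south spline basis
  over area centroids.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "HOLIDAY_CATEGORIES",
    "WARM_SEASON_MONTHS",
    "DOW_LEVELS",
    "combine_stations",
    "lagged_exposure",
    "warm_season_subset",
    "natural_spline_basis",
    "doy_spline_basis",
    "temporal_design",
    "spatial_basis",
]

#: Holiday categories used as indicator levels; ``none`` is the reference.
HOLIDAY_CATEGORIES = ("standard", "christmas", "jan2", "other")

#: Months defining the warm season (October through March).
WARM_SEASON_MONTHS = frozenset({10, 11, 12, 1, 2, 3})

#: Day-of-week indicator levels; Monday is the reference category.
DOW_LEVELS = ("Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


def _as_daily_index(dates) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(pd.to_datetime(dates))
    if idx.has_duplicates:
        raise ValueError("dates contain duplicates")
    return idx.sort_values()


def _dated_series(frame: pd.DataFrame, col: str) -> pd.Series:
    """Column of a dated frame as a date-indexed, date-sorted series."""
    idx = pd.DatetimeIndex(pd.to_datetime(frame["date"]))
    if idx.has_duplicates:
        raise ValueError("dates contain duplicates")
    return pd.Series(np.asarray(frame[col], dtype=float), index=idx).sort_index()


def combine_stations(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Merge two station series into a single exposure series.

    Uses the mean of the two stations on days where both report, the single
    available measurement when one is missing, and missing when both are.

    Parameters
    ----------
    a, b
        Weather frames with columns ``date`` and ``tmax`` on an identical
        date grid.
    """
    sa = _dated_series(a, "tmax")
    sb = _dated_series(b, "tmax")
    if len(sa) != len(sb) or not (sa.index == sb.index).all():
        raise ValueError("station series must share an identical date grid")
    stacked = np.vstack([sa.to_numpy(), sb.to_numpy()])
    with np.errstate(invalid="ignore"):
        merged = np.nanmean(stacked, axis=0)
    return pd.DataFrame({"date": sa.index, "tmax": merged})


def lagged_exposure(weather: pd.DataFrame, lag: int = 1) -> pd.DataFrame:
    """Return ``tmax1``: maximum temperature shifted forward by ``lag`` days.

    Dates whose lagged value is unavailable (the first ``lag`` days, or gaps
    in the record) carry a missing ``tmax1`` and are dropped from model rows
    downstream rather than imputed.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    tmax = _dated_series(weather, "tmax")
    full = pd.date_range(tmax.index.min(), tmax.index.max(), freq="D")
    tmax1 = tmax.reindex(full).shift(lag)
    out = pd.DataFrame({"date": full, "tmax1": tmax1.to_numpy()})
    return out[out["date"].isin(tmax.index)].reset_index(drop=True)


def season_label(date: pd.Timestamp) -> str:
    """Warm-season label for a date; Oct Y .. Mar Y+1 share ``"Y-Y+1"``."""
    y = date.year if date.month >= 10 else date.year - 1
    return f"{y}-{y + 1}"


def warm_season_subset(dates) -> pd.DataFrame:
    """Restrict dates to the warm season (Oct-Mar) and label each season.

    A warm season spans the year boundary: October of year ``Y`` through
    March of year ``Y+1`` all receive ``season_id = "Y-Y+1"``.
    """
    idx = _as_daily_index(dates)
    keep = idx[idx.month.isin(list(WARM_SEASON_MONTHS))]
    labels = [season_label(d) for d in keep]
    return pd.DataFrame({"date": keep, "season_id": labels})


# ---------------------------------------------------------------------------
# Natural cubic splines
# ---------------------------------------------------------------------------

def natural_spline_basis(
    x: np.ndarray,
    knots: np.ndarray,
) -> np.ndarray:
    """Natural cubic spline basis (no intercept) with the given knots.

    Uses the standard truncated-power construction: with knots
    ``xi_1 < ... < xi_K`` the basis is ``x`` together with
    ``d_k(x) - d_{K-1}(x)`` for ``k = 1..K-2`` where
    ``d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k)``.
    Every basis function is linear beyond the boundary knots, so the span is
    the space of natural cubic splines on those knots (K columns including
    the implicit intercept; K-1 returned here).
    """
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    if len(knots) < 3:
        raise ValueError("need at least 3 knots (2 boundary + 1 interior)")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be distinct")
    K = len(knots)

    def d(k):
        num = np.clip(x - knots[k], 0.0, None) ** 3 - np.clip(x - knots[-1], 0.0, None) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x]
    dK1 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK1)
    return np.column_stack(cols)


def _quantile_knots(x: np.ndarray, n_interior: int) -> np.ndarray:
    """Boundary knots at min/max, interior knots at equally spaced quantiles."""
    qs = np.linspace(0, 1, n_interior + 2)
    knots = np.quantile(np.asarray(x, dtype=float), qs)
    if len(np.unique(knots)) != len(knots):
        raise ValueError("degenerate data: duplicate knots")
    return knots


def doy_spline_basis(
    design_dates: pd.DataFrame,
    interior_knots_per_season: int = 5,
    end_season_knots: int | None = None,
) -> pd.DataFrame:
    """Piecewise per-season day-of-year basis capturing seasonality and trend.

    For each warm season, a natural cubic spline in the within-season day
    index (days since the season's first retained date, so the basis is
    continuous across 31 Dec -> 1 Jan) with ``interior_knots_per_season``
    interior knots at equally spaced quantiles; the first and last season of
    the study period, typically truncated, receive ``end_season_knots``
    (default: one fewer).  Boundary knots sit at each season's first and last
    day.  Seasons occupy disjoint column blocks, and season-level indicator
    columns (reference = first season) let the piecewise basis absorb
    between-season level shifts, i.e. the long-term trend.

    Parameters
    ----------
    design_dates
        Frame with ``date`` and ``season_id`` columns, as produced by
        :func:`warm_season_subset`.
    """
    if interior_knots_per_season < 1:
        raise ValueError("need at least 1 interior knot per season")
    if end_season_knots is None:
        end_season_knots = max(interior_knots_per_season - 1, 1)
    df = design_dates.copy()
    df["date"] = pd.to_datetime(df["date"])
    seasons = sorted(df["season_id"].unique())
    out = pd.DataFrame(index=df.index)
    for s_i, sid in enumerate(seasons):
        mask = (df["season_id"] == sid).to_numpy()
        dts = df.loc[mask, "date"]
        day_idx = (dts - dts.min()).dt.days.to_numpy(dtype=float)
        span = day_idx.max()
        n_int = (
            end_season_knots
            if (s_i == 0 or s_i == len(seasons) - 1) and len(seasons) > 1
            else interior_knots_per_season
        )
        if len(dts) < n_int + 2:
            raise ValueError(
                f"season {sid} has {len(dts)} days; needs >= {n_int + 2}"
            )
        # rescale to [0, 1] within the season for numerical conditioning
        x = day_idx / span if span > 0 else day_idx
        basis = natural_spline_basis(x, _quantile_knots(x, n_int))
        if s_i > 0:
            lvl = np.zeros(len(df))
            lvl[mask] = 1.0
            out[f"doy_{sid}_lvl"] = lvl
        for j in range(basis.shape[1]):
            col = np.zeros(len(df))
            col[mask] = basis[:, j]
            out[f"doy_{sid}_s{j + 1}"] = col
    return out


def temporal_design(
    dates,
    calendar: pd.DataFrame,
    interior_knots_per_season: int = 5,
    end_season_knots: int | None = None,
) -> pd.DataFrame:
    """Assemble the per-day regressors: dow + hols indicators + doy basis.

    Restricts to the warm season, then attaches 6 day-of-week indicators
    (reference Monday), 4 holiday-category indicators (reference ``none``),
    and the piecewise day-of-year spline basis.

    Parameters
    ----------
    dates
        Candidate dates (restricted internally to October-March).
    calendar
        Holiday calendar with columns ``date`` and ``category``; must cover
        every retained date.
    """
    ws = warm_season_subset(dates)
    cal = calendar.copy()
    cal["date"] = pd.to_datetime(cal["date"])
    cat = cal.set_index("date")["category"]
    missing = ~ws["date"].isin(cat.index)
    if missing.any():
        raise ValueError(
            f"{int(missing.sum())} dates outside holiday-calendar coverage "
            f"(first: {ws.loc[missing, 'date'].iloc[0].date()})"
        )
    out = ws.copy()
    dow_names = np.array(["Mon", *DOW_LEVELS])
    dow = out["date"].dt.dayofweek.to_numpy()
    for i, name in enumerate(DOW_LEVELS, start=1):
        out[f"dow_{name}"] = (dow == i).astype(float)
    cats = cat.reindex(out["date"]).to_numpy()
    for name in HOLIDAY_CATEGORIES:
        out[f"hols_{name}"] = (cats == name).astype(float)
    doy = doy_spline_basis(
        out[["date", "season_id"]],
        interior_knots_per_season=interior_knots_per_season,
        end_season_knots=end_season_knots,
    )
    return pd.concat([out.reset_index(drop=True), doy.reset_index(drop=True)], axis=1)


def design_columns(design: pd.DataFrame) -> list[str]:
    """Names of the regression columns in a temporal design table."""
    return [
        c
        for c in design.columns
        if c.startswith(("dow_", "hols_", "doy_"))
    ]


def spatial_basis(areas: pd.DataFrame, df_per_direction: int = 2) -> pd.DataFrame:
    """Directional spatial smoother basis over area centroids.

    A natural cubic spline with ``df_per_direction`` degrees of freedom in
    each of the east-west and north-south centroid coordinates (boundary
    knots at the coordinate range, ``df - 1`` interior knots at quantiles),
    columns centred to mean zero.  This encodes smooth large-scale
    north-south / east-west variation in admission rates.
    """
    if df_per_direction < 1:
        raise ValueError("df_per_direction must be >= 1")
    out = pd.DataFrame({"area_id": areas["area_id"].to_numpy()})
    for label, col in (("ew", "centroid_ew"), ("ns", "centroid_ns")):
        x = np.asarray(areas[col], dtype=float)
        if len(np.unique(x)) < df_per_direction + 1:
            raise ValueError(
                f"degenerate {label} coordinates: need >= {df_per_direction + 1} "
                "distinct values"
            )
        knots = _quantile_knots(x, df_per_direction - 1) if df_per_direction > 1 else None
        if knots is None:
            basis = x[:, None]
        else:
            basis = natural_spline_basis(x, knots)
        basis = basis - basis.mean(axis=0)
        for j in range(basis.shape[1]):
            out[f"{label}_{j + 1}"] = basis[:, j]
    return out


def spatial_columns(basis: pd.DataFrame) -> list[str]:
    return [c for c in basis.columns if c.startswith(("ew_", "ns_"))]
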