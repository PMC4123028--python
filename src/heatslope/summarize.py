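"""Reported quantities: percent change per 10 degC, area slope tables,
cross-level modifier effects and the spatial-autocorrelation check.

The fitted temperature slopes live on the log scale per degC; reports follow
the field convention of a percent change in admissions per 10 degC rise in
the previous day's maximum temperature, ``100 * (exp(10 * gamma) - 1)``,
summarized by the posterior median and the central 95 % credible interval.
An area is classed as a significant positive (negative) association when
its credible interval lies entirely above (below) zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "percent_change",
    "extra_admissions",
    "SlopeTable",
    "slope_table",
    "modifier_table",
    "MoranResult",
    "morans_i",
    "knn_weights",
    "contiguity_weights",
]


def percent_change(gamma_draws, delta_t: float = 10.0) -> dict:
    """Percent change in admissions for a ``delta_t`` rise in temperature.

    Applies ``100 * (exp(gamma * delta_t) - 1)`` to every posterior draw and
    returns the posterior median with the 2.5/97.5 percentile bounds.
    """
    draws = np.asarray(gamma_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draws")
    if not np.all(np.isfinite(draws)):
        raise ValueError("draws must be finite")
    pct = 100.0 * (np.exp(draws * delta_t) - 1.0)
    return {
        "median": float(np.median(pct)),
        "cri_low": float(np.percentile(pct, 2.5)),
        "cri_high": float(np.percentile(pct, 97.5)),
    }


def extra_admissions(mean_rate: float, pct: float) -> float:
    """Additional admissions per day implied by a percent change in the rate.

    E.g. a 7.2 % rise on a mean of 193 admissions/day is 13.9 extra
    admissions/day (report tables round to 1 decimal).
    """
    if mean_rate < 0:
        raise ValueError("mean_rate must be >= 0")
    return mean_rate * pct / 100.0


def _signif(lo: float, hi: float) -> str:
    if lo > 0:
        return "positive"
    if hi < 0:
        return "negative"
    return "null"


@dataclass
class SlopeTable:
    """Per-area slope summaries plus significance counts."""

    table: pd.DataFrame
    n_positive: int
    n_negative: int


def slope_table(draws, areas: pd.DataFrame, delta_t: float = 10.0) -> SlopeTable:
    """Summarize per-area slopes as percent change per ``delta_t`` degC.

    One row per area with the posterior median, 95 % credible bounds and a
    significance class; rows are laid out with significant-style ordering:
    positives sorted descending, then nulls, then negatives sorted ascending
    (strongest decrease first).
    """
    if "gamma_k" not in draws.params:
        raise ValueError("fit has no per-area slope draws (gamma_k)")
    gk = draws.stacked("gamma_k")  # (ndraws, K)
    area_ids = list(draws.area_ids)
    missing = set(areas["area_id"]) - set(area_ids)
    if missing:
        raise ValueError(f"no slope draws for areas: {sorted(missing)[:5]}")
    rows = []
    for j, aid in enumerate(area_ids):
        s = percent_change(gk[:, j], delta_t)
        rows.append(
            {
                "area_id": aid,
                "pct_per_10C": s["median"],
                "cri_low": s["cri_low"],
                "cri_high": s["cri_high"],
                "signif": _signif(s["cri_low"], s["cri_high"]),
            }
        )
    df = pd.DataFrame(rows)
    order = {"positive": 0, "null": 1, "negative": 2}
    df["_grp"] = df["signif"].map(order)
    df["_key"] = np.where(df["_grp"] == 2, df["pct_per_10C"], -df["pct_per_10C"])
    df = df.sort_values(["_grp", "_key"]).drop(columns=["_grp", "_key"])
    df = df.reset_index(drop=True)
    return SlopeTable(
        table=df,
        n_positive=int((df["signif"] == "positive").sum()),
        n_negative=int((df["signif"] == "negative").sum()),
    )


def modifier_table(fits: dict, unit_changes: dict) -> pd.DataFrame:
    """Cross-level modifier effects as percent change in the slope per unit.

    ``fits`` maps a label to a model-3 fit; each fit contributes one row per
    modifier it contains, reporting the posterior median and 95 % credible
    interval of ``100 * lambda * unit / gamma_star`` — the percent change in
    the temperature-admissions slope per ``unit`` change of the covariate.
    Multi-modifier fits yield rows labelled "(adjusted for ...)".
    """
    rows = []
    for label, fit in fits.items():
        if not fit.modifier_names:
            raise KeyError(f"fit {label!r} carries no modifier draws")
        gs = fit.stacked("gamma_star")
        for cov in fit.modifier_names:
            if cov not in unit_changes:
                raise ValueError(f"no reporting unit given for covariate {cov!r}")
            unit = unit_changes[cov]
            lam = fit.stacked(f"lambda_{cov}")
            ratio = 100.0 * lam * unit / gs
            others = [c for c in fit.modifier_names if c != cov]
            name = cov if not others else f"{cov} (adjusted for {', '.join(others)})"
            rows.append(
                {
                    "predictor": name,
                    "unit_change": unit,
                    "pct_change_in_slope": float(np.median(ratio)),
                    "cri_low": float(np.percentile(ratio, 2.5)),
                    "cri_high": float(np.percentile(ratio, 97.5)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spatial autocorrelation
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    I: float
    p_value: float
    n_perm: int
    weights_spec: str


def _moran_stat(z: np.ndarray, W: np.ndarray, S0: float) -> float:
    n = len(z)
    return float(n / S0 * (z @ W @ z) / (z @ z))


def morans_i(values, weights, n_perm: int = 999, seed: int | None = None,
             weights_spec: str = "user-supplied") -> MoranResult:
    """Moran's I with a two-sided permutation p-value.

    ``I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2`` with ``z`` the
    centred values and ``S0`` the total weight.  The p-value counts random
    permutations of the values whose statistic is at least as far from the
    null expectation ``-1/(n-1)`` as the observed one, using
    ``(r + 1) / (n_perm + 1)``.
    """
    v = np.asarray(values, dtype=float)
    W = np.asarray(weights, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 areas")
    if W.shape != (n, n):
        raise ValueError("weights must be n x n")
    if np.any(W < 0):
        raise ValueError("weights must be non-negative")
    if np.any(np.diag(W) != 0):
        raise ValueError("weights must have a zero diagonal")
    z = v - v.mean()
    if np.all(z == 0):
        raise ValueError("undefined statistic: values are constant")
    S0 = float(W.sum())
    if S0 <= 0:
        raise ValueError("weights sum to zero")
    I_obs = _moran_stat(z, W, S0)
    e_null = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    r = 0
    for _ in range(n_perm):
        I_p = _moran_stat(rng.permutation(z), W, S0)
        if abs(I_p - e_null) >= abs(I_obs - e_null):
            r += 1
    return MoranResult(
        I=I_obs,
        p_value=(r + 1) / (n_perm + 1),
        n_perm=n_perm,
        weights_spec=weights_spec,
    )


def knn_weights(centroids: np.ndarray, k: int = 5) -> tuple[np.ndarray, str]:
    """Row-standardized k-nearest-neighbour weights from centroids.

    Returns the weight matrix and a description string for provenance.
    """
    pts = np.asarray(centroids, dtype=float)
    n = len(pts)
    if k >= n:
        raise ValueError("k must be smaller than the number of areas")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)
    W = np.zeros((n, n))
    for i in range(n):
        for j in idx[i, 1:]:
            W[i, j] = 1.0 / k
    return W, f"k-nearest-neighbour (k={k}), row-standardized"


def contiguity_weights(polygons: dict) -> tuple[np.ndarray, str]:
    """Row-standardized queen-contiguity weights from area polygons.

    ``polygons`` maps area id to a shapely geometry; areas sharing any
    boundary point are neighbours.  Areas without neighbours keep a zero
    row.
    """
    ids = list(polygons)
    n = len(ids)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = polygons[ids[i]], polygons[ids[j]]
            if gi.touches(gj) or gi.intersects(gj):
                W[i, j] = W[j, i] = 1.0
    sums = W.sum(axis=1, keepdims=True)
    np.divide(W, sums, out=W, where=sums > 0)
    return W, "queen contiguity from polygons, row-standardized"
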