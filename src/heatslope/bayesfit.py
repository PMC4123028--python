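"""Hierarchical Bayesian Poisson models for heat-related admissions.

Three models of increasing complexity, all with a log link and a
log-population offset:

* **Model 1** (citywide): ``O_j ~ Poisson(mu_j)``,
  ``log mu_j = alpha + log E + time_j + gamma * tmax1_j`` where ``time_j``
  collects holiday, day-of-week and day-of-year terms and ``tmax1`` is the
  previous day's maximum temperature.
* **Model 2** (area slopes): per area ``k``,
  ``log mu_jk = alpha + log E_k + time_j + gamma_k * tmax1_j + pi_k +
  smooth.area_k`` with exchangeable random slopes
  ``gamma_k ~ N(mu_gamma, sigma_gamma^2)``, random intercepts
  ``pi_k ~ N(0, sigma_pi^2)`` and a 2-df directional spline smoother
  ``smooth.area_k``.
* **Model 3** (cross-level modifier): the slope mean is regressed on
  area-level covariates, ``gamma_k = gamma_star + lambda . x_k + u_k``,
  ``u_k ~ N(0, sigma_gamma^2)`` (the residual term ``u_k`` can be switched
  off for the strictly deterministic slope form).

Priors are noninformative normals (variance 1000 by default) on all
location parameters and Gamma(1, 1) on each variance component — i.e. an
Exponential(1) prior on sigma^2, which supports arbitrarily small variances
and so permits full shrinkage of the area slopes.  The alternative
convention, Gamma(1, 1) on the precision 1/sigma^2, is available as an
option but is strongly informative at the per-degC slope scale (it places
essentially no mass on precisions above ~10, i.e. forces sigma above ~0.3)
and is not the default for that reason.

Posteriors are sampled with a preconditioned Hamiltonian Monte Carlo kernel
over all location parameters (mass matrix from the Hessian at the posterior
mode, step size tuned by dual averaging during burn-in) combined with Gibbs
updates of the precision components, which are conditionally conjugate.
The conditional posterior of the location block given the precisions is
log-concave, a regime in which this kernel mixes rapidly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky

from . import tempdesign

__all__ = [
    "McmcSettings",
    "PosteriorDraws",
    "ConvergenceWarning",
    "linear_predictor",
    "aggregate_citywide",
    "fit_model1",
    "fit_model2",
    "fit_model3",
]

_V0_DEFAULT = 1000.0  # prior variance of location parameters


class ConvergenceWarning(UserWarning):
    """Raised when MCMC diagnostics suggest the chains have not converged."""


@dataclass
class McmcSettings:
    """MCMC configuration.

    ``burn_in`` and ``samples`` are per chain.  ``prior_mean_sd`` is the SD
    of the normal priors on location parameters (default sqrt(1000));
    ``prior_var_shape``/``prior_var_rate`` are the Gamma hyperparameters on
    each precision component (or on the variance itself when
    ``variance_prior_on="variance"``).
    """

    burn_in: int = 5000
    samples: int = 5000
    chains: int = 4
    seed: int = 0
    prior_mean_sd: float = float(np.sqrt(_V0_DEFAULT))
    prior_var_shape: float = 1.0
    prior_var_rate: float = 1.0
    leapfrog_steps: int = 8
    target_accept: float = 0.8
    variance_prior_on: str = "variance"  # or "precision"

    def __post_init__(self):
        for name in ("burn_in", "samples", "chains", "leapfrog_steps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.prior_mean_sd <= 0 or self.prior_var_shape <= 0 or self.prior_var_rate <= 0:
            raise ValueError("prior hyperparameters must be positive")
        if self.variance_prior_on not in ("precision", "variance"):
            raise ValueError("variance_prior_on must be 'precision' or 'variance'")


# ---------------------------------------------------------------------------
# model internals
# ---------------------------------------------------------------------------

@dataclass
class _ModelData:
    """Row-level data plus the parameter layout for one model fit.

    theta layout: [beta (p_f) | gamma_k (K) | pi_k (K) | mean params (m)].
    Model 1 has only the beta block (slope included as a fixed column).
    Mean params are (mu_gamma,) for model 2 and (gamma_star, lambda...) for
    model 3 with a residual slope.
    """

    y: np.ndarray
    offset: np.ndarray
    X: np.ndarray                 # fixed-effect columns, intercept first
    names: list                   # names of the fixed columns
    t: np.ndarray | None = None   # centred exposure per row (area models)
    area: np.ndarray | None = None
    K: int = 0
    Xm: np.ndarray | None = None  # (K, m) standardized modifier matrix
    mean_names: list = field(default_factory=list)
    v0: float = _V0_DEFAULT

    @property
    def hierarchical(self) -> bool:
        return self.K > 0

    @property
    def n_mean(self) -> int:
        return len(self.mean_names)

    @property
    def dim(self) -> int:
        return self.X.shape[1] + 2 * self.K + self.n_mean

    def unpack(self, theta):
        p = self.X.shape[1]
        beta = theta[:p]
        gamma = theta[p : p + self.K]
        pi = theta[p + self.K : p + 2 * self.K]
        mean = theta[p + 2 * self.K :]
        return beta, gamma, pi, mean

    def slope_prior_mean(self, mean):
        """Prior mean of gamma_k given the mean-level parameters."""
        if self.Xm is not None:
            return mean[0] + self.Xm @ mean[1:]
        return np.full(self.K, mean[0])

    def eta(self, theta):
        beta, gamma, pi, _ = self.unpack(theta)
        eta = self.X @ beta + self.offset
        if self.hierarchical:
            eta = eta + self.t * gamma[self.area] + pi[self.area]
        return eta

    def loglik(self, theta) -> float:
        eta = self.eta(theta)
        with np.errstate(over="ignore"):
            mu = np.exp(eta)
        return float(self.y @ eta - mu.sum())

    def logp_grad(self, theta, tau_g, tau_p):
        """Joint log density (up to a constant) and its gradient in theta."""
        beta, gamma, pi, mean = self.unpack(theta)
        eta = self.eta(theta)
        with np.errstate(over="ignore"):
            mu = np.exp(eta)
        if not np.all(np.isfinite(mu)):
            return -np.inf, np.zeros_like(theta)
        r = self.y - mu
        lp = float(self.y @ eta - mu.sum()) - 0.5 * float(beta @ beta) / self.v0
        g = np.empty_like(theta)
        p = self.X.shape[1]
        g[:p] = self.X.T @ r - beta / self.v0
        if self.hierarchical:
            m_k = self.slope_prior_mean(mean)
            dev_g = gamma - m_k
            lp -= 0.5 * tau_g * float(dev_g @ dev_g)
            lp -= 0.5 * tau_p * float(pi @ pi)
            lp -= 0.5 * float(mean @ mean) / self.v0
            g[p : p + self.K] = (
                np.bincount(self.area, weights=r * self.t, minlength=self.K)
                - tau_g * dev_g
            )
            g[p + self.K : p + 2 * self.K] = (
                np.bincount(self.area, weights=r, minlength=self.K) - tau_p * pi
            )
            gm = np.empty(self.n_mean)
            gm[0] = tau_g * dev_g.sum()
            if self.Xm is not None:
                gm[1:] = tau_g * (self.Xm.T @ dev_g)
            g[p + 2 * self.K :] = gm - mean / self.v0
        return lp, g

    def hessian(self, theta, tau_g, tau_p):
        """Negative Hessian of the log density (a positive definite matrix)."""
        eta = self.eta(theta)
        w = np.exp(np.clip(eta, None, 60.0))
        p = self.X.shape[1]
        d = self.dim
        H = np.zeros((d, d))
        Xw = self.X * w[:, None]
        H[:p, :p] = self.X.T @ Xw + np.eye(p) / self.v0
        if not self.hierarchical:
            return H
        K, a, t = self.K, self.area, self.t
        # cross blocks fixed x (gamma, pi): group sums of w * t * X and w * X
        for k_block, wt in (("g", w * t), ("p", w)):
            M = np.zeros((K, p))
            np.add.at(M, a, self.X * wt[:, None])
            sl = slice(p, p + K) if k_block == "g" else slice(p + K, p + 2 * K)
            H[sl, :p] = M
            H[:p, sl] = M.T
        wgg = np.bincount(a, weights=w * t * t, minlength=K)
        wgp = np.bincount(a, weights=w * t, minlength=K)
        wpp = np.bincount(a, weights=w, minlength=K)
        ig = np.arange(p, p + K)
        ip = np.arange(p + K, p + 2 * K)
        H[ig, ig] = wgg + tau_g
        H[ip, ip] = wpp + tau_p
        H[ig, ip] = wgp
        H[ip, ig] = wgp
        im = np.arange(p + 2 * K, d)
        # mean-level block and its coupling with gamma_k
        Z = np.ones((K, 1)) if self.Xm is None else np.column_stack([np.ones(K), self.Xm])
        H[np.ix_(im, im)] = tau_g * (Z.T @ Z) + np.eye(self.n_mean) / self.v0
        H[np.ix_(ig, im)] = -tau_g * Z
        H[np.ix_(im, ig)] = -tau_g * Z.T
        return H


def _newton_map(data: _ModelData, tau_g, tau_p, theta0=None, max_iter=60, tol=1e-8):
    """Posterior mode of the location block given the precisions."""
    theta = np.zeros(data.dim) if theta0 is None else theta0.copy()
    if theta0 is None:
        # start the intercept near the crude rate so exp() stays in range
        theta[0] = float(np.log(max(data.y.mean(), 0.1)) - data.offset.mean())
    lp, g = data.logp_grad(theta, tau_g, tau_p)
    for _ in range(max_iter):
        H = data.hessian(theta, tau_g, tau_p)
        try:
            step = cho_solve(cho_factor(H), g)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-6 * np.eye(data.dim), g)
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            lp_new, g_new = data.logp_grad(cand, tau_g, tau_p)
            if np.isfinite(lp_new) and lp_new >= lp - 1e-12:
                break
            scale *= 0.5
        else:
            break
        moved = np.max(np.abs(cand - theta))
        theta, lp, g = cand, lp_new, g_new
        if moved < tol:
            break
    return theta, lp


def _init_precisions(data: _ModelData, settings: McmcSettings):
    """Alternate mode-finding and moment updates to locate sensible
    starting precisions and a preconditioning point."""
    tau_g, tau_p = 1.0 / 0.02**2, 1.0 / 0.3**2
    theta, _ = _newton_map(data, tau_g, tau_p)
    a0, b0 = settings.prior_var_shape, settings.prior_var_rate

    def point(S):
        if settings.variance_prior_on == "precision":
            return (a0 + data.K / 2) / (b0 + 0.5 * S)
        # conditional-mean variance under the on-variance prior
        shape = data.K / 2 - a0 + 1
        v = (0.5 * S) / max(shape, 0.5)
        return min(1.0 / max(v, 1e-12), _TAU_MAX)

    for _ in range(3):
        _, gamma, pi, mean = data.unpack(theta)
        dev = gamma - data.slope_prior_mean(mean)
        tau_g = point(float(dev @ dev))
        tau_p = point(float(pi @ pi))
        theta, _ = _newton_map(data, tau_g, tau_p, theta0=theta)
    return theta, tau_g, tau_p


class _Preconditioner:
    def __init__(self, H):
        self.L = cholesky(H, lower=True)  # mass M = H = L L^T

    def sample_momentum(self, rng, d):
        return self.L @ rng.standard_normal(d)

    def velocity(self, p):
        # M^{-1} p via two triangular solves
        from scipy.linalg import solve_triangular

        z = solve_triangular(self.L, p, lower=True)
        return solve_triangular(self.L.T, z, lower=False)

    def kinetic(self, p):
        from scipy.linalg import solve_triangular

        z = solve_triangular(self.L, p, lower=True)
        return 0.5 * float(z @ z)


_TAU_MAX = 1e10  # numerical cap on sampled precisions


def _update_precision(rng, dev, a0, b0, tau_old, on: str):
    """Draw the precision of one variance component.

    Conjugate Gamma draw when the Gamma(a0, b0) prior sits on the precision.
    For the on-variance prior the conditional is
    ``p(v) ~ v^(a0 - 1 - K/2) exp(-S / 2v) exp(-b0 v)`` with ``v = sigma^2``
    and ``S`` the sum of squared deviations; an inverse-gamma independence
    proposal matches everything except the ``exp(-b0 v)`` factor, so the
    Metropolis correction is just ``exp(-b0 (v' - v))`` and acceptance is
    near 1 whenever the variance is small.  A random-walk step on
    ``log sigma^2`` is the fallback when the proposal shape is invalid.
    """
    K = len(dev)
    S = float(dev @ dev) + 1e-300
    if on == "precision":
        return min(rng.gamma(a0 + K / 2, 1.0 / (b0 + 0.5 * S)), _TAU_MAX)
    shape = K / 2 - a0
    v_old = 1.0 / tau_old
    if shape > 0:
        v_prop = (S / 2) / rng.gamma(shape)
        if np.log(rng.random()) < -b0 * (v_prop - v_old):
            v_old = v_prop
    else:
        def logp(log_v):
            v = np.exp(log_v)
            return (a0 - K / 2) * log_v - S / (2 * v) - b0 * v

        log_v = np.log(v_old)
        prop = log_v + 0.6 * rng.standard_normal()
        if np.log(rng.random()) < logp(prop) - logp(log_v):
            v_old = float(np.exp(prop))
    return min(1.0 / v_old, _TAU_MAX)


def _run_chain(data: _ModelData, settings: McmcSettings, seed, theta0, tau0, precond):
    rng = np.random.default_rng(seed)
    d = data.dim
    eps = 0.25
    mu_da = np.log(10 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma_da, t0_da, kappa_da = 0.05, 10.0, 0.75
    tau_g, tau_p = tau0
    a0, b0 = settings.prior_var_shape, settings.prior_var_rate

    theta = theta0 + 0.5 * np.linalg.solve(precond.L.T, rng.standard_normal(d))
    lp, grad = data.logp_grad(theta, tau_g, tau_p)
    n_iter = settings.burn_in + settings.samples
    refresh_at = {settings.burn_in // 4, settings.burn_in // 2}
    draws = np.empty((settings.samples, d))
    tau_draws = np.empty((settings.samples, 2))
    ll_draws = np.empty(settings.samples)
    n_accept = 0

    for it in range(n_iter):
        if it in refresh_at and data.hierarchical:
            try:
                precond = _Preconditioner(data.hessian(theta, tau_g, tau_p))
            except np.linalg.LinAlgError:
                pass
        p_mom = precond.sample_momentum(rng, d)
        h0 = -lp + precond.kinetic(p_mom)
        th, g = theta.copy(), grad.copy()
        p_cur = p_mom.copy()
        diverged = False
        for _ in range(settings.leapfrog_steps):
            p_cur += 0.5 * eps * g
            th += eps * precond.velocity(p_cur)
            lp_new, g = data.logp_grad(th, tau_g, tau_p)
            if not np.isfinite(lp_new):
                diverged = True
                break
            p_cur += 0.5 * eps * g
        if diverged:
            alpha_acc = 0.0
        else:
            h1 = -lp_new + precond.kinetic(p_cur)
            alpha_acc = min(1.0, float(np.exp(min(h0 - h1, 0.0))))
            if rng.random() < alpha_acc:
                theta, lp = th, lp_new
                grad = g
                if it >= settings.burn_in:
                    n_accept += 1
        if it < settings.burn_in:
            m = it + 1
            h_bar = (1 - 1 / (m + t0_da)) * h_bar + (
                settings.target_accept - alpha_acc
            ) / (m + t0_da)
            log_eps = mu_da - np.sqrt(m) / gamma_da * h_bar
            w = m ** (-kappa_da)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
        elif it == settings.burn_in:
            eps = float(np.exp(log_eps_bar))
        if data.hierarchical:
            _, gamma_b, pi_b, mean_b = data.unpack(theta)
            tau_g = _update_precision(
                rng, gamma_b - data.slope_prior_mean(mean_b), a0, b0, tau_g,
                settings.variance_prior_on,
            )
            tau_p = _update_precision(
                rng, pi_b, a0, b0, tau_p, settings.variance_prior_on
            )
            lp, grad = data.logp_grad(theta, tau_g, tau_p)
        if it >= settings.burn_in:
            j = it - settings.burn_in
            draws[j] = theta
            tau_draws[j] = (tau_g, tau_p)
            ll_draws[j] = data.loglik(theta)
    return draws, tau_draws, ll_draws, n_accept / settings.samples


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for (chains, draws)."""
    c, n = x.shape
    if n < 4:
        return np.nan
    half = n // 2
    chains = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n2 = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n2 * means.var(ddof=1)
    var_hat = (n2 - 1) / n2 * W + B / n2
    return float(np.sqrt(var_hat / W)) if W > 0 else np.nan


@dataclass
class PosteriorDraws:
    """Posterior draws from one model fit.

    ``params`` maps parameter names to arrays with shape (chains, draws) for
    scalars or (chains, draws, K) for per-area vectors (``gamma_k``,
    ``pi_k``).  Variance components are stored on the SD scale as
    ``sigma_gamma`` / ``sigma_pi``.
    """

    model: str
    params: dict
    log_likelihood: np.ndarray
    map_estimate: dict
    accept_rate: float
    area_ids: np.ndarray | None = None
    modifier_names: list = field(default_factory=list)

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled across chains: shape (ndraws,) or (ndraws, K)."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def gamma_draws(self, area_id=None) -> np.ndarray:
        """Slope draws: citywide (model 1 / mean slope) or for one area."""
        if area_id is None:
            for name in ("gamma", "mu_gamma", "gamma_star"):
                if name in self.params:
                    return self.stacked(name)
            raise KeyError("no citywide slope parameter in this fit")
        idx = int(np.where(self.area_ids == area_id)[0][0])
        return self.stacked("gamma_k")[:, idx]

    def rhat(self, name: str) -> float:
        arr = self.params[name]
        if arr.ndim == 2:
            return _split_rhat(arr)
        return float(np.nanmax([_split_rhat(arr[:, :, k]) for k in range(arr.shape[2])]))

    def summary(self, names=None) -> pd.DataFrame:
        names = names or [n for n, a in self.params.items() if a.ndim == 2]
        rows = []
        for n in names:
            s = self.stacked(n)
            rows.append(
                {
                    "param": n,
                    "median": float(np.median(s)),
                    "mean": float(np.mean(s)),
                    "q2.5": float(np.percentile(s, 2.5)),
                    "q97.5": float(np.percentile(s, 97.5)),
                    "rhat": self.rhat(n),
                }
            )
        return pd.DataFrame(rows)

    def to_long_frame(self) -> pd.DataFrame:
        """Long (chain, draw, parameter, value) table for serialization."""
        recs = []
        for name, arr in self.params.items():
            c, n = arr.shape[:2]
            if arr.ndim == 2:
                df = pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), n),
                        "draw": np.tile(np.arange(n), c),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
                recs.append(df)
            else:
                for k in range(arr.shape[2]):
                    label = f"{name}[{self.area_ids[k]}]"
                    recs.append(
                        pd.DataFrame(
                            {
                                "chain": np.repeat(np.arange(c), n),
                                "draw": np.tile(np.arange(n), c),
                                "parameter": label,
                                "value": arr[:, :, k].reshape(-1),
                            }
                        )
                    )
        return pd.concat(recs, ignore_index=True)

    def to_inferencedata(self):
        import arviz as az

        flat = {}
        for name, arr in self.params.items():
            flat[name] = arr
        return az.from_dict(posterior=flat)


# ---------------------------------------------------------------------------
# fitting entry points
# ---------------------------------------------------------------------------

def linear_predictor(params, design_row, tmax1, log_E, area_id=None):
    """Log rate (log mu) for one day/area under one parameter draw.

    ``params`` maps parameter names to values: ``alpha``, one value per
    design column, ``gamma`` (citywide) or ``gamma_k``/``pi_k`` mappings
    keyed by area.  ``design_row`` maps design-column names to values.
    """
    if tmax1 is None or (isinstance(tmax1, float) and np.isnan(tmax1)):
        raise ValueError("missing exposure: tmax1 is required")
    eta = float(params["alpha"]) + float(log_E)
    for name, value in design_row.items():
        eta += float(params[name]) * float(value)
    if area_id is None:
        eta += float(params["gamma"]) * float(tmax1)
    else:
        eta += float(params["gamma_k"][area_id]) * float(tmax1)
        eta += float(params["pi_k"][area_id])
    return eta


def aggregate_citywide(panel: pd.DataFrame) -> pd.DataFrame:
    """Sum a long (date, area_id, count) panel to citywide daily counts."""
    out = panel.groupby("date", as_index=False)["count"].sum()
    out["date"] = pd.to_datetime(out["date"])
    return out.sort_values("date").reset_index(drop=True)


def _check_counts(y: np.ndarray):
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")


def _merge_rows(counts, design, exposure):
    design = design.copy()
    design["date"] = pd.to_datetime(design["date"])
    exposure = exposure.copy()
    exposure["date"] = pd.to_datetime(exposure["date"])
    counts = counts.copy()
    counts["date"] = pd.to_datetime(counts["date"])
    rows = counts.merge(design, on="date", how="inner").merge(
        exposure[["date", "tmax1"]], on="date", how="inner"
    )
    rows = rows[~rows["tmax1"].isna()].reset_index(drop=True)
    if rows.empty:
        raise ValueError("no usable rows after joining design and exposure")
    return rows


def _draws_from_chains(chain_draws, settings):
    return np.stack(chain_draws)  # (chains, samples, dim)


def _pack_output(model, data, all_draws, tau_all, ll_all, acc, map_theta,
                 t_mean, area_ids=None, modifier_names=(), modifier_scales=()):
    """Split raw theta draws into named parameters and undo the internal
    exposure centring / modifier standardization."""
    p = data.X.shape[1]
    K = data.K
    params = {}
    chains, ns, _ = all_draws.shape
    beta = all_draws[:, :, :p]
    names = data.names
    by_name = {nm: beta[:, :, i] for i, nm in enumerate(names)}

    if model == "model1":
        gamma = by_name["gamma"]
        by_name["alpha"] = by_name["alpha"] - gamma * t_mean
        params.update(by_name)
    else:
        gamma_k = all_draws[:, :, p : p + K]
        pi_k = all_draws[:, :, p + K : p + 2 * K]
        mean_par = all_draws[:, :, p + 2 * K :]
        mu = mean_par[:, :, 0]
        # undo exposure centring: the per-area shift gamma_k * t_mean was
        # absorbed by pi_k, the citywide part by alpha
        by_name["alpha"] = by_name["alpha"] - mu * t_mean
        pi_k = pi_k - (gamma_k - mu[:, :, None]) * t_mean
        params.update(by_name)
        params["gamma_k"] = gamma_k
        params["pi_k"] = pi_k
        if model == "model2":
            params["mu_gamma"] = mu
        else:
            params["gamma_star"] = mu
            for j, nm in enumerate(modifier_names):
                params[f"lambda_{nm}"] = mean_par[:, :, 1 + j] / modifier_scales[j]
        params["sigma_gamma"] = 1.0 / np.sqrt(tau_all[:, :, 0])
        params["sigma_pi"] = 1.0 / np.sqrt(tau_all[:, :, 1])

    map_named = {}
    bmap, gmap, pmap, mmap = data.unpack(map_theta)
    for i, nm in enumerate(names):
        map_named[nm] = float(bmap[i])
    if model == "model1":
        map_named["alpha"] = float(bmap[names.index("alpha")] - bmap[names.index("gamma")] * t_mean)
    return PosteriorDraws(
        model=model,
        params=params,
        log_likelihood=ll_all,
        map_estimate=map_named,
        accept_rate=float(acc),
        area_ids=area_ids,
        modifier_names=list(modifier_names),
    )


def _run_model(model, data, settings, t_mean, area_ids=None,
               modifier_names=(), modifier_scales=()):
    if data.hierarchical:
        theta0, tau_g0, tau_p0 = _init_precisions(data, settings)
    else:
        theta0, _ = _newton_map(data, 0.0, 0.0)
        tau_g0 = tau_p0 = 1.0
    precond = _Preconditioner(data.hessian(theta0, tau_g0, tau_p0))
    ss = np.random.SeedSequence(settings.seed)
    chain_seeds = ss.spawn(settings.chains)
    results = [
        _run_chain(data, settings, cs, theta0, (tau_g0, tau_p0), precond)
        for cs in chain_seeds
    ]
    all_draws = np.stack([r[0] for r in results])
    tau_all = np.stack([r[1] for r in results])
    ll_all = np.stack([r[2] for r in results])
    acc = float(np.mean([r[3] for r in results]))
    out = _pack_output(
        model, data, all_draws, tau_all, ll_all, acc, theta0, t_mean,
        area_ids=area_ids, modifier_names=modifier_names,
        modifier_scales=modifier_scales,
    )
    slope_name = {"model1": "gamma", "model2": "mu_gamma", "model3": "gamma_star"}[model]
    rh = out.rhat(slope_name)
    if np.isfinite(rh) and rh > 1.05:
        warnings.warn(
            f"{model}: R-hat for {slope_name} is {rh:.3f} (> 1.05); "
            "chains may not have converged",
            ConvergenceWarning,
        )
    return out


def fit_model1(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    exposure: pd.DataFrame,
    total_population: float,
    mcmc: McmcSettings | None = None,
) -> PosteriorDraws:
    """Fit the citywide Poisson model (model 1).

    Parameters
    ----------
    counts
        Citywide daily counts (``date``, ``count``); a long panel with an
        ``area_id`` column is aggregated automatically.
    design, exposure
        Output of :func:`heatslope.tempdesign.temporal_design` and
        :func:`heatslope.tempdesign.lagged_exposure`.
    total_population
        The scalar offset ``E`` (total population across areas).
    """
    mcmc = mcmc or McmcSettings()
    if "area_id" in counts.columns:
        counts = aggregate_citywide(counts)
    rows = _merge_rows(counts, design, exposure)
    y = rows["count"].to_numpy(dtype=float)
    _check_counts(y)
    t = rows["tmax1"].to_numpy(dtype=float)
    if np.var(t) == 0:
        raise ValueError("degenerate design: exposure has zero variance")
    t_mean = float(t.mean())
    cols = tempdesign.design_columns(rows)
    X = np.column_stack(
        [np.ones(len(rows)), rows[cols].to_numpy(dtype=float), t - t_mean]
    )
    names = ["alpha", *cols, "gamma"]
    offset = np.full(len(rows), np.log(float(total_population)))
    data = _ModelData(y=y, offset=offset, X=X, names=names,
                      v0=mcmc.prior_mean_sd**2)
    return _run_model("model1", data, mcmc, t_mean)


def _area_rows(panel, design, exposure, areas, basis):
    area_ids = np.sort(areas["area_id"].unique())
    unknown = set(panel["area_id"]) - set(area_ids)
    if unknown:
        raise ValueError(f"panel areas missing from the area frame: {sorted(unknown)[:5]}")
    rows = _merge_rows(panel, design, exposure)
    lookup = {a: i for i, a in enumerate(area_ids)}
    a_idx = rows["area_id"].map(lookup).to_numpy(dtype=int)
    areas_sorted = areas.set_index("area_id").loc[area_ids]
    basis_sorted = basis.set_index("area_id").loc[area_ids]
    return rows, area_ids, a_idx, areas_sorted, basis_sorted


def _build_area_data(rows, a_idx, areas_sorted, basis_sorted, v0):
    y = rows["count"].to_numpy(dtype=float)
    _check_counts(y)
    t = rows["tmax1"].to_numpy(dtype=float)
    t_mean = float(t.mean())
    cols = tempdesign.design_columns(rows)
    sp_cols = tempdesign.spatial_columns(basis_sorted)
    sp = basis_sorted[sp_cols].to_numpy(dtype=float)[a_idx]
    X = np.column_stack([np.ones(len(rows)), rows[cols].to_numpy(dtype=float), sp])
    names = ["alpha", *cols, *sp_cols]
    offset = np.log(areas_sorted["population"].to_numpy(dtype=float))[a_idx]
    return y, offset, X, names, t - t_mean, t_mean


def fit_model2(
    panel: pd.DataFrame,
    design: pd.DataFrame,
    exposure: pd.DataFrame,
    areas: pd.DataFrame,
    basis: pd.DataFrame,
    mcmc: McmcSettings | None = None,
) -> PosteriorDraws:
    """Fit the area-level random-slope model (model 2).

    Each area receives its own temperature slope ``gamma_k``, exchangeable
    around a citywide mean ``mu_gamma`` with SD ``sigma_gamma``, plus a
    random intercept ``pi_k`` and the directional spatial smoother.
    Defaults follow the area models' shorter runs (2,000 burn-in / 2,000
    samples per chain).
    """
    mcmc = mcmc or McmcSettings(burn_in=2000, samples=2000)
    if areas["area_id"].nunique() < 2:
        raise ValueError("the area model needs at least 2 areas")
    rows, area_ids, a_idx, areas_s, basis_s = _area_rows(
        panel, design, exposure, areas, basis
    )
    y, offset, X, names, t_c, t_mean = _build_area_data(
        rows, a_idx, areas_s, basis_s, mcmc.prior_mean_sd**2
    )
    data = _ModelData(
        y=y, offset=offset, X=X, names=names, t=t_c, area=a_idx,
        K=len(area_ids), mean_names=["mu_gamma"], v0=mcmc.prior_mean_sd**2,
    )
    return _run_model("model2", data, mcmc, t_mean, area_ids=area_ids)


def fit_model3(
    panel: pd.DataFrame,
    design: pd.DataFrame,
    exposure: pd.DataFrame,
    areas: pd.DataFrame,
    basis: pd.DataFrame,
    modifier_name,
    mcmc: McmcSettings | None = None,
    residual_slope: bool = True,
) -> PosteriorDraws:
    """Fit the cross-level modifier model (model 3).

    The area slope mean is ``gamma_star + sum_j lambda_j x_jk`` for one or
    more area-level covariates; by default a residual deviation
    ``u_k ~ N(0, sigma_gamma^2)`` is retained so slope uncertainty is not
    understated (set ``residual_slope=False`` for the strictly deterministic
    form).  Covariates are mean-centred and scaled internally; reported
    ``lambda`` draws are per original covariate unit, and ``gamma_star`` is
    the slope at the citywide covariate mean, i.e. the average slope.
    """
    mcmc = mcmc or McmcSettings(burn_in=2000, samples=2000)
    modifiers = [modifier_name] if isinstance(modifier_name, str) else list(modifier_name)
    for m in modifiers:
        if m not in areas.columns:
            raise ValueError(f"modifier {m!r} is not an area covariate")
    rows, area_ids, a_idx, areas_s, basis_s = _area_rows(
        panel, design, exposure, areas, basis
    )
    Xm_raw = areas_s[modifiers].to_numpy(dtype=float)
    if not np.all(np.isfinite(Xm_raw)):
        raise ValueError("modifier covariates must be finite")
    scales = Xm_raw.std(axis=0)
    if np.any(scales == 0):
        bad = [m for m, s in zip(modifiers, scales) if s == 0]
        raise ValueError(f"degenerate modifier (constant across areas): {bad}")
    Xm = (Xm_raw - Xm_raw.mean(axis=0)) / scales
    if len(modifiers) > 1:
        corr = np.corrcoef(Xm, rowvar=False)
        off = corr[~np.eye(len(modifiers), dtype=bool)]
        if np.any(np.abs(off) > 0.999):
            raise ValueError("degenerate modifier set: covariates are collinear")
    y, offset, X, names, t_c, t_mean = _build_area_data(
        rows, a_idx, areas_s, basis_s, mcmc.prior_mean_sd**2
    )
    if not residual_slope:
        # deterministic slope: gamma_k = gamma_star + lambda.x enters as
        # fixed columns t and t*x_k (pi_k random intercepts retained)
        data = _ModelData(
            y=y, offset=offset,
            X=np.column_stack([X, t_c[:, None], t_c[:, None] * Xm[a_idx]]),
            names=[*names, "gamma_star", *[f"lambda_{m}" for m in modifiers]],
            t=np.zeros_like(t_c), area=a_idx, K=len(area_ids),
            mean_names=["mu_gamma"], v0=mcmc.prior_mean_sd**2,
        )
        out = _run_model("model2", data, mcmc, 0.0, area_ids=area_ids)
        out.model = "model3"
        out.modifier_names = modifiers
        # rescale lambda to original units; correct alpha for t centring
        gs = out.params.pop("gamma_star")
        out.params["gamma_star"] = gs
        out.params["alpha"] = out.params["alpha"] - gs * t_mean
        for m, s in zip(modifiers, scales):
            out.params[f"lambda_{m}"] = out.params[f"lambda_{m}"] / s
        return out
    data = _ModelData(
        y=y, offset=offset, X=X, names=names, t=t_c, area=a_idx,
        K=len(area_ids), Xm=Xm,
        mean_names=["gamma_star", *[f"lambda_{m}" for m in modifiers]],
        v0=mcmc.prior_mean_sd**2,
    )
    return _run_model(
        "model3", data, mcmc, t_mean, area_ids=area_ids,
        modifier_names=modifiers, modifier_scales=scales,
    )
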