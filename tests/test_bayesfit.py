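"""Model-fitting checks: linear predictor arithmetic, input validation,
seeded reproducibility, offset invariance, null and heterogeneous slope
recovery, and interval calibration at small scale."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import heatslope as hs
from heatslope.synthdata import SimulationTruth

from conftest import single_area_frame


class TestLinearPredictor:
    def test_all_zero_coefficients(self):
        eta = hs.linear_predictor(
            {"alpha": 0.0, "x1": 0.0, "gamma": 0.0}, {"x1": 1.0}, tmax1=25.0, log_E=0.0
        )
        assert eta == 0.0

    def test_offset_additivity(self):
        eta = hs.linear_predictor(
            {"alpha": np.log(2), "gamma": 0.0}, {}, tmax1=25.0, log_E=np.log(100)
        )
        assert eta == pytest.approx(np.log(200), abs=1e-12)

    def test_matches_bruteforce_dot_product(self):
        rng = np.random.default_rng(0)
        names = ["c1", "c2", "c3"]
        coefs = dict(zip(names, rng.normal(size=3)))
        row = dict(zip(names, rng.normal(size=3)))
        params = {"alpha": rng.normal(), "gamma": rng.normal(), **coefs}
        t, logE = 31.2, np.log(5000.0)
        eta = hs.linear_predictor(params, row, tmax1=t, log_E=logE)
        brute = (
            params["alpha"]
            + logE
            + sum(coefs[n] * row[n] for n in names)
            + params["gamma"] * t
        )
        assert eta == pytest.approx(brute, abs=1e-12)

    def test_area_terms(self):
        params = {
            "alpha": 0.0,
            "gamma_k": {"A": 0.01},
            "pi_k": {"A": 0.3},
        }
        eta = hs.linear_predictor(params, {}, tmax1=10.0, log_E=0.0, area_id="A")
        assert eta == pytest.approx(0.1 + 0.3, abs=1e-12)

    def test_missing_exposure_rejected(self):
        with pytest.raises(ValueError):
            hs.linear_predictor({"alpha": 0.0, "gamma": 0.0}, {}, tmax1=np.nan, log_E=0.0)


def _simulate_citywide(truth, seed, start="2007-06-01", end="2009-09-30"):
    areas = single_area_frame()
    w = hs.gen_weather(start, end, seed=seed)
    cal = hs.gen_holiday_calendar(range(2006, 2011))
    truth = hs.calibrate_alpha(truth, areas, w, cal, 193.0)
    sim = hs.simulate_admissions(areas, w, cal, truth, seed=seed + 1)
    design = hs.temporal_design(w["date"], cal)
    expo = hs.lagged_exposure(w)
    return sim, design, expo, areas


class TestModel1:
    def test_validation_errors(self, study, quick_mcmc):
        design, expo = study["design"], study["exposure"]
        counts = pd.DataFrame({"date": design["date"], "count": 5.5})
        with pytest.raises(ValueError):
            hs.fit_model1(counts, design, expo, 1000.0, quick_mcmc)
        flat = expo.assign(tmax1=20.0)
        ok = pd.DataFrame({"date": design["date"], "count": 5})
        with pytest.raises(ValueError):
            hs.fit_model1(ok, design, flat, 1000.0, quick_mcmc)

    def test_null_slope_recovery(self, quick_mcmc):
        truth = SimulationTruth(gamma_star=0.0, sigma_gamma=0.0, sigma_pi=0.0)
        sim, design, expo, areas = _simulate_citywide(truth, seed=21)
        fit = hs.fit_model1(
            sim.panel, design, expo, areas["population"].sum(), quick_mcmc
        )
        pct = hs.percent_change(fit.stacked("gamma"))
        assert abs(pct["median"]) < 2.0

    def test_seeded_fit_is_reproducible(self, quick_mcmc):
        truth = SimulationTruth(sigma_gamma=0.0, sigma_pi=0.0)
        sim, design, expo, areas = _simulate_citywide(
            truth, seed=22, end="2008-09-30"
        )
        fits = [
            hs.fit_model1(sim.panel, design, expo, areas["population"].sum(), quick_mcmc)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(
            fits[0].stacked("gamma"), fits[1].stacked("gamma")
        )

    def test_offset_shift_leaves_slope_invariant(self, quick_mcmc):
        """Scaling E by e^c shifts alpha by -c and leaves gamma unchanged."""
        truth = SimulationTruth(sigma_gamma=0.0, sigma_pi=0.0)
        sim, design, expo, areas = _simulate_citywide(
            truth, seed=23, end="2008-09-30"
        )
        E = areas["population"].sum()
        c = 2.0
        f1 = hs.fit_model1(sim.panel, design, expo, E, quick_mcmc)
        f2 = hs.fit_model1(sim.panel, design, expo, E * np.exp(c), quick_mcmc)
        g1, g2 = f1.stacked("gamma"), f2.stacked("gamma")
        assert abs(np.median(g1) - np.median(g2)) < 0.5 * g1.std()
        a_shift = np.median(f1.stacked("alpha")) - np.median(f2.stacked("alpha"))
        assert a_shift == pytest.approx(c, abs=0.5 * f1.stacked("alpha").std() + 0.02)

    def test_posterior_mode_matches_mle_oracle(self, quick_mcmc):
        """MAP under flat-ish priors sits at the Poisson MLE (IRLS oracle)."""
        sm = pytest.importorskip("statsmodels.api")
        truth = SimulationTruth(sigma_pi=0.0, sigma_gamma=0.0)
        sim, design, expo, areas = _simulate_citywide(truth, seed=24)
        E = float(areas["population"].sum())
        fit = hs.fit_model1(sim.panel, design, expo, E, quick_mcmc)
        rows = (
            hs.bayesfit.aggregate_citywide(sim.panel)
            .merge(design, on="date")
            .merge(expo, on="date")
            .dropna(subset=["tmax1"])
        )
        cols = hs.tempdesign.design_columns(rows)
        X = np.column_stack([np.ones(len(rows)), rows[cols], rows["tmax1"]])
        glm = sm.GLM(
            rows["count"].to_numpy(),
            X,
            family=sm.families.Poisson(),
            offset=np.full(len(rows), np.log(E)),
        ).fit()
        post_sd = fit.stacked("gamma").std()
        assert abs(fit.map_estimate["gamma"] - glm.params[-1]) < 3 * post_sd

    def test_interval_coverage_across_replicates(self):
        """95% credible intervals for gamma cover the truth in >= 90% of
        seeded replicates (small per-replicate panels)."""
        mcmc = hs.McmcSettings(burn_in=300, samples=300, chains=1, seed=0)
        truth0 = SimulationTruth(sigma_gamma=0.0, sigma_pi=0.0)
        hits = 0
        for rep in range(20):
            sim, design, expo, areas = _simulate_citywide(
                dataclasses.replace(truth0), seed=100 + rep, end="2008-09-30"
            )
            fit = hs.fit_model1(
                sim.panel, design, expo, areas["population"].sum(),
                dataclasses.replace(mcmc, seed=rep),
            )
            g = fit.stacked("gamma")
            lo, hi = np.percentile(g, [2.5, 97.5])
            hits += lo <= hs.HEADLINE_SLOPE <= hi
        assert hits >= 18


@pytest.fixture(scope="module")
def area_sim(study):
    truth = hs.calibrate_alpha(
        SimulationTruth(), study["areas"], study["weather"], study["calendar"], 193.0
    )
    sim = hs.simulate_admissions(
        study["areas"], study["weather"], study["calendar"], truth, seed=31
    )
    return sim, truth


class TestModel2:
    def test_heterogeneous_slopes_recovered(self, study, area_sim, quick_mcmc):
        sim, _ = area_sim
        fit = hs.fit_model2(
            sim.panel, study["design"], study["exposure"], study["areas"],
            study["basis"], quick_mcmc,
        )
        gk = fit.stacked("gamma_k")
        post_mean = gk.mean(axis=0)
        rank = pd.Series(post_mean).corr(
            pd.Series(sim.gamma_k.values), method="spearman"
        )
        assert rank > 0.6
        lo = np.percentile(gk, 2.5, axis=0)
        hi = np.percentile(gk, 97.5, axis=0)
        covered = int(((lo <= sim.gamma_k.values) & (sim.gamma_k.values <= hi)).sum())
        assert covered >= 9  # ~95% nominal over 12 areas, binomial slack
        assert (fit.stacked("sigma_gamma") > 0).all()

    def test_homogeneous_truth_shrinks_together(self, study, quick_mcmc):
        truth = hs.calibrate_alpha(
            SimulationTruth(sigma_gamma=0.0, sigma_pi=0.1),
            study["areas"], study["weather"], study["calendar"], 193.0,
        )
        sim = hs.simulate_admissions(
            study["areas"], study["weather"], study["calendar"], truth, seed=32
        )
        fit = hs.fit_model2(
            sim.panel, study["design"], study["exposure"], study["areas"],
            study["basis"], quick_mcmc,
        )
        pct = 100 * (np.exp(10 * fit.stacked("gamma_k").mean(axis=0)) - 1)
        assert pct.max() - pct.min() < 5.0

    def test_area_mismatch_rejected(self, study, area_sim, quick_mcmc):
        sim, _ = area_sim
        extra = sim.panel.copy()
        extra.loc[extra.index[-1], "area_id"] = "SLA999"
        with pytest.raises(ValueError):
            hs.fit_model2(
                extra, study["design"], study["exposure"], study["areas"],
                study["basis"], quick_mcmc,
            )

    def test_single_area_rejected(self, study, quick_mcmc):
        one = study["areas"].iloc[:1]
        with pytest.raises(ValueError):
            hs.fit_model2(
                pd.DataFrame({"date": [], "area_id": [], "count": []}),
                study["design"], study["exposure"], one, study["basis"], quick_mcmc,
            )

    def test_label_equivariance_in_distribution(self, quick_mcmc):
        """Relabelling two areas (with all their data) swaps the gamma_k
        posteriors up to Monte-Carlo error."""
        areas = hs.gen_area_frame(3, seed=41)
        w = hs.gen_weather("2007-06-01", "2008-09-30", seed=42)
        cal = hs.gen_holiday_calendar(range(2007, 2009))
        truth = hs.calibrate_alpha(SimulationTruth(), areas, w, cal, 60.0)
        sim = hs.simulate_admissions(areas, w, cal, truth, seed=43)
        design = hs.temporal_design(w["date"], cal)
        expo = hs.lagged_exposure(w)
        basis = hs.spatial_basis(areas)
        swap = {"SLA001": "SLA002", "SLA002": "SLA001", "SLA003": "SLA003"}
        areas_sw = areas.assign(area_id=areas["area_id"].map(swap))
        panel_sw = sim.panel.assign(area_id=sim.panel["area_id"].map(swap))
        basis_sw = basis.assign(area_id=basis["area_id"].map(swap))
        f = hs.fit_model2(sim.panel, design, expo, areas, basis, quick_mcmc)
        f_sw = hs.fit_model2(panel_sw, design, expo, areas_sw, basis_sw, quick_mcmc)
        for orig, new in swap.items():
            g = f.gamma_draws(orig)
            g_sw = f_sw.gamma_draws(new)
            assert abs(np.median(g) - np.median(g_sw)) < 0.5 * g.std()


class TestModel3:
    def test_modifier_validation(self, study, area_sim, quick_mcmc):
        sim, _ = area_sim
        args = (sim.panel, study["design"], study["exposure"])
        with pytest.raises(ValueError):
            hs.fit_model3(*args, study["areas"], study["basis"], "nope", quick_mcmc)
        const = study["areas"].assign(flat=1.0)
        with pytest.raises(ValueError):
            hs.fit_model3(*args, const, study["basis"], "flat", quick_mcmc)
        twice = study["areas"].assign(density2=study["areas"]["pop_density"] * 2)
        with pytest.raises(ValueError):
            hs.fit_model3(
                *args, twice, study["basis"], ["pop_density", "density2"], quick_mcmc
            )

    def test_strong_modifier_sign_recovered(self, study, quick_mcmc):
        lam = 1.5 * hs.HEADLINE_SLOPE / 1000.0  # +150% slope per 1,000/km^2
        truth = hs.calibrate_alpha(
            SimulationTruth(lambda_=lam), study["areas"], study["weather"],
            study["calendar"], 193.0, modifier_name="pop_density",
        )
        sim = hs.simulate_admissions(
            study["areas"], study["weather"], study["calendar"], truth,
            modifier_name="pop_density", seed=44,
        )
        fit = hs.fit_model3(
            sim.panel, study["design"], study["exposure"], study["areas"],
            study["basis"], "pop_density", quick_mcmc,
        )
        lam_draws = fit.stacked("lambda_pop_density")
        assert np.median(lam_draws) > 0
        assert fit.rhat("gamma_star") < 1.2

    def test_deterministic_slope_variant(self, study, area_sim, quick_mcmc):
        sim, _ = area_sim
        fit = hs.fit_model3(
            sim.panel, study["design"], study["exposure"], study["areas"],
            study["basis"], "pop_density",
            hs.McmcSettings(burn_in=300, samples=300, chains=1, seed=7),
            residual_slope=False,
        )
        assert "lambda_pop_density" in fit.params
        assert fit.stacked("gamma_star").ndim == 1


def test_draw_shapes_and_rhat(study, area_sim, quick_mcmc):
    sim, _ = area_sim
    fit = hs.fit_model2(
        sim.panel, study["design"], study["exposure"], study["areas"],
        study["basis"], quick_mcmc,
    )
    K = len(study["areas"])
    assert fit.params["gamma_k"].shape == (quick_mcmc.chains, quick_mcmc.samples, K)
    assert fit.params["mu_gamma"].shape == (quick_mcmc.chains, quick_mcmc.samples)
    assert np.isfinite(fit.rhat("mu_gamma"))
    assert fit.log_likelihood.shape == (quick_mcmc.chains, quick_mcmc.samples)
    long = fit.to_long_frame()
    assert {"chain", "draw", "parameter", "value"} <= set(long.columns)
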