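"""Three-pool radiocarbon model: fits, carbon ages, transit times, Delta-14C.

For each treatment x depth, forward-simulates Delta-14C observations at the
two sampling years from the study-condition model, refits the five rate
parameters by Levenberg-Marquardt (stock-constrained), and derives the
system/SOC age distributions, transit times and the SOC Delta-14C mass
distribution. Writes results/radiocarbon/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from warmsoil import radiocarbon as rc, synthetic as syn, tables

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
COMBOS = [("control", "0-10"), ("warmed", "0-10"), ("control", "10-20"), ("warmed", "10-20")]


def main() -> None:
    cfg = syn.SyntheticConfig(seed=SEED)
    curve = syn.synth_atmospheric_curve()
    rng = cfg.rng("radiocarbon")
    age_rows, fit_rows = [], []
    for treatment, depth in COMBOS:
        model = syn.default_radiocarbon_model(treatment, depth)
        obs = syn.synth_radiocarbon_obs(
            model, curve, noise_sigma=cfg.c14_noise_sigma,
            seed=int(rng.integers(2**31 - 1)),
        )
        pool_stocks = dict(zip(model.pool_names, model.steady_state()))
        fit = rc.fit_model(
            obs, curve, litter_input=syn.LITTERFALL_C_INPUT, stocks=pool_stocks,
            n_starts=3, seed=int(rng.integers(2**31 - 1)),
            depth=depth, treatment=treatment,
        )
        sys_age = rc.age_distribution(fit.model, "system")
        soc_age = rc.age_distribution(fit.model, "bulk_soc")
        transit = rc.transit_time_distribution(fit.model)
        d14c = rc.delta14c_mass_distribution(soc_age, curve, 2019.0, bins=60)
        fit_rows.append((treatment, depth, *(fit.params[k] for k in ("k1", "k2", "k3", "a31", "a32"))))
        age_rows.append(
            (treatment, depth, sys_age.mean, sys_age.median, soc_age.mean,
             soc_age.median, transit.mean, d14c.mean_delta14c())
        )
        print(f"{treatment} {depth} cm: SOC age {soc_age.mean:.0f} "
              f"({soc_age.median:.0f}) yr, system {sys_age.mean:.0f} "
              f"({sys_age.median:.0f}) yr, transit {transit.mean:.0f} yr")

    ages = pd.DataFrame(
        age_rows,
        columns=["treatment", "depth", "system_mean_yr", "system_median_yr",
                 "soc_mean_yr", "soc_median_yr", "mean_transit_yr",
                 "soc_mean_delta14c_2019_permil"],
    )
    fits = pd.DataFrame(
        fit_rows, columns=["treatment", "depth", "k1", "k2", "k3", "a31", "a32"]
    )
    tables.write_table(ages, ROOT / "radiocarbon" / "ages.csv")
    tables.write_table(fits, ROOT / "radiocarbon" / "fitted_rates.csv")

    for depth in ("0-10", "10-20"):
        sub = ages[ages["depth"] == depth].set_index("treatment")
        d = sub.loc["control", "soc_mean_yr"] - sub.loc["warmed", "soc_mean_yr"]
        print(f"warming rejuvenates SOC at {depth} cm by {d:.0f} yr (mean age)")


if __name__ == "__main__":
    main()
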