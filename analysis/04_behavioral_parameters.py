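"""Estimate Social-EPR behavioral parameters and subcategory popularity shifts.

Fits the exploration law p(S) = ρS^(−γ), estimates social exploration σ_s
(share of explorations into places whose majority income quantile differs
from the visitor's, majority labels held fixed at the 2019 baseline), and
ranks subcategory popularity changes Δf_r for each pandemic month against
its 2019 baseline. Writes results/behavior_parameters.csv and
results/popularity_shifts.csv.
"""

import pandas as pd

from common import RESULTS, load_or_simulate
from urbandiv import behavior, metrics, study


def main():
    world, stays = load_or_simulate()
    cbg, poi, users = world

    rows, pop_rows = [], []
    for month in list(study.STRINGENCY_BY_MONTH):
        base_label = f"2019-{month.split('-')[1]}"
        labels = behavior.majority_labels(metrics.place_exposure(stays[base_label], users))
        for label in (base_label, month):
            ev = behavior.label_explorations(stays[label])
            fit = behavior.fit_exploration_law(ev)
            sig = behavior.estimate_social_exploration(ev, labels, users)
            rows.append(
                {
                    "period": label,
                    "rho": fit["rho"],
                    "gamma": fit["gamma"],
                    "sigma_s": sig["sigma_s"],
                    "sigma_s_lo": sig["ci"][0],
                    "sigma_s_hi": sig["ci"][1],
                    "n_explorations": sig["n_explorations"],
                    "sigma_s_truth": study.pandemic_scenario(
                        month, study.STRINGENCY_BY_MONTH[month]
                    ).sigma_s_override
                    if label == month
                    else study.BASE_EPR.sigma_s,
                }
            )
        f_base = behavior.subcategory_popularity(stays[base_label], poi, r=5)
        f_now = behavior.subcategory_popularity(stays[month], poi, r=5)
        shift = behavior.popularity_shift(f_now, f_base)
        shift.insert(0, "month", month)
        pop_rows.append(shift)

    params = pd.DataFrame(rows).round(4).drop_duplicates(subset="period")
    params.to_csv(RESULTS / "behavior_parameters.csv", index=False)
    pops = pd.concat(pop_rows, ignore_index=True).round(4)
    pops.to_csv(RESULTS / "popularity_shifts.csv", index=False)

    print(params.to_string(index=False))
    apr = pops.loc[pops["month"] == "2020-04"]
    print("\n2020-04 subcategories gaining popularity:")
    print(apr.head(3)[["subcategory", "f_r", "f_r_2019", "delta_f_r"]].to_string(index=False))
    print("2020-04 subcategories losing popularity:")
    print(apr.tail(3)[["subcategory", "f_r", "f_r_2019", "delta_f_r"]].to_string(index=False))


if __name__ == "__main__":
    main()
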