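"""Monthly experienced income diversity and its change from 2019.

Computes mean place diversity D̄_α and mean individual diversity D̄_i per
study month, then the deseasonalized percentage change ΔD(t) against the
same calendar month of 2019. Writes results/diversity_trends.csv.
"""

import pandas as pd

from common import RESULTS, load_or_simulate
from urbandiv import metrics, study


def main():
    world, stays = load_or_simulate()
    users = world[2]
    d = {
        label: {
            "D_place": metrics.mean_place_diversity(s, users),
            "D_indiv": metrics.mean_individual_diversity(s, users),
        }
        for label, s in stays.items()
    }
    rows = []
    for label in study.STRINGENCY_BY_MONTH:
        base = f"2019-{label.split('-')[1]}"
        rows.append(
            {
                "month": label,
                "D_place": d[label]["D_place"],
                "D_place_2019": d[base]["D_place"],
                "delta_D_place_pct": metrics.delta_percent(d[label]["D_place"], d[base]["D_place"]),
                "D_indiv": d[label]["D_indiv"],
                "D_indiv_2019": d[base]["D_indiv"],
                "delta_D_indiv_pct": metrics.delta_percent(d[label]["D_indiv"], d[base]["D_indiv"]),
            }
        )
    out = pd.DataFrame(rows).round(4)
    out.to_csv(RESULTS / "diversity_trends.csv", index=False)
    print(out.to_string(index=False))
    worst = out.loc[out["delta_D_indiv_pct"].idxmin()]
    print(
        f"\nlargest drop: {worst['month']} "
        f"(D̄_i {worst['delta_D_indiv_pct']:.1f}%, D̄_α {worst['delta_D_place_pct']:.1f}%)"
    )


if __name__ == "__main__":
    main()
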