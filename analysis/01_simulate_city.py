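"""Simulate the synthetic city and its three-factor pandemic year.

Generates the city (CBGs, POIs, users), a 2019 baseline month for each
study month, and the 2020 pandemic months whose behavioral perturbations
(activity cuts by income quantile, shorter trips, reduced social
exploration, subcategory preference shifts) scale with a monthly policy
stringency ramp. Panels are cached under scratch/panels; a small panel
summary goes to results/panel_summary.csv.
"""

import pandas as pd

from common import RESULTS, load_or_simulate


def main():
    world, stays = load_or_simulate()
    cbg, poi, users = world
    rows = []
    for label, s in sorted(stays.items()):
        rows.append(
            {
                "period": label,
                "n_visits": len(s),
                "n_users": s["user_id"].nunique(),
                "total_dwell_hours": round(s["dwell_min"].sum() / 60.0, 1),
                "visits_per_user_day": round(len(s) / s["user_id"].nunique() / 30.0, 2),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "panel_summary.csv", index=False)
    print(f"city: {len(cbg)} CBGs, {len(poi)} POIs, {len(users)} users")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
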