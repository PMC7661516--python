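#!/usr/bin/env python
"""Latent Poisson trend models per location and for the whole region.

Aggregates yearly counts per location (and pooled), applies the low-count
exclusion rules, fits AR1/RW1/RW2 latent models, compares them by WAIC and
LCPO, and classifies each chosen model's 2003–2008 (or available-range)
trend direction.  Writes comparison tables, fitted trajectories and the
exclusion report under results/trends/.
"""

from pathlib import Path

import pandas as pd

from abrolhos.survey import read_survey_csv
from abrolhos.trend_models import (aggregate_counts, compare_trends,
                                   series_guard, trend_direction)

SEED = 44
BASE = Path(__file__).resolve().parents[1] / "results"
OUT = BASE / "trends"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = read_survey_csv(BASE / "simulated" / "surveys.csv")
    comp_rows, fit_rows, excl_rows, dir_rows = [], [], [], []
    for stage in ("juvenile", "adult"):
        series_list = aggregate_counts(records, group="location",
                                       life_stage=stage)
        series_list.append(aggregate_counts(records, group="all",
                                            life_stage=stage))
        for i, series in enumerate(series_list):
            guarded, report = series_guard(series, min_total=10)
            if report.excluded:
                excl_rows.append({"life_stage": stage,
                                  "group": series.label,
                                  "reasons": "; ".join(report.reasons)})
                continue
            comp = compare_trends(guarded, seed=SEED + 10 * i)
            comp_rows.append(comp.table.assign(life_stage=stage,
                                               group=series.label))
            best = comp.fits[comp.chosen]
            fit_rows.append(best.fitted.assign(life_stage=stage,
                                               group=series.label,
                                               model=comp.chosen))
            y0, y1 = guarded.years[0], guarded.years[-1]
            label, p = trend_direction(best, y0, y1)
            dir_rows.append({"life_stage": stage, "group": series.label,
                             "model": comp.chosen, "from": y0, "to": y1,
                             "direction": label, "p_decline": round(p, 3)})
    pd.concat(comp_rows, ignore_index=True).to_csv(
        OUT / "model_comparison.csv", index=False)
    pd.concat(fit_rows, ignore_index=True).to_csv(
        OUT / "trend_fits.csv", index=False)
    pd.DataFrame(excl_rows).to_csv(OUT / "exclusions.csv", index=False)
    directions = pd.DataFrame(dir_rows)
    directions.to_csv(OUT / "trend_directions.csv", index=False)
    print(directions.to_string(index=False))
    if excl_rows:
        print("\nexcluded series:")
        print(pd.DataFrame(excl_rows).to_string(index=False))


if __name__ == "__main__":
    main()
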