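#!/usr/bin/env python
"""Aggregate the grazing-vs-production budget and the predator biovolume
budget.

Combines the grazing budget (step 02) and the fitted growth rate (step 03)
into the fraction of daily prokaryotic production removed by protists, the
unexplained mortality fraction, and the scuticociliate's biovolume/GGE
doubling-time range; also shows the Q10-scaled rate an epilimnetic
temperature would imply. Writes budget_report.csv under results/budget/.
"""

import json
from pathlib import Path

import pandas as pd

from hypograze import (mcv_from_dims, predator_budget, production_removed,
                       q10_scale, read_table, write_table)
from hypograze.io import dims_from_table

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "budget"

if __name__ == "__main__":
    params = json.loads((ROOT / "data" / "budget_params.json").read_text())
    grazing = pd.read_csv(ROOT / "results" / "grazing" / "grazing_budget.csv").iloc[0]
    growth = pd.read_csv(ROOT / "results" / "growth" / "growth_fit.csv").iloc[0]
    uptake = pd.read_csv(ROOT / "results" / "grazing" / "uptake_estimates.csv")
    cil_uptake = float(uptake.set_index("group").loc["ciliate", "mean_uptake_per_h"])

    removed = production_removed(grazing["pct_standing_stock_daily"],
                                 growth["rate_per_day"], convention="linear")

    dims = dims_from_table(
        read_table(ROOT / "results" / "synthetic" / "cell_dimensions.csv", "dims"))
    predator_vol = mcv_from_dims(dims).mean
    pb = predator_budget(cil_uptake, params["prey_mcv_um3"], predator_vol,
                         params["gge_low"], params["gge_high"])

    epi_rate = q10_scale(growth["rate_per_day"], params["temperature_c"], 20.0,
                         params["q10"])

    rows = [
        ("pct_standing_stock_daily", grazing["pct_standing_stock_daily"], "% day-1"),
        ("removal_time_h", grazing["removal_time_h"], "h"),
        ("prok_growth_rate", growth["rate_per_day"], "day-1"),
        ("prok_doubling_time_h", growth["doubling_time_h"], "h"),
        ("production_removed", removed, "% day-1"),
        ("unexplained_production_fraction", 100.0 - removed, "% day-1"),
        ("predator_volume", predator_vol, "um3"),
        ("predator_ingested_volume_daily", pb.ingested_volume_daily, "um3 day-1"),
        ("predator_doubling_high_gge_h", pb.doubling_time_range_h[0], "h"),
        ("predator_doubling_low_gge_h", pb.doubling_time_range_h[1], "h"),
        ("q10_scaled_rate_at_20C", epi_rate, "day-1"),
    ]
    write_table(pd.DataFrame(rows, columns=["quantity", "value", "units"]),
                OUT / "budget_report.csv")

    print(f"Protists remove {removed:.1f}% of daily prokaryotic production "
          f"(linear convention); {100 - removed:.1f}% is unexplained "
          f"(viral lysis, predatory bacteria, ...).")
    print(f"Scuticociliate ({predator_vol:.0f} μm³) ingests "
          f"{pb.ingested_volume_daily:.0f} μm³ day⁻¹ → doubling "
          f"{pb.doubling_time_range_h[0]:.0f}–{pb.doubling_time_range_h[1]:.0f} h "
          f"at GGE {params['gge_high']:.0%}–{params['gge_low']:.0%}.")
    print(f"Q10={params['q10']} scaling predicts "
          f"{epi_rate / growth['rate_per_day']:.1f}× faster prokaryotic growth "
          f"at 20 °C ({epi_rate:.2f} day⁻¹).")
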