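#!/usr/bin/env python
"""Validate the synthetic weather generator against the 13 site climates.

Generates 100 years per site (seed 1) and compares the realized mean annual
temperature and precipitation with each site's scenario normals. Writes
results/weather_validation.csv.
"""

import pathlib

import pandas as pd

import droughtwheat as dw
from droughtwheat.weather import WeatherGenConfig

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for site_id in dw.list_site_ids():
        site = dw.load_site(site_id)
        series = dw.generate_series(site, WeatherGenConfig(n_years=100, seed=1))
        summ = dw.summarize_series(series)
        rows.append({
            "site_id": site_id, "name": site.name,
            "target_temp_c": site.mean_annual_temp,
            "realized_temp_c": round(summ.mean_annual_temp, 2),
            "temp_error_c": round(summ.mean_annual_temp - site.mean_annual_temp, 2),
            "target_precip_mm": site.annual_precip,
            "realized_precip_mm": round(summ.mean_annual_precip, 1),
            "precip_error_pct": round(100 * (summ.mean_annual_precip
                                             / site.annual_precip - 1), 1),
            "jun_jul_precip_mm": round(float(summ.monthly_mean_precip[5:7].sum()), 1),
            "summer_dryness": site.summer_dryness,
        })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "weather_validation.csv", index=False)
    print(df.to_string(index=False))
    worst_t = df["temp_error_c"].abs().max()
    worst_p = df["precip_error_pct"].abs().max()
    print(f"\nLargest |temperature error|: {worst_t:.2f} degC (tolerance 0.5)")
    print(f"Largest |precipitation error|: {worst_p:.1f}% (tolerance 10%)")


if __name__ == "__main__":
    main()
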