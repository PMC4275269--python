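"""Map gridded yearly temperature trends with a 90% significance mask.

Fits one OLS trend per 1-degree cell and depth layer from July-November
yearly mean temperatures, then prints the significant cells: these are the
coloured cells of a basin trend map (grey = not significant).
"""

from medheat import (SyntheticConfig, TrendField, apply_qc, sample_profiles,
                     trend_map, trend_table)

field = TrendField.two_region((40.0, 42.0, 5.0, 9.0), -0.04, 0.05,
                              split_lon=7.0)
cfg = SyntheticConfig(seed=12, trend_field=field, profiles_per_cell_year=4.0)

pset, _ = sample_profiles(cfg)
passed, _ = apply_qc(pset)
results = trend_map(passed)

tab = trend_table(results)
band = tab[tab.layer == "BAND_0_50"].sort_values(["cell_lon_edge",
                                                  "cell_lat_edge"])
print(band.to_string(index=False,
                     float_format=lambda v: f"{v:.4f}"))
sig = band[band.significant]
print(f"\n{len(sig)}/{len(band)} cells significant at 90%; "
      f"slopes west of 7E are negative, east positive — the 0-50 m trend "
      f"recovers the sign of the generating field (attenuated with depth "
      f"by the stratification profile).")
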