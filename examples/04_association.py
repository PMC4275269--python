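"""Associate mortality events with the trend map: ratios, bins, KS test.

Places 33 events with probability proportional to exp(10*beta) over a
mixed-sign trend field, matches each to its 1-degree cell's 0-50 m trend,
and quantifies the attraction of events to warming cells.
"""

from medheat import (SyntheticConfig, TrendField, associate, generate_events,
                     sample_profiles, trend_map)
from medheat.interp import BAND_0_50

field = TrendField.gradient((40.0, 42.0, 0.0, 20.0), -0.10, 0.15)
cfg = SyntheticConfig(seed=14, trend_field=field, profiles_per_cell_year=6.0,
                      n_events=33, gamma=10.0)

pset, _ = sample_profiles(cfg)
results = trend_map(pset, layers=(BAND_0_50,))
events, _ = generate_events(cfg)

res = associate(events, results)
s = res.sign
print(f"occurrences: {s.n_neg:g} in cooling vs {s.n_pos:g} in warming cells "
      f"(ratio 1:{s.event_ratio[1]:.1f})")
print(f"available area: {s.cells_neg} cooling vs {s.cells_pos} warming "
      f"significant cells (ratio 1:{s.area_ratio[1]:.2f})")
print("histogram over 5 equal trend intervals:",
      [int(round(c)) for c in res.histogram])
print(f"KS vs uniform-over-range: D={res.ks.D:.3f}, p={res.ks.p:.2g}")
print("-> events over-occupy warming cells relative to the area available; "
      "a small KS p-value rejects placement independent of the trend.")
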