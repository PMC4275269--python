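# Methods

This note documents the models, statistical procedures, numerical choices
and known limitations behind `medheat`. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Data model

A *profile* (cast) is one vertical series of (depth, temperature) levels at
a station and time, taken by one of {bottle, MBT, XBT, CTD}. Levels are
sorted by depth at construction; longitudes are normalised to [−180, 180);
day-of-month may be absent (monthly analyses never use it). The analysis
window is the stratified season, July–November, over 1945–2011.

Two interchange formats are supported: a long-format CSV (one row per
level; declared precision 0.001 °C and degrees, 0.1 m depth) and a CF-style
netCDF contiguous ragged array (one `obs` record dimension plus a
per-profile `row_size`). Malformed rows are collected into a reject report,
never silently dropped, so level counts always satisfy
*in = kept + rejected*.

## Quality control

The screening battery reproduces the function of a standard hydrographic
QC procedure; each threshold is a `QCConfig` field:

| rule | default | rationale |
|---|---|---|
| out_of_region | 30–46 °N, −6–36.5 °E | basin bounding box |
| out_of_window | 1945–2011 | systematically archived record |
| bad_month | months ∉ {7…11} | stratified season only |
| gross_range | outside 3–35 °C | brackets upper-layer values with margin |
| spike | dev > 3 °C within 5 m | interior test, see below |
| non_monotonic_depth | any Δz ≤ 0 | depth inversion/repeat |
| constant_value | ≥3 identical levels | stuck sensor |
| too_few_levels | <2 levels in 0–50 m | cannot interpolate |
| no_shallow_data | shallowest > 10 m | surface layer unsampled |
| duplicate | 1 km, 24 h, same instrument | repeated station occupation |

The spike statistic is |T(z) − median of neighbours within 5 m|, evaluated
only at levels with at least one neighbour on *each* side of the window.
Endpoint deviations are excluded deliberately: across a sharp thermocline
the real vertical gradient over 5 m can exceed 3 °C, and a one-sided
comparison would flag genuine structure (measured false-positive rate with
the interior rule on clean synthetic casts: none in 2×10⁴ casts at noise
SD 0.3 °C; isolated ~5σ events can still occur at 0.5 °C).

A profile failing any rule is discarded wholesale — no single-level
editing — which keeps the contract simple and conservative. Duplicate
groups keep the cast with the most levels (ties: deepest, then smallest
id). QC is idempotent and monotone in its thresholds (tested). The default
synthetic defect mix discards ≈15% of casts, the loss fraction typical of
a real archive of this kind.

## Vertical interpolation and layers

Casts are linearly interpolated onto integer depths 0–50 m strictly within
[shallowest, deepest] level — no extrapolation, so depth 0 is defined only
when a level sits at the surface. (A constant surface fill from the
shallowest level is available behind `surface_fill=True` but is off by
default; the no-extrapolation invariant is the contract.) Layer means over
0–10 / 11–30 / 31–50 m (and the merged 0–50 m band) are unweighted means
of the defined grid values — the natural discretisation of a depth average
on a uniform 1 m grid — and are reported only when at least 50% of the
layer's depths are defined, so a partially sampled layer reads as missing
rather than biased toward whichever part was sampled.

## Gridded trends and significance

Per 1°×1° cell (half-open edges, lower edge inclusive; index =
floor(coordinate)) and layer, the yearly value is the plain mean of layer
means over all casts of that cell, year and selected months. The trend is
the OLS slope of yearly value on calendar year; significance is the
two-sided t-test on the slope at α = 0.10 ("90%"). Cells with fewer than
`min_years = 10` distinct years are reported as insufficient rather than
non-significant — a regression through a handful of years is meaningless,
and the floor is configurable. The merged 0–50 m trend is fitted from its
own 0–50 m layer means, not averaged from per-layer slopes.

Calibration: under a no-trend generator with time-homogeneous sampling the
significance mask fires in 9.3% of 1,000 cells (within the 10% ± 2%
expectation; computed in the test suite). Under the *inhomogeneous*
default sampling — densest mid-record, mimicking real archives — the same
test fires in ~15% of cells: sparse (noisier) years at the record's ends
carry the highest leverage, inflating the plain t-test. This is a genuine
property of per-cell OLS on such archives and is left visible rather than
corrected (no weighted/robust variant is claimed by the method).

## Climatology, anomalies, extremes

Within a named ~2°×2° box, monthly climatologies are per-depth means and
sample (n−1) SDs over all in-box casts of a calendar month and reference
period — 1945–1982 (before the first documented mortality event, 1983) vs
1983–2011 — with depths sampled by fewer than `n_min = 3` casts masked.
The event-month profile is the mean over *all* in-box casts of that month
and year (not only casts at the mortality site); its anomaly is reported
against each period climatology together with the maximum positive anomaly
and its depth (first occurrence from the surface on ties). Absence of
event-month data is an explicit `no_data` result, never a zero anomaly.

A *positive temperature extreme* is a cast whose layer-mean temperature
exceeds the full-period (1945–2011) reference mean, or the mean plus one
SD; frequencies are tabulated per (box, layer, month, period) as counts
and proportions. The five default box rectangles (Ligurian Sea, Provence
Coast, Eastern/Western Tyrrhenian, Balearic–Columbretes) are editable
defaults — exact published bounds are not available. A per-box seafloor
depth limit is honoured only when casts carry a seafloor attribute;
otherwise the box is used as-is with a logged warning (no bathymetry
database dependency).

## Event catalog

One row = one (event, location) record; multi-site outbreaks (e.g. one
event along 1,000 km of coastline) share an `event_id`/`group_id`, since
the association stage matches locations to cells individually. `n.r.`
marks absent values and round-trips. Percent intensities parse
numerically. Events lacking a month are excluded from anomaly matching but
kept in the (year-insensitive) trend-sign association. The bundled
`s1_events_synthetic.csv` is a synthetic stand-in for a published review
table, constructed to carry the documented tallies (19 distinct events, 59
species, 35 publication keys, 1983–2009) and regional structure.

## Association statistics

Each event is matched to the cell containing its coordinates, against the
merged 0–50 m trend by default (`band_0_50`), or one assignment per
overlapped depth layer (`per_layer`) with weights 1/k so a three-layer
event is not triple-counted (an unweighted mode reproduces row counting).
By default only cells significant at 90% participate; a flag reruns
everything over all assessed cells.

* **Sign ratios** — occurrence counts by slope sign, reported as 1:k
  (k = larger/smaller; a one-sided outcome reports 0:n without division),
  next to the same ratio over available significant cells. An exactly zero
  slope counts as positive and is logged (measure-zero, documented for
  determinism).
* **Binned distribution** — five equal-width intervals partitioning the
  significant map's slope range (not the event slopes' range), right-open
  except the last; degenerate range collapses to one bin.
* **KS test** — primary: one-sample KS of the matched slopes against the
  uniform distribution on [min, max] of the significant map's slopes,
  asymptotic p. The published description (binned occurrences vs uniform)
  is unusual for a KS statistic; the continuous form is the well-defined
  reading, and the binned histogram plus a two-sample KS (event slopes vs
  all cell slopes) are reported alongside. Fewer than 3 assignments yields
  an explicit underpowered result. Under uniform placement on a
  uniform-slope significant map the test rejects at α = 0.01 in 1.8% of
  500 replicate catalogs; with placement ∝ exp(10·β) on a strong-contrast
  field (β ∈ [−0.15, 0.25] °C/yr, chosen so γ·range ≈ 4) it rejects in
  100% of 500 replicates at n = 33 (both computed in the test suite).

## Synthetic generator

The column model is the minimal smooth stratified profile consistent with
observed summer profiles:

    T(cell, year, month, z) = T_deep
        + (ΔT_month + β_cell · (year − 1945)) · (1 − tanh((z − z_th)/w)) / 2

with defaults T_deep = 13.5 °C (intermediate-water temperature of a
temperate marginal sea), surface excesses ΔT = 10.5/12.5/11/7.5/4.5 °C for
July–November, thermocline centre z_th = 20 m and width w = 10 m. The
trend β acts on the warm-layer amplitude, so the *measured* trend at depth
z is β·(1 − tanh((z−z_th)/w))/2 — surface layers carry nearly the full β,
the 31–50 m layer almost none, and the 0–50 m band mean is ≈ 0.40·β.
Tests of trend recovery account for this attenuation explicitly (or use a
deep-thermocline configuration in which the 0–50 m column is well mixed
and the measured trend equals β).

Realism choices, fixed once: Gaussian level noise SD 0.5 °C (instrument
error plus submesoscale variability); instrument mix bottle/MBT/XBT/CTD =
15/30/40/15% with level spacings 10/5/2/1 m and maximum depths 100/60/80/
100 m; casts per cell-year Poisson with mean 2.0 (the scale of ~10⁵ casts
over ~680 marine cells and 67 years), modulated by a mid-record bump
(peak ≈ 1980) mimicking archive inhomogeneity; defect injection mutually
exclusive per cast at per-rule rates summing to 15%. Mortality events are
placed over cells with probability ∝ exp(γ·β) (γ = 0 is the uniform null;
default γ = 10), with late-summer-weighted start months and catalog years
1983–2009. Truth sidecars record each cast's cell/β/defect and each
event's cell/β.

The generator deliberately omits advection, salinity, mixed-layer physics,
instrument depth biases (e.g. XBT fall-rate error) and spatial correlation
of noise. Passing tests therefore demonstrate the *statistical machinery*
— QC bookkeeping, estimator calibration, association power — not oceanic
realism; conclusions about real archives inherit all the caveats of the
underlying method (notably the type-I inflation under inhomogeneous
sampling documented above).

## Problem sizes

The suite's simulation tests use: 1,000 cells × 67 years at 2 casts/
cell-year for type-I calibration; 60-cell maps at 6 casts/cell-year with
500 replicate 33-event catalogs for KS null and power; 2×2 cells at 8
casts/cell-year for trend recovery; 50 replicates of a one-cell box at 15
casts/cell-year for anomaly-depth recovery. The acceptance script
simulates a 189-cell basin at the default density. These sizes were chosen
as the smallest at which the binomial tolerances of the checks are
meaningful.

## Known limitations

* Per-cell OLS ignores serial correlation and heteroscedasticity of yearly
  means; the significance mask is nominal only under homogeneous sampling.
* The spike test cannot screen endpoint glitches, by design.
* Layer means from the 1 m grid assume the linear-in-depth interpolant;
  casts sampled more coarsely than ~20 m resolve the thermocline poorly.
* The association is an observational co-occurrence statistic: events are
  recorded only as positive outcomes, with no survey-effort correction.
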