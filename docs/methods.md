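# Methods

This note records the modelling choices behind `chillscape`: the models
and their assumptions, the parameters that matter, what the synthetic
generator does and does not emulate, the numerical conventions, and the
places where the design was genuinely open and a choice had to be made.

## Calendar

Every stage runs on a 365-day ("no-leap") calendar: February 29 is removed
on ingest and never generated. This makes day-of-year arithmetic uniform —
March 1 is day 60 in every year, a 30-year daily series is always 10,950
records, and the November 1 – February 28 chill window is always 120 days.
The alternative (keeping Feb 29 outside the bias-correction step only)
would make window lengths and DOY thresholds year-dependent for no
analytical gain.

## Hourly reconstruction

Chill and heat models need hourly input; the data are daily extremes.
Hours are reconstructed with the standard horticultural diurnal-curve
model:

- Solar declination from the Spencer Fourier series with a 365-day
  denominator; hour angle `ωs = arccos(−tan φ · tan δ)`; daylength
  `= 24·ωs/π`; sunrise/sunset symmetric about solar noon. Latitudes are
  restricted to |φ| ≤ 66° (no polar day/night).
- Daytime (`sunrise ≤ h ≤ sunset`):
  `T = Tmin + (Tmax − Tmin)·sin(π(h − sunrise)/(daylength + 4))`. The
  4-hour stretch places the daily maximum about two hours after solar
  noon for a 12-hour day and guarantees the peak falls before sunset
  whenever daylength ≥ 4 h (shorter days raise an error).
- Night, `n` hours after sunset (`n` clamped to [1, night_length] to avoid
  `ln 0` and overshoot): `T = Ts − (Ts − Tmin_next)·ln(n)/ln(night_length)`
  where `Ts` is the *sine-curve value at sunset*, not Tmax — this keeps
  the piecewise curve continuous. The curve lands exactly on the next
  day's minimum at `n = night_length`. Pre-sunrise hours continue the
  previous day's night curve toward the current day's minimum.
- The hour grid is integer solar hours 0–23. No longitude/time-zone
  correction is applied: chill and heat sums are insensitive to a constant
  phase shift of the whole day. Consequences of the discretization: a
  day's hourly maximum undershoots Tmax by at most
  `(Tmax − Tmin)·(π/(2(daylength+4)))²/2` (≈ 0.5 % of the range for a
  12-hour day).

The model assumes an idealized clear-sky diurnal cycle; fronts, wind and
cloud are not represented. That is a property of the reconstruction
tradition itself, not of this implementation.

## Chill portions (Dynamic Model)

Two-step kinetic model: hourly temperature drives an intermediate product
`E`; when `E ≥ 1` a portion `xi·E` is banked irreversibly and the
intermediate is reduced by the delivered share on the next step. Constants
are the canonical published set (`slp = 1.6`, `tetmlt = 277 K`,
`a0 = 1.395e5`, `a1 = 2.567e18`, `e0 = 4153.5 K`, `e1 = 12888.8 K`) with a
273 K Celsius offset to match the lineage of the reference
implementations. The state carries `xi` of the previous hour because the
recursion's over-threshold branch needs it; a two-field state would be
subtly wrong.

Accumulation starts from a zero state on November 1 each season with no
carry-over between seasons (the fixed-window definition). The vectorized
accumulator (time-sequential, broadcast across cells × seasons) is tested
to 1e-9 against an independent scalar transliteration of the recursion.

One property worth knowing: chill delivery is quantized in ~1-portion
events, so the CP-vs-constant-temperature curve at fixed window length is
unimodal only up to sub-portion wiggles (≤ ~0.25 portions at a 0.25 °C
scan step) where a delivery slips past the window edge. Tests assert
unimodality with a one-portion tolerance.

## Growing degree hours

Cosine response with base 4 °C, optimum 26 °C (as used in the regional
literature this package follows; the original formulation used 25 °C —
a parameter difference, not a structural one), critical 36 °C, stress
factor fixed at 1. Zero outside [4, 36], continuous everywhere, maximum
22 degree-hours at the optimum. Heat window February 1 – March 31
(59 days, 1,416 hours), so a constant-optimum window accumulates
31,152 GDH exactly.

## Spring frost probability

Seasons span October–June. The last frost is the latest day with
Tmin ≤ 0 °C (inclusive threshold) in the January–June segment. Two edge
cases are resolved explicitly, since DOY indexing alone would get them
wrong:

- a season whose only frosts fall in October–December carries a DOY of
  274–365 from the *previous* calendar year; counting it as "after day
  60" would misread autumn frost as late-spring frost, so such seasons
  are treated as having no spring frost;
- frost-free seasons stay in the denominator (SFPO is a probability over
  seasons) and never enter the numerator.

SFPO = 1 − CDF(60), evaluated in exact counting arithmetic so the result
equals the per-season indicator mean bit for bit. Raising the threshold
can only lower SFPO.

## Quantile-mapping bias correction

Per cell and variable, empirical quantiles at knots 0, 0.05, …, 1
(endpoints included — "resolution 0.05" read literally) of the observed
and the model-historical calibration series (1971–2000 by default, pooled
over all days of the year; monthly stratification was considered and left
out because the underlying description is of a single CDF per series).
Correction interpolates linearly between knot pairs; beyond the calibrated
range a constant additive offset from the nearest end knot is used, which
encodes the usual bias-stationarity assumption. Tmin and Tmax are
corrected independently; any corrected pair with tmax < tmin is repaired
by swapping. Correction is applied per ensemble member before any
ensemble statistic.

Two analytical facts shape the recovery tests:

- Under a pure scale bias `s` on anomalies, EQM's transfer is effectively
  `x → μ + (x − μ)/s`, which rescales any additive trend by `1/s`: EQM is
  not trend-preserving under multiplicative bias. Scale-recovery is
  therefore assessed on trend-free future draws (exactly the stationary
  regime the method assumes), additive-recovery on warming draws (where
  the edge policy makes the correction exact).
- The corrected series inherits the sampling difference between the two
  30-year calibration climatologies (~0.08 °C sd per cell here) — any
  quantile mapping does. Recovery error is therefore measured as a
  grid-mean over 9 cells (~0.03 °C sampling noise), which exposes the
  mapping's systematic error rather than a coin flip on sampling noise.
  Measured systematic recovery error: ≤ 0.02 °C for additive biases of
  ±1/±3 °C and scale factors 0.8/1.2.

## Synthetic climate generator

The generator emulates the statistical structure the pipeline needs, with
known ground truth:

| parameter | default | meaning |
| --- | --- | --- |
| `annual_mean_at_sea_level` | 16.5 °C | annual-mean Tmean at 0 m |
| `seasonal_amplitude` | 8.5 °C | half-range of the annual cosine (peak day 197) |
| `lapse_rate` | 6.5 °C/km | linear elevation lapse of the mean |
| `diurnal_range_mean` | 10 °C | mean Tmax − Tmin |
| `ar1_rho` | 0.7 | day-to-day persistence of the anomaly |
| `noise_sd` | 2.0 °C | *marginal* sd of the AR(1) anomaly |
| `warming_per_decade` | 0.3 °C | scenario trend (×1 RCP4.5, ×2 RCP8.5) from 2006 |
| `model_bias_add` | +1.0 °C | additive model bias |
| `model_bias_mult` | 1.1 | multiplicative bias on anomalies |

Tmean is base + seasonal cosine + AR(1) noise; Tmin/Tmax sit half a
diurnal range below/above with independent perturbations
(sd = 0.5·noise_sd each) and a swap repair, so Tmin and Tmax share the
synoptic signal but are not perfectly coupled. Model members redraw the
noise (streams keyed on seed, member, scenario and start year) and apply
`+bias_add + (bias_mult − 1)·(value − cell mean) + trend`.

The defaults sketch an Ebro-valley-like region: a 100-cell grid spanning
150–1500 m with a south–north elevation gradient yields valley floors with
moderate late-frost risk, mid-slopes where SFPO transitions to ~1, winters
delivering 60–100 chill portions, and springs of a few thousand GDH.
What the generator does *not* emulate: spatially correlated weather
(cells are independent draws around a smooth mean surface), skewed or
heavy-tailed temperature distributions, elevation-dependent diurnal range,
cold-air pooling, and trend nonlinearity. Passing tests therefore
demonstrate correctness of the *machinery* under controlled conditions,
not climatological fidelity for any real region.

## Periods, anomalies, change indices

30-year windows stepped by 10 years, anchored at the series end (1950–2020
gives 1951–1980 … 1991–2020). The standardized-anomaly denominator is the
per-cell interannual sample sd (ddof = 1 throughout) of the 1971–2000
reference — the only reference-period spread the pipeline computes;
spatial-sd standardization would answer a different question. SFPO is a
single probability per period (pooled over member-seasons), so its change
is reported as a delta only. Change indices aggregate Sa across the
scenario × period axis per cell; `magnitude ≥ |direction|` always, with
equality exactly when all anomalies share one sign.

## Bivariate densities

CP–GDH and CP–SFPO pairs are taken over fruit-area cells only (period
means per cell), trimmed to the marginal [q5, q95] box, min–max scaled to
the unit square, and smoothed with an isotropic Gaussian kernel of
sd 0.1 *in scaled units* — the natural reading of a single bandwidth
applied to variables whose raw scales differ by two orders of magnitude.
The surface is divided by its maximum to land in [0, 1]; the
pre-normalization integral is retained and checked against 1 by grid
quadrature. Spearman rho uses mid-ranks and returns NaN when a margin is
constant (e.g. frost probability collapsing to zero everywhere under
strong warming). Quantiles everywhere use linear interpolation between
order statistics. Fewer than 20 fruit-area pairs make the q5–q95 trim
meaningless, so density blocks are skipped (with a warning) on very small
grids.

## Pipeline and problem sizes

The end-to-end synthetic study runs 100 fine cells (10 × 10 lattice,
coarse model grid every 5th cell per axis → 2 × 2), 35 observational
years (1966–2000, reference 1971–2000), and 2 scenarios × 2 members ×
30 future years (2041–2070, members simulated from 2040 so every season's
October–June span is covered). These sizes keep a full run around half a
minute on one core while leaving every stage statistically meaningful;
larger grids and the five historical windows are available through
`PipelineConfig`. Bilinear regridding precomputes node weights once
(exact for affine fields, clamped to the coarse bounding box at the rim);
hourly reconstruction is chunked over ~1500-day blocks with a one-day halo
to bound memory. Outputs are deterministic CSV (fixed float format), so
reruns with the same seed are byte-identical. Coordinates are abstract
lon/lat: no CRS handling, by design.

## Known limitations

- The diurnal-curve and frost statistics assume the no-leap calendar; real
  data must be passed through `drop_leap_days` first.
- EQM with pooled calibration cannot correct seasonally varying bias and
  is not trend-preserving under multiplicative bias (see above).
- SFPO from 30 seasons has a resolution of 1/30 ≈ 0.033; per-cell deltas
  smaller than that are not interpretable.
- NetCDF export uses the NetCDF3 (scipy) backend with integer time
  indices plus year/doy variables rather than encoded CF times.
- The Spearman/KDE summaries describe association over cells, not causal
  or process relationships between chill and heat.
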