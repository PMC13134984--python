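# chillscape

Agroclimatic analysis of temperate fruit-growing regions on gridded daily
temperatures: winter chill, spring heat, late-frost risk, and how all three
shift under climate-model projections.

## Who this is for

Researchers in horticultural climatology and agroclimatic risk assessment
who need a tested, reproducible implementation of the standard indicator
chain — from daily Tmin/Tmax grids to bias-corrected scenario maps of
chill portions, growing degree hours and spring-frost probability — without
hand-rolling the hourly reconstruction, the kinetic chill model or the
quantile-mapping machinery each time.

## The models

**Chill portions (CP), Dynamic Model.** Winter chill accumulates in two
kinetic steps: low temperatures build an intermediate product

- `xi(T) = sr/(1+sr)`, `sr = exp(slp·tetmlt·(T_K − tetmlt)/T_K)`
- `xs(T) = (a0/a1)·exp((e1−e0)/T_K)`, `ak1(T) = a1·exp(−e1/T_K)`
- `E_t = xs − (xs − S)·exp(−ak1)`, with `S = E_{t−1}` below the threshold
  and `S = E_{t−1}(1 − xi_{t−1})` above it

and whenever `E ≥ 1` a portion `xi·E` is irreversibly banked. High
temperatures destroy the intermediate, so heat can cancel partial progress
but never banked portions. Accumulated hourly over a fixed window
November 1 – February 28 (120 days in the package's 365-day calendar).

**Growing degree hours (GDH, Anderson-type).** Each hour at temperature T
contributes a cosine response between the 4 °C base and 36 °C critical
temperature, peaking at 22 degree-hours at the 26 °C optimum, summed over
February 1 – March 31 (1,416 hours).

**Spring frost probability of occurrence (SFPO).** Per season
(October–June), the last day with Tmin ≤ 0 °C; SFPO is the empirical
probability over seasons that this day falls after March 1 (day-of-year
60): `SFPO = 1 − CDF(60)` of the last-frost DOY sample.

**Hourly reconstruction.** Hourly temperatures come from daily extremes via
a sine rise from sunrise to the daily maximum and a logarithmic nocturnal
decline toward the next day's minimum, with sunrise/sunset from the
Spencer declination series and the day-of-year/latitude geometry.

**Bias correction (EQM).** Model series are corrected per cell and
variable by empirical quantile mapping calibrated on 1971–2000 at
probability knots 0, 0.05, …, 1, with constant additive extrapolation
beyond the calibrated range.

**Change analysis.** Indicators are averaged over overlapping 30-year
windows; period deltas are standardized by the reference period's
interannual spread (`Sa = Δ/sd_ref`), and per-cell change indices summarize
them: magnitude = mean |Sa|, direction = mean Sa, variability = sd of Sa.
Bivariate CP–GDH and CP–SFPO structure over fruit-growing cells is
summarized by q5–q95-filtered Gaussian kernel densities (bandwidth 0.1 in
min–max-scaled units), Spearman rho and quartile statistics.

A synthetic-data module generates observation-like fine grids and biased,
trend-bearing coarse model ensembles with known ground truth, so the whole
chain is testable without any external download.

## Worked example

```python
import numpy as np
from chillscape import (SyntheticParams, make_grid, simulate_daily_obs,
                        chill_accumulate, gdh_hour, sfpo)
from chillscape.indicators import seasonal_indicators, seasonal_last_frosts

grid = make_grid(9, seed=11)
obs = simulate_daily_obs(grid, 1995, 2000, SyntheticParams(seed=5))
ind = seasonal_indicators(obs, grid.lat)
print(ind.groupby("season")[["cp", "gdh"]].mean().round(1))

frost = seasonal_last_frosts(obs)
events = frost.loc[frost.cell_id == 0, "last_frost_doy"]
print("cell 0 SFPO:", sfpo([None if np.isnan(d) else int(d) for d in events]).probability)
```

prints

```
          cp     gdh
season
1996    82.6  3081.9
1997    84.4  3065.3
1998    83.5  2938.6
1999    82.4  2883.2
2000    83.3  2918.5
cell 0 SFPO: 0.0
```

Around 83 chill portions per winter would satisfy even high-chill species,
while ~3,000 degree-hours by the end of March is a cool spring — this
synthetic grid emulates a cold-winter region. Cell 0 (the lowest, warmest
corner of the grid) saw no frost after March 1 in any of the five seasons,
so its empirical late-frost probability is 0.

The same stages are available from the shell:

```sh
chillscape simulate --n-cells 16 --years 1971:2000 --seed 1 --out obs.csv
chillscape indicators --in obs.csv --grid obs.grid.csv --out indicators.csv
chillscape frost --in obs.csv --out sfpo.csv
chillscape run-all --seed 1 --out bundle/
```

## Layout

| module | contents |
| --- | --- |
| `chillscape.calendar365` | 365-day calendar arithmetic, Feb 29 removal |
| `chillscape.grid` / `synthetic` | grids and the synthetic climate generator |
| `chillscape.solar` | declination, daylength, hourly reconstruction |
| `chillscape.thermal` | Dynamic Model chill + GDH over fixed windows |
| `chillscape.frost` | last-frost extraction, empirical CDF, SFPO |
| `chillscape.eqm` | empirical quantile mapping + diagnostics |
| `chillscape.anomaly` | 30-year windows, Δ/Sa, change indices |
| `chillscape.density` | q5–q95 filter, 2-D KDE, Spearman, quartiles |
| `chillscape.pipeline` / `cli` | end-to-end orchestration and `chillscape` CLI |

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
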