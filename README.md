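# herpranges

Simulation-based comparison of space-use estimators for reptile VHF
radio-telemetry: can the estimators herpetologists actually use —
Minimum Convex Polygons (MCP) and fixed Kernel Density Estimation (KDE)
— represent where a tracked reptile moved, and does the dynamic Brownian
Bridge Movement Model (dBBMM) do better under realistic, sparse tracking
schedules?

The package is aimed at movement ecologists designing VHF tracking
studies (and at methodologists auditing estimator behaviour). Everything
is synthetic and self-contained: no field data are required.

## What it does

1. **Simulates archetypal reptile movement** from a 3-state hidden
   Markov model — sheltering (1), moving (2), resting (3) — with
   state-dependent Gamma step lengths and near-uniform von Mises turning
   angles (κ ≈ 0.01). Transition probabilities use a multinomial logit
   with diagonal reference,

   η<sub>ij</sub> = β<sub>0,ij</sub> + a<sub>ij</sub> cos(2πt/T) +
   b<sub>ij</sub> sin(2πt/T) + c<sub>ij</sub> z(x,y),

   where T = 24 h for transitions into resting (circadian rhythm), T =
   a multi-day shelter period for transitions into sheltering, and
   z(x, y) is a spatially autocorrelated habitat covariate (fractional
   Brownian motion landscape) acting on transitions into moving. Three
   archetypes are preset: a highly mobile active hunter, a large ambush
   forager, and a small ambush predator (moving-state mean steps
   150 / 75 / 30 m per 30 min).

2. **Thins each full-year, 30-min track (n = 17,521 fixes)** to eight
   field sampling regimes: full data; 4/day; 2/day; 1/day; 2/week;
   1/week; 1/month (1460 / 730 / 365 / 104 / 52 / 12 fixes); and
   "relocations only" (the 4/day schedule with stationary fixes
   removed).

3. **Estimates 95% space-use regions** with 95% MCP, fixed KDE under the
   reference bandwidth h<sub>ref</sub> = √((s²ₓ+s²ᵧ)/2)·n<sup>−1/6</sup>
   and under least-squares cross-validation (LSCV, with boundary-minimum
   convergence detection), and the dBBMM (sliding-window Brownian motion
   variance σ²<sub>m</sub> with BIC breakpoint selection, 5 m location
   error).

4. **Scores every estimate against the true movement pathway** — the
   union of 40 / 20 / 10 m discs (by archetype) around every simulated
   fix — via commission error (false-positive area as % of true-pathway
   area), omission error (bounded at 100%), precision, recall and the
   F-measure 2·TP/(2·TP + FP + FN), all rasterized on one shared grid
   per individual.

It also computes positional semivariograms and the number of days until
autocorrelation becomes insignificant, which shows why thinning cannot
rescue the KDE independence assumption.

## Worked example

```python
import numpy as np
import herpranges as hr

land = hr.generate_fbm_landscape(512, 512, 10.0, hurst=0.5, seed=1)
track = hr.simulate_individual(hr.archetype_presets(1), land,
                               duration_days=365, seed=1)
print(track.n_fixes)                      # 17521

monthly = hr.apply_regime(track, hr.regime_schedule(7))
print(monthly.n_fixes)                    # 12

mvs = hr.dynamic_variance_series(monthly)
grid = hr.make_grid(track.x, track.y, cell_size=10.0, padding=2000.0)
ud = hr.dbbmm_ud(monthly, mvs, grid)
region = hr.isopleth_region(ud, 0.95, "dBBMM")
truth = hr.true_pathway_buffer(track, 40.0, grid)
m = hr.score_region(region, truth)
print(round(m.commission_pct), round(m.omission_pct), round(m.f_measure, 2))
```

The last line prints commission and omission percentages and the
F-measure of the monthly-sampling dBBMM against the true pathway (for
this seed: `139 23 0.48` — at one fix per month the occurrence estimate
still finds most of the pathway, at the cost of a large false-positive
fringe).

The full study is driven by the numbered scripts in `analysis/`:

```sh
python analysis/01_simulate_tracks.py   --seed 1   # tracks + landscape
python analysis/02_autocorrelation.py   --seed 1   # variograms, independence
python analysis/03_run_estimators.py    --seed 1   # the estimator sweep
python analysis/04_summarize.py         --seed 1   # tables + regime-8 study
```

With the default desk scale (3 individuals per archetype) script 03
prints, among other rows, mean commission/omission/F per method and
regime — e.g. KDE h<sub>ref</sub> reaches ~970% commission at monthly
sampling while dBBMM stays balanced and attains the best F-measure at
every regime except the full-resolution one, and script 04 reports LSCV
convergence failure at 100% of high-frequency fits, falling to 0% at the
two coarsest regimes.

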