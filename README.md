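# voltigen

Degree-day voltinism projections for the tobacco caterpillar
(*Spodoptera litura* Fab.) on peanut under downscaled climate-change
scenarios, with an uncertainty decomposition across locations, climate
models, emission scenarios and time periods.

`voltigen` is aimed at crop-protection and pest-risk modellers who want
to ask: *if daily temperatures warm the way the GCM ensemble says they
will, how many more pest generations fit into the crop season, and which
source of uncertainty — where you are, when, which model, which
scenario — dominates the answer?*

## The model

Insect development tracks accumulated heat. Each day contributes

```
DD = max(0, min((Tmax + Tmin)/2, T_upper) − t0)
```

degree-days, with a lower developmental threshold `t0 = 10 °C` (below
it, no development) and a horizontal upper cut-off `T_upper = 37 °C`
(heat above it does not accelerate development; the daily mean is
capped). Summing DD over the peanut crop season — standard
meteorological weeks 26–44, a fixed 133-day window (days 176–308 of the
year) — gives the total degree-days TDD, and

```
N  = TDD / K          (K = 522.7 DD per egg-to-adult cycle)
GT = 133 / N          (generation time, days)
```

give the (fractional) number of generations and the mean generation
time. The study design is factorial: 6 Indian peanut-growing locations
× 7 climate models (six GCMs + their ensemble AVG) × 3 SRES emission
scenarios (A2/A1B/B1) × 4 period slices (baseline 1975, near future
2020, distant future 2050, very distant future 2080), with 20
stochastic replicate years per cell. A balanced fixed-effects ANOVA then
divides each source's sum of squares by the total SS to attribute shares
of the prediction variance to location, period, model, scenario and the
location×period interaction.

The original daily GCM weather is not deposited anywhere, so the package
ships a transparent surrogate generator (sinusoidal seasonal cycle +
Gaussian daily noise + uniform scenario warming offsets) whose annual
means are pinned to the published projected annual-mean temperature
table, bundled as `voltigen/data/annual_mean_projections.csv`.

## Worked example

```python
import voltigen as vg

climate = vg.LocationClimate("Bhubaneswar",
                             baseline_tmax_mean=31.34,
                             baseline_tmin_mean=22.77,
                             daily_noise_sd=0.0)

# baseline year
series = vg.generate_weather_series(climate, seed=1)
pred = vg.accumulate_generations(series)
print(f"TDD = {pred.tdd:.1f} DD, N = {pred.n_generations:.2f}, "
      f"GT = {pred.generation_time:.2f} d")

# very-distant-future A2 warming for the same site
off = vg.ScenarioOffset("A2", "VDF", delta_tmax=2.95, delta_tmin=2.76)
warm = vg.generate_weather_series(climate, off, seed=1)
pw = vg.accumulate_generations(warm)
print(f"TDD = {pw.tdd:.1f} DD, N = {pw.n_generations:.2f}, "
      f"GT = {pw.generation_time:.2f} d")
print(f"GT shortening: {vg.percent_change_gt(pw.generation_time, pred.generation_time):.2f} %")
```

prints

```
TDD = 2155.0 DD, N = 4.12, GT = 32.26 d
TDD = 2534.7 DD, N = 4.85, GT = 27.43 d
GT shortening: 14.98 %
```

i.e. at Bhubaneswar the noise-free baseline season accumulates 2155
degree-days — 4.12 generations of 32.3 days each — and adding the A2
2080 warming offsets (+2.95 °C Tmax, +2.76 °C Tmin) fits 4.85
generations of 27.4 days into the same 133-day window, a 15 % shorter
generation time.

The full factorial study runs from the command line:

```bash
voltigen run --seed 1 --out-dir out/
```

which writes per-replicate predictions, per-cell mean ± SE summaries,
t-tests of every future ensemble cell against its baseline, the percent
change in generation time per model × scenario × period, the variance
partition, and a manifest that reproduces the run bit-for-bit.
Subcommands `generate`, `convert`, `predict` and `analyze` expose the
individual stages (weather synthesis, DSSAT ``.WTG`` ↔ CSV conversion,
degree-day prediction, ANOVA) separately.

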