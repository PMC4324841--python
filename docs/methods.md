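# Methods

## The degree-day voltinism model

Development of *S. litura* is modelled as a linear function of
temperature above a lower threshold. The daily heat unit is the
simple-average formula with a horizontal upper cut-off:

    DD(d) = max(0, min((Tmax_d + Tmin_d)/2, T_upper) − t0)

The cut-off is applied to the *daily mean* before subtracting the
threshold. The horizontal convention means temperatures above `T_upper`
neither add nor subtract development — the daily contribution saturates
at `T_upper − t0` (27 DD with the defaults). Days whose mean falls below
`t0` contribute zero; the raw formula would go negative, but degree-day
practice (and the biology: development ceases, it does not reverse)
forbids negative accumulation.

Parameters, with defaults:

| parameter | default | units | meaning |
|---|---|---|---|
| `t0` | 10 | °C | lower developmental threshold for *S. litura* on peanut |
| `T_upper` | 37 | °C | horizontal upper cut-off |
| `K` | 522.7 | DD | thermal constant, egg→adult |
| season | weeks 26–44 | standard weeks | peanut crop window, 133 days |

Standard week `w` is defined as days `7(w−1)+1 … 7w` of the calendar
year (week 1 = Jan 1–7; day 365/366 belongs to no week). This is the
only convention under which weeks 26–44 comprise exactly 19 × 7 = 133
days, which fixes the window at days 176–308. The window is deliberately
*not* the calendar year: accumulation is restricted to the crop season,
so the estimates are conservative with respect to any future lengthening
of the growing season. Within the default window, daily means
essentially never reach the 37 °C cut-off; the cap matters only for
calendar-year-style uses and for stress tests.

Accumulation: `H(d) = Σ DD` over the window; `TDD = H(end)`; the number
of generations is the *fractional* `N = TDD / K` (an
`integer_generations` option floors it for comparison with
integer-voltinism conventions). Boundary days record where each multiple
of `K` is first attained. The per-generation accumulated DD (`mean_gdd`)
is reported as a self-check: it can exceed `K` only by the sub-daily
overshoot of the day that closes a generation, so a large deviation from
`K` signals an accumulation bug.

Generation time has two definitions:

- **window** (default): `GT = 133 / N`, fractional generations included.
  Chosen because the published per-cell summaries satisfy `N × GT ≈ 133`
  almost everywhere, so this is evidently the convention behind them.
- **boundary** (option): the mean interval between successive completed
  generation boundaries. Retained because "average development time" is
  also a defensible reading; it differs from the window definition by
  excluding the incomplete final generation.

A small numerical tolerance (1e-9 relative to `K`) is applied when
testing whether the cumulative sum has reached a multiple of `K`, so
constant-DD series that land exactly on a boundary are counted
deterministically.

## The surrogate weather generator

The original inputs were replicate daily weather years from a stochastic
downscaling generator driven by six GCMs; neither the daily data nor the
generator's fitted parameters are available. The downstream engine
consumes only daily Tmax/Tmin, and the published constraint on the
climate inputs is the table of projected *annual means* per location ×
scenario × period. The surrogate therefore models each variable as

    T(d) = annual_mean + A·cos(2π(d − peak_day)/365) + Δ + ε,  ε ~ N(0, σ²)

- The cosine sums exactly to zero over the year, so the noise-free
  annual mean equals `annual_mean + Δ` to machine precision — the
  generator is pinned to the published table by construction.
- Scenario/period offsets Δ are the column-wise differences of the
  published annual-mean table against its 1975 baseline row, applied
  uniformly to every day. Baseline offsets are zero by definition.
- Seasonal amplitude defaults to 4 °C with the warmest day at day-of-year
  135 (pre-monsoon peak, plausible for peninsular India). Amplitude and
  phase do not move annual means and only weakly affect window sums.
- Daily noise defaults to σ = 1 °C, independent across days and between
  Tmax and Tmin — the simplest replicate model that yields a non-zero
  standard error across 20 replicates. Replicate `r` draws from a child
  seed derived deterministically from `(seed, r)`.
- Days where noise inverts the order (Tmin > Tmax) are repaired by
  swapping the two values. Swapping preserves the daily mean (hence all
  degree-day quantities), the day count and seed determinism; rejection
  sampling would preserve none of the latter two.
- Baseline cells are generated noise-free, so their 20 replicates are
  identical and the cell SE is exactly 0.00 — matching the published
  baseline convention and exercising the degenerate-variance t-test
  path that the published tables imply.

What the surrogate does **not** emulate: rainfall coupling, solar
radiation, autocorrelated spells, skewness, monthly-resolved anomalies,
or any per-model spatial structure. Consequently, passing tests show
that the *pipeline* is correct and that annual-mean-driven conclusions
(directions of effect, orders of magnitude, variance attribution
mechanics) follow from the published temperature table — not that the
surrogate reproduces the original daily weather. The published headline
voltinism values (e.g. specific cell means near 5.6 generations)
depend on the undeposited daily data and are out of reach by design.

### Per-model offsets

The published record gives scenario-level annual means but no per-model
daily climates, only a qualitative ranking (CNR, ECH, CSI project
warmer; BCC, MIR cooler). Each GCM is therefore assigned a fixed
multiplicative scale on the scenario warming offset:

    BCC 0.88, CNR 1.12, CSI 1.08, ECH 1.10, INM 0.95, MIR 0.92

The spread (±12 %) keeps the model factor a small contributor to total
variance, consistent with the study's finding that model choice explains
little. All models coincide at baseline, where the offset is zero. The
ensemble model AVG is, by default, the day-wise average of the six model
weather series per replicate index, computed *before* degree-day
accumulation ("weather" mode); averaging the six predictions instead is
available ("predictions" mode). The two differ only where the capped
degree-day map is active (it is concave, so weather-first averaging
never yields fewer degree-days); far from the cut-off they coincide.

## Statistics

- **Warming deltas** are plain cell-wise subtractions against the
  baseline row; aggregates are the extremes over future cells and the
  per-scenario 2080 mean over 6 locations × {Tmax, Tmin}. Deltas may be
  negative (the table prints one future cell cooler than baseline).
- **Percent change in generation time** is
  `100 · (GT_BL − GT_future)/GT_BL`; positive = shortening.
- **t-tests** are two-sample, two-sided, equal-variance (pooled), df =
  n₁+n₂−2, no multiple-testing correction, with a `p < 0.01` flag. When
  one sample has zero variance (the noise-free baseline), the pooled
  formula carries the other sample's variance alone; this is computed
  directly and flagged. Variances below a relative tolerance of 1e-9
  are treated as zero so that replicates identical by construction do
  not produce a catastrophically cancelled t. Both samples degenerate
  with equal means → t undefined, reported as NaN.
- **Variance partition**: fixed-effects OLS ANOVA with sequential
  (Type I) sums of squares via statsmodels. The factorial design is
  balanced, where all SS types coincide and the decomposition is
  order-independent — asserted at runtime by refitting with the source
  order reversed. Main effects and the location×period interaction are
  reported separately; all remaining interactions and replicate noise
  are pooled into "others", so shares always total 100 %. Unbalanced
  inputs are rejected (no Type-II/III fallback) with the offending cell
  counts. The baseline period is excluded from the partition by default
  (the quantities of interest are departures from it); a flag includes
  it. The replicate-level values are analysed, not cell means, since
  the published SE columns imply replicate data.

## Problem sizes

The default study is the full published design: 6 × 7 × 3 × 4 = 504
cells × 20 replicates = 10 080 replicate-years of 365 days, which runs
in well under a minute on a single core. Property-based checks use 1000
random series for the accumulation-oracle equivalence and a 200-run
seeded simulation for ranking recovery of planted variance shares.

## Known limitations

- Uniform annual offsets cannot produce seasonal redistribution of
  warming; location×period interaction in the surrogate arises only
  through the (rarely active) nonlinearities, so its share is smaller
  than in the original study.
- The DSSAT dialect writer emits two-digit-year date tokens (pivot
  1970) where unambiguous and four-digit years otherwise; temperatures
  round-trip at one decimal place.
- A cluster of published near-future cells violates `N × GT ≈ 133` by
  up to ~11 % (median cell deviation is ~0.4 %); the consistency check
  reports rather than hides this.
- One published future cell (Junagadh, B1, 2020) is printed cooler than
  baseline; any generator faithful to the published annual means must
  predict fewer generations there, and does.
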