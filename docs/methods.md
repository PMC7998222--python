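# Methods

## Model and conventions

`vinephen` implements single-phase thermal-forcing phenology models at
daily resolution. A phenophase is predicted on the first day whose
cumulative forcing, summed from the start day `t0` **inclusive**, reaches
the critical value `F*`; ties are resolved to the first crossing day, and
the predicted event is reported as a whole day with no sub-daily
interpolation of the crossing. The driving variable is the daily **mean**
temperature for all three rate functions; daily minima and maxima are
carried for quality control and synthetic realism only.

The day coordinate is an integer axis anchored at Jan 1 of the event year
(= day 1). Days of the previous calendar year take indices ≤ 0; Sep 1 is
always day −121 (Sep 1–Dec 31 spans 122 days in any year), and leap years
are handled by calendar lookup rather than a fixed 365-day year. This
back-extended axis lets `t0` range into the previous autumn, which the
start-window comparison requires.

Boundary conventions of the rate functions: the GDD rate is exactly 0 at
`x = Tb`; the triangular rate is 0 **at and beyond** both outer cardinal
temperatures (`x ≤ Tmin`, `x ≥ Tmax`) and 1 at `Topt`; the UniFORC
sigmoid is hard-zero below 0 °C — an unusual printed cutoff in this model
family, implemented as printed — and `expit` is used so extreme arguments
saturate instead of overflowing.

Degenerate inputs are loud: gapped or temperature-inverted series are
construction errors; a threshold never reached within the series is an
explicit no-event value (`None`), distinct from exceptions for malformed
input. Missing days in meteorology files are a hard error by default;
linear interpolation across gaps of at most 3 days is available behind an
explicit flag, because silent gap-filling biases accumulation.

## Calibration

The loss is the residual sum of squares (SSres) of predicted vs observed
event days. Minimising SSres simultaneously maximises EFF and minimises
RMSE, so one criterion drives all the reported selection metrics. A
variety-year whose forcing never reaches `F*` is predicted at the last
day of its series — a large but finite penalty that keeps the search
landscape defined everywhere.

`F*` is not a free search dimension. Given the threshold parameters, the
accumulation reached at each observed event day defines the informative
range of thresholds, and the objective profiles `F*` over two candidates:
the **minimum** and the **mean** of those accumulations, keeping the
SSres minimiser (ties to the smaller value). The minimum candidate makes
noiseless data exactly recoverable: any threshold between the latest
pre-event accumulation and the earliest event-day accumulation predicts
every year exactly, and the minimum always lies in that interval when it
is non-empty. The mean is the natural estimate under date noise. Richer
candidate sets were deliberately avoided — giving the profile more
freedom lets the search reproduce observation noise and biases the fitted
base temperature low. The public `estimate_fstar` helper reports the
plain mean of the event-day accumulations (excluding, with a warning,
years that accumulate nothing), which inverts generating thresholds
exactly when crossings are exact; with day-resolution crossings any value
in the zero-loss interval is observationally equivalent, so "the"
generating `F*` is identified only up to that interval.

The search is Metropolis simulated annealing with geometric cooling
(`T_{k+1} = 0.95 T_k`), 200 single-parameter proposals per temperature
level, 30 levels, and 10 independent restarts; all settings are
config-overridable, and tests and the acceptance script use lighter
settings (documented per run) since the checks there are structural.
Proposals are Gaussian (sd 1 unit) for continuous parameters and
integer-snapped (sd 2 days) for `t0`, reflected at the bounds; triangular
proposals violating the cardinal ordering are rejected. The initial
temperature is set from a 40-proposal warm-up so that roughly 80% of
early uphill moves are accepted. Restarts are seeded as
`default_rng([seed, start_index])`, so a run is fully reproducible from
one root seed. The best restart is reported (ties broken by smaller
`Tb`-like threshold, then earlier `t0`); restarts whose loss lies within
5% of the best define the per-parameter (max; min) ranges, a reproducible
operationalisation of multi-start parameter uncertainty. Default bounds:
`t0 ∈ [−122, 150]` (intersected with actual data coverage, hence −121 in
practice), `Tb ∈ [0, 30]` °C, cardinals `Tmin ∈ [0, 15]`,
`Topt ∈ [5, 30]`, `Tmax ∈ [15, 50]` °C, `d ∈ [−40, −0.01]`,
`e ∈ [5, 25]` °C.

Inside the annealer the dataset is stacked onto its common day window and
evaluated with matrix operations; the arithmetic (slice, then cumulative
sum) is ordered identically to the public per-series path, so the final
reported metrics, external validation and the fast search agree
bit-for-bit. This is load-bearing: the validation matrix's diagonal must
reproduce the estimation metrics exactly.

## The multistep workflow

1. **Start-window comparison** — fit with `t0` allowed from Sep 1 of the
   previous year vs from Jan 1 of the event year; keep the window with
   the higher EFF, ties to Jan 1 as the simpler frame. The workflow runs
   this once per phenophase on the pooled dataset; per-variety window
   comparisons add cost without changing the decision on data of this
   design.
2. **Per-variety calibration** — each variety fitted independently for
   each requested model family; varieties with fewer than two years are
   skipped with a warning. The same root seed is used per variety so
   identical datasets give identical fits.
3. **Family selection** — best EFF wins, but any family within 0.01 EFF
   of the best yields to the simpler one (GDD < UniFORC < triangular by
   parameter count).
4. **External validation** — each variety's fitted model, parameters
   frozen, is scored on every other variety's data, giving a
   donor × recipient EFF/RMSE grid whose diagonal is the estimation fit.
   The donor with the highest mean off-diagonal EFF is the best
   transferring model.
5. **Global model** — one parameter set fitted on the pooled
   all-variety dataset (48 observations per phenophase in the default
   design).

## Synthetic data

The generator emulates a 12-season, 4-variety observation campaign at a
single temperate Atlantic site. Daily mean temperature is a seasonal
sinusoid (annual mean 13.3 °C, amplitude 7.5 °C, warmest day mid-July)
plus AR(1) residuals (lag-1 correlation 0.75, marginal sd 3.0 °C) and a
per-season mean shift (sd 1.0 °C); minima/maxima are the mean ∓ a 5 °C
diurnal half-range. Autocorrelated residuals are not cosmetic: multi-day
cold and warm spells around the threshold are what make a base
temperature identifiable from event dates, and with white-noise springs
the `t0`/`Tb` ridge is nearly flat and fitted `Tb` drifts low. Setting
`ar1=0` restores a white-noise process for experiments.

Each variety carries a generating ("truth") model per phenophase; the
defaults are GDD truths seeded from published per-variety estimates
(e.g. budburst `t0=49, Tb=5` and flowering `t0=52, Tb=6` for the
earliest varieties) so the synthetic study reads like a real one, with
budburst near DOY 90–100 and flowering near DOY 145–160. Observation
error is applied to the **date**, not the temperatures — rounded Gaussian
noise (default sd 2 days) optionally snapped forward to the next
scheduled field visit (default every 7 days for budburst, 4 for
flowering, emulating discrete scouting; 0 records exact days). Truth
models that never trigger raise an error naming the variety-year.

What passing tests on these data do **not** show: real vineyards add
dormancy/chilling dynamics, observer variability beyond a visit grid,
microclimate differences between plots, and weather features (fronts,
heat waves, autocorrelation structure beyond AR(1)) that a sinusoid
cannot produce. Results on synthetic data certify the machinery —
recovery, validation logic, metric arithmetic — not field performance.

## Problem sizes

Default test and acceptance runs use 12 seasons × 4 varieties (48
observations per phenophase), annealing at reduced depth (3–6 restarts,
60–120 proposals per level, 20–25 levels) chosen as the smallest sizes at
which the structural checks are stable; the library defaults (10
restarts, 200 × 30) remain the recommended analysis settings.

## Known limitations

* Single-phase forcing only: no chilling/dormancy submodel, no
  photoperiod, no hourly disaggregation.
* `F*` is identified only up to the zero-loss interval at day resolution;
  reported heat sums inherit that granularity.
* The `t0`/`Tb`/`F*` ridge is intrinsically flat on smooth climates;
  multi-start ranges should be read as the honest uncertainty statement.
* The 95% interval on the origin-regression slope is the zero-intercept
  model's slope CI (`n − 1` degrees of freedom); it is reported for bias
  assessment, not used for model selection.
* Annealing is stochastic; all results are reproducible only under the
  documented seed discipline.
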