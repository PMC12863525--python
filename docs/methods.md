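# Methods

This note documents the models and procedures `reeftherm` implements, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Nighttime pairing and aggregation

Satellite SST is a single nighttime value per region per day, so logger
records are filtered to the local-time window **[22:00, 02:00)** before any
comparison. The window is half-open to avoid double counting at its
boundaries, and a night is labelled by the *evening's* date (22:00 of day
*d* through 01:59 of day *d*+1 → night *d*), pairing each night with the
same night's satellite read. Nightly maxima and minima are computed within
the night window only — they describe the night the satellite sampled, not
the full day. Records earlier than one day after deployment are discarded
(loggers are launched on land; the kept interval is closed on the left, so
a record at exactly deployment + 24 h survives). Temperatures outside
[15, 40] °C are flagged and excluded from aggregates; this is a coarse
plausibility screen for tropical reef water, not a drift correction (logger
drift, < 0.1 °C/yr for the hardware emulated here, is ignored).

Regional values are **unweighted means across loggers**, and the "all"
scope is the **mean of region means** rather than the mean over all
loggers; otherwise a logger-rich region would dominate the archipelago
average. Calendar-month means are flagged when fewer than 50% of nights
are present. Paired panels carry a `block_id` that increments at every
gap in the shared date sequence; downstream stages (smoothing,
walk-forward) never bridge blocks. All timestamps are naive local time
(the emulated deployment is Palau, UTC+9, no DST); no timezone logic
exists anywhere.

## Heat-stress metrics

- **MMM** — the warmest calendar-month mean within the trailing 12-month
  window ending at the evaluation month (default: last covered month), as
  a single per-series constant. Months failing the coverage rule are
  excluded; at least 12 covered months are required. A
  `variant="climatology"` switch instead takes the warmest entry of the
  multi-year monthly climatology (the operational Coral Reef Watch form).
- **Bleaching threshold** — MMM + 1 °C, by definition.
- **DHW** — HotSpot(d) = max(T(d) − MMM, 0); the daily contribution is
  HotSpot/7 when HotSpot ≥ 1 °C and 0 otherwise (the CRW convention:
  accumulation counts only once temperature is within reach of the
  threshold, and division by 7 yields °C-weeks); DHW(d) sums contributions
  over the trailing 84 days. A `variant="excess"` switch accrues
  max(T − threshold, 0)/7 instead, since field wordings of "degrees over
  the threshold" are genuinely ambiguous between the two; neither variant
  is claimed to reproduce any specific published series. The window sum is
  computed as an explicit per-date trailing-window sum (strided view), so
  it is bit-identical to a brute-force recomputation.
- **Coverage rule** — a date's DHW is flagged undefined when fewer than
  80% of its trailing-window days (window clipped at the series start)
  have data; without this, field-season gaps silently deflate apparent
  heat accumulation.
- When comparing heat accumulation between origins, the in situ MMM is
  anchored to the satellite's: MMM_insitu = MMM_SSST + mean monthly
  (in situ − SSST) offset. This keeps DHW differences about *accumulation
  dynamics* rather than the constant baseline bias.

## Comparison regressions and HAC inference

Each metric and scope is fit by OLS with in situ as the response, and the
interesting nulls are slope = 1 and intercept = 0 (the satellite tracks
in situ changes one-for-one, with no constant bias). The diurnal-range
regression instead tests slope = 0: there is no 1:1 expectation between a
range and a nightly mean. Nightly residuals are strongly serially
correlated, so coefficient covariances use Bartlett-kernel sandwich
estimators with weights w_l = 1 − l/(L+1):

- **Newey-West** for single-region fits (moments summed along one series);
- **Driscoll-Kraay** for the pooled all-region fit: per-date moment
  contributions are first summed across regions, then the kernel is
  applied over dates — robust to arbitrary cross-sectional correlation.

The truncation lag defaults to the plug-in rule L = ⌊4(T/100)^{2/9}⌋ (T =
number of dates) and is overridable. Degrees of freedom are T − 2 (dates,
not stacked rows, for the panel estimator). Driscoll-Kraay covariances can
lose positive semi-definiteness in small samples; negative eigenvalues are
floored at zero with a warning. An exact fit (residual RMSE at machine
precision) makes the t ratio 0/0; it is reported as t = 0, p = 1 when the
coefficient sits on its null and as an infinite statistic otherwise.
Bonferroni correction multiplies p-values by the family size — the four
scopes (all, Northern, Western, Southern) of one metric; single-scope
families (the DHW comparison) require an explicit override. The
alternative "Beck & Katz" (panel-corrected) covariance sometimes named for
full-scope fits in this setting is *not* implemented; the package commits
to Driscoll-Kraay.

**Known limitation — plug-in lag under strong persistence.** The slope
test's size depends on the persistence of the moment process x·e, i.e. on
the *product* of predictor and error ACFs. With AR(1) errors at φ = 0.7
the test holds close to its nominal 5% level (~0.065–0.07 at n = 500)
when the predictor's own persistence is moderate (φ ≈ 0.35–0.5), but if
the predictor is as persistent as the errors the Bartlett kernel at the
plug-in lag (L = 5 at n = 500) captures only ~80% of the long-run
variance and the empirical size rises to ~0.09–0.10 for both estimators.
The calibration study shipped with the package therefore uses predictor
persistence 0.35; users regressing two highly persistent series should
pass a larger lag explicitly.

## Walk-forward validation

An expanding training window ends at each forecast origin; the calibration
regression fit on all rows dated ≤ origin predicts the half-open horizon
(origin, origin + 30 days], restricted to the origin's contiguous block so
forecasts never jump a field-season gap. Origins advance by exactly 30
calendar days from the first origin (default 2019-04-01 for the emulated
deployment); an origin falling in a gap yields a skipped window, not a
shifted one — the simplest deterministic reading of a fixed 30-day step.
Windows are scored by MAE and averaged; the baseline predicts every target
with the training-period mean of the response (for monthly panels, the
mean of monthly means). The horizon and step are configurable but only
the 30/30 default is benchmarked.

## Latent-state models

Six standardized nightly-mean series y (2 origins × 3 regions) are modelled
as y_t = Z x_t + ε_t, ε_t ~ N(0, R) diagonal, with latent random walks
x_t = x_{t−1} + w_t, w_t ~ N(0, Q). Two groupings compete: **region** (3
states; both origins of a region observe its state) and **origin** (2
states; all regions of an origin observe its state). "Variance at the
group level and shared among group states" is parameterized as a
compound-symmetric innovation covariance **Q = σ²_shared·J +
diag(σ²_specific)** — the most direct expression of a component common to
all states plus state-specific components. Each series has its own
loading; the first series per state is pinned at 1 for identifiability.
Free parameters: (6 − m) loadings + 1 shared + m specific + 6 observation
variances (13 for either grouping).

Likelihoods are exact Gaussian log-likelihoods from the Kalman filter
(statsmodels' state-space machinery; missing observations skipped
entry-wise), with the diffuse prior approximated by x_1 ~ N(0, 10⁷·I).
Maximization is quasi-Newton (L-BFGS) on log-variances and unconstrained
loadings, from a moment-based start (loadings 1; variances split from the
mean first-difference variance) plus seeded Gaussian perturbations
(default 5 starts; the best kept). Models are compared by **AIC = −2ℓ +
2k** on identical data (enforced by a data fingerprint).

**Variance partition.** Random walks are nonstationary, so each series'
variability is decomposed on the innovation (first-difference) scale:
loading² × σ²_specific (shared with the series' group), loading² ×
σ²_shared (crossing groups, "inter-origin" in the origin model), and the
observation variance, normalized to proportions. No published formula
exists for this decomposition in the setting emulated here; this
definition is documented and validated against simulated ground truth
only. Two caveats: (1) treating the observation variance (white) and
innovation variances (accumulating) on a common per-step scale is a
modelling convention, and (2) per-series z-scoring rescales each state by
its anchor series' realized SD, which redefines the shared/specific split
when series scales differ — recovery of generator ground truth is
therefore evaluated on unstandardized panels, while real-data pipelines
standardize for cross-series comparability, as is conventional.

## Synthetic data

`simulate_dataset` emulates the study design: per region, a seasonal
sinusoid (default base 28.8 °C, amplitude 1.2 °C, peak at day-of-year 196)
plus a latent random-walk trend (shared σ 0.02 + region-specific σ 0.01
°C/day) plus daily AR(1) noise (φ 0.7, σ 0.2 °C); loggers add a diurnal
sinusoid peaking at 15:00 (amplitude 0.5 °C at logger depth), a constant
per-logger offset (σ 0.1 °C, the within-region spread, a free parameter —
no study value is claimed), and white 10-minute jitter (σ 0.02 °C). The
satellite series shares the seasonal cycle and regional trend, carries its
own AR(1) noise, and is offset by the origin bias (default −0.58 °C, the
satellite's cool-skin nighttime bias). Default region offsets make the
Western region warmest and the Northern coolest. Gap intervals (field
seasons) drop logger records entirely.

Daily-resolution components are piecewise-constant over a "process day"
running 02:00–01:59 local, so the whole night window sees one daily value
(zero-order hold; this keeps the nightly aggregate's autocorrelation
exactly the injected AR(1)), and the satellite value includes the diurnal
sinusoid's night-window mean, so that in the noise-free limit the nightly
in situ mean minus SSST equals the negative origin bias *exactly* — the
anchor for the pipeline's exact end-to-end checks (slope 1, intercept
0.58, zero walk-forward MAE).

What the generator does **not** emulate: spatial SST fields (one series
per region; the emulated product averages a bounding box), tides or
weather-band variability beyond AR(1), depth stratification, logger clock
drift, or sensor failure modes other than whole-interval gaps. Passing
tests demonstrate the *statistical machinery* is correct under known
ground truth; they do not certify any particular real-world satellite
product's bias.

`simulate_latent_panel` draws directly from the grouped random-walk
observation model (both the standardized panel the pipeline consumes and
the raw panel recovery studies need); `simulate_paired_series` /
`simulate_paired_panel` generate daily paired series with a known affine
relation and AR(1) or white errors for calibration, bias-recovery, and
walk-forward studies.

## Problem sizes used in the shipped studies

Monte-Carlo studies are sized to be decisive yet quick: HAC calibration at
n = 500 with 3000 replicates (Monte-Carlo SE ≈ 0.005 on a rejection
rate); bias recovery over 200 replicates of one-year series; AIC model
selection and variance-partition recovery over 50 seeds at T = 1000 with
the moment-based optimizer start (the AIC separations between groupings
are three to four orders of magnitude larger than any start-dependence);
end-to-end pipeline runs on two-year, six-to-nine-logger datasets. The
10-minute record volume of such a dataset (~0.6–1 M rows) ingests in
seconds.
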