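# Methods

This note records the models, numerical choices and design decisions
behind `droughtring`, and what its synthetic-data tests do and do not
demonstrate about real tree-ring data.

## Screening and collection statistics

The intercorrelation of a series is its Pearson correlation with the
leave-one-out master chronology over their common years, computed
after high-pass filtering every series by first differences of log
ring width. Raw ring series correlate strongly through the shared
age trend alone; the filter removes that trend so the 0.328 default
threshold measures shared year-to-year signal, as in COFECHA-style
quality control. Screening is one-pass: the master is built from all
other series, rejected series are not removed iteratively. Series
whose overlap with the master is under 10 years are rejected
explicitly as not-assessable. `rbar` is the mean of all pairwise
Pearson correlations over pairwise common years, on unfiltered values.

Missing rings (gaps) are rejected at ingestion rather than supported;
locally absent rings in real collections must be resolved upstream.

## Spline detrending

The age-trend estimate is a discrete penalized least-squares smoother
(second-difference penalty), the discrete analogue of the classical
smoothing spline used for flexible ring-width standardization. Its
design target is an amplitude frequency response of 0.50 at a
wavelength of 0.67 × series length. For an infinitely long series
the penalty weight with that response is λ = (1−f)/(16 f sin⁴(π/p));
at p = 0.67 n, however, the wavelength is of the same order as the
series, and the smoother's natural boundaries pass substantially more
low-frequency amplitude than the interior formula predicts (measured
realized response ≈ 0.55 with the analytic λ). The stiffness is
therefore *calibrated*: for each (n, wavelength, response) the package
root-finds the λ whose realized response — the least-squares sinusoid
amplitude of the smoothed sinusoid over the central half of the
series, averaged over input phase — equals the target. Calibrated
stiffnesses are cached. The realized response at the series ends
remains higher than in the centre; this is a property of every
natural-boundary smoother.

RWI is the ratio rw / fit (dimensionless, mean ≈ 1); a non-positive
fitted value aborts with the offending year. Chronologies are per-year
Tukey biweight robust means (c = 9 × MAD, one weighting pass from the
median, as in standard dendro practice); the arithmetic mean is an
option. Years covered by no series are omitted, never imputed.

## PET, SPEI and drought classes

PET follows Thornthwaite: annual heat index I = Σ(t/5)^1.514 over
months with t > 0; exponent a = 6.75e−7 I³ − 7.71e−5 I² + 1.792e−2 I
+ 0.49239; unadjusted PET = 0 for t ≤ 0, 16(10t/I)^a for
0 < t < 26.5 °C, and the Willmott polynomial −415.85 + 32.24t −
0.43t² above. The day-length correction uses the solar-declination
approximation δ = 0.4093 sin(2πJ/365.25 − 1.405) at mid-month
day-of-year J, with calendar month lengths (28 for February).

SPEI-k standardizes the rolling k-month sum of D = P − PET per
calendar month. The distribution is the 3-parameter log-logistic in
Hosking's generalized-logistic L-moment parameterization (location ξ,
scale α, shape κ), fitted by unbiased probability-weighted moments;
the GLO form covers both signs of L-skewness, which matters because
the k-month balances of individual calendar months routinely have
slightly negative sample L-skewness. The fitted non-exceedance
probability maps to a z-score through the Abramowitz–Stegun 26.2.23
rational approximation (max error < 4.5e−4 against the exact normal
quantile). The calibration period is the full record (configurable);
records under 20 years are refused. Values beyond a bounded support
edge are clipped into (1e−9, 1−1e−9) before the quantile map.

Drought classes use continuous half-open bands — moderate (−1.5, −1],
severe (−2, −1.5], extreme ≤ −2 — so the bands partition (−∞, −1]
and boundary values like −1.5 and −2.0 fall into the more severe
class deterministically. A drought *year* is any calendar year
containing at least one month of the class in question.

Caveat: the per-calendar-month mean ≈ 0 / sd ≈ 1 property of SPEI
holds for homogeneous records. A record carrying a gross imposed (or
real) multi-month drought can show a transformed sd above 1.1 in the
affected calendar months, because the outlier is genuinely far in the
fitted tail; the construction tests therefore run on drought-free
synthetic climate.

## Pointer years

Relative growth change RGC(t) = 100 (rw_t − rw_{t−1})/rw_{t−1} per
tree; a tree is influenced in year t when |RGC(t)| ≥ 10% (the common
default; the threshold is a parameter, since a supermajority criterion
alone cannot define "influenced"). A year with ≥ 60% of covering
trees influenced in the same direction is a pointer year of that
sign; years covered by fewer than 5 trees are skipped with a log
notice. RGC is computed on raw ring width, not RWI.

## Resilience indices

Lloret indices per tree × event with window w = 3 years: preDr and
postDr are means of the w years before/after the event; Res = Dr/preDr,
Rec = postDr/Dr, Rsl = postDr/preDr, relRsl = (postDr − Dr)/preDr.
They are computed on raw ring width (an RWI-based variant is a
sensitivity option via detrended input). Two identities are exact by
construction and verified to 1e−12: relRsl = Rsl − Res and
Rec = Rsl/Res. When two event years lie closer than 2w + 1 years
(e.g. 2000 and 2003 at w = 3), each record is flagged
`contaminated` — the windows overlap the other event — but the values
are reported as-is, never corrected. Group summaries are tree-weighted
means (not means of block means); provenance-weighted summaries can be
had by aggregating twice.

## Provenance-variation model

For a trait X of tree m (provenance j, block k, year l):

X_jklm = μ + P_j + B_k + Y_l + (P×Y)_jl + e_jklm

with P and P×Y random, B and Y fixed. Year is treated as fixed
because year mean squares are a standard fixed-effect output of this
analysis; the interaction remains random. Fits are REML via
statsmodels MixedLM (grouping = provenance; random intercept plus a
per-year variance component within provenance). The Powell optimizer
is used first — on near-boundary fits the gradient-based optimizers
intermittently converge to poor local optima (observed llf deficits
of > 100) while Powell matched lme4's REML optimum on every check —
with an L-BFGS fallback.

Each random effect is tested by 2·(llf_full − llf_reduced) with the
same fixed effects, which makes the REML LRT valid. The reference
distribution is, by default, the Self & Liang 50:50 mixture of a
point mass at zero and χ²(1), the standard correction for a variance
component on its boundary: p = 0.5 P(χ²₁ ≥ LRT) for LRT > 0. The
uncorrected χ²(1) reference (as in lmerTest's `ranova`) is available
with `boundary_mixture=False`; it is roughly twice as conservative —
measured null rejection ≈ 0.0125 at α = 0.05 under a 20-provenance ×
3-block × 15-year design versus ≈ 0.027 with the mixture — and was
not adopted as the default because a test whose true size sits at the
edge of its nominal calibration band cannot be verified by any
feasible simulation. Zero-variance (singular) fits are flagged; the
LRT remains defined. Fixed-effect mean squares and their p-values
come from the type-II ANOVA of the fixed part.

Correlation tables are plain Pearson r with two-sided t-test p-values
and the three-tier star convention (5%/1%/0.1%); coordinates enter
untransformed, and no multiple-testing correction is applied. The
pipeline computes them at the provenance-mean level (n = number of
provenances); tree-level tables are available by passing tree-level
frames.

## Moving-window climate–growth functions

Windows of 25 years slide in 1-year steps (span − length + 1 windows;
1981–2020 gives 16). Predictors are monthly mean temperature and
precipitation, March–September of the current year (14 predictors),
with no previous-year lags. The correlation function is Pearson r per
predictor. The response function is a principal-components
regression: predictors standardized within the window, components
with eigenvalue > 1 retained (cumulative-variance retention is an
option), the standardized chronology regressed on the scores, and
coefficients rotated back to the predictor basis — collinearity is
the method's point, never an error; zero retained components is.
Significance for both: resample years i.i.d. with replacement within
the window (1000 draws by default), flag coefficients whose 95%
percentile interval excludes zero. One seeded generator drives every
window, so whole analyses are bit-reproducible. At window length 25
the percentile interval under-covers slightly; the measured
false-positive rate on climate-independent chronologies is ≈ 8%
rather than 5%, which is inherited from the bootstrap, not from the
implementation.

Strict invariance of fitted values under predictor duplication holds
only when all components are retained; under eigenvalue > 1 retention
duplication perturbs the component basis, and the fitted chronology
stays close (r > 0.9 in the packaged check) rather than identical.

## Synthetic trial generator

The generator emulates the study system: three-block randomised
complete block design, 81 provenances, four cored trees per plot,
1972–2020 (49 years), montane Carpathian climate normals
(MAT ≈ 5.5 °C, AP ≈ 690 mm), a +0.4 °C/decade temperature trend, and
two imposed droughts — 2000 (June–December, 60% precipitation
deficit, 40% growth reduction) and 2003 (May–August, 60% deficit, 30%
reduction), with the 2000 event's extent matching the published
drought calendar so that 2000 is the driest simulated year. Monthly
temperature is normal + trend + N(0, 0.7 °C); precipitation is gamma
(shape 9) around the normals, scaled down in deficit months.

Ring width is multiplicative on the log scale:

log RW = log(a e^{−b·age} + c) + P_j + B_k + β z_t + log(1 − d_t s_j) + ε

with age curve a = 2.5 mm, b = 0.05/yr, c = 1.6 mm (mature rings
≈ 1.8–2.8 mm); provenance effects P_j ~ N(0, 0.10), block effects
B_k ~ N(0, 0.05), a shared summer (Jun–Aug) water-balance z-score
signal with β = 0.15, drought-year reductions d_t scaled by a
per-provenance sensitivity s_j ~ N(1, 0.2) clipped at 0, and ring
noise ε ~ N(0, 0.10). The multiplicative form gives the resilience
indices closed-form expectations (a lone 40% reduction ⇒ E[Res] ≈
0.6), which the tests exploit with β = 0 to isolate the direct
channel. Earlywood/latewood split by a latewood fraction
0.28 + 0.04 × late-season dryness + N(0, 0.02), clipped to
[0.05, 0.60], so EW + LW = RW exactly. Provenance origin coordinates
are drawn uniformly (lat 46–62°, lon 5–28°, 300–1500 m) and carried
in the ground truth; by default they are independent of the growth
effects, so geography–trait correlations are null rather than
structured.

What the generator does not emulate: crossdating error and missing
rings, autocorrelated ring noise, spatial autocorrelation among
blocks, age-dependent climate sensitivity, and any dependence of
provenance effects on origin climate. Passing tests demonstrate the
pipeline's correctness and calibration under known ground truth, not
the field validity of the published estimates.

A known boundary behaviour: with both events imposed, the weaker 2003
event is the second-lowest balance in its calendar months of a
49-year record (empirical tail probability ≈ 0.03), so its SPEI-3
minimum fluctuates around the extreme threshold −2 and lands in the
severe class in roughly 10% of seeds. The end-to-end recovery check
runs at that measured 90% rate; the analogous interference between
close events is exactly why resilience records carry contamination
flags.

## Problem sizes in the packaged studies

The simulation studies run at reduced, fixed sizes chosen to keep the
whole suite in the minutes range while leaving comfortable statistical
margins: LRT power and type-I at 20 provenances × 3 blocks × 15 years
(200 and 400 replicates), pointer-year detection over 100 seeds of a
7-provenance × 3-block design, moving-window calibration over 200
null chronologies with 200 bootstrap draws, and SPEI oracle agreement
over the 12 calendar months of one 49-year climate.

## Known limitations

- No crossdating, gap filling, or Heidelberg/FH format support.
- Thornthwaite PET only (temperature-driven); no Penman–Monteith or
  Hargreaves options, so PET is biased in strongly advective climates.
- The drought calendar classifies on SPEI alone; no soil or snow
  memory beyond the k-month aggregation.
- The mixed model assumes independent homoscedastic residuals; no
  temporal autocorrelation within trees, which real increment series
  possess. LRTs on heavily unbalanced designs rely on REML
  asymptotics.
- Moving-window analyses use current-year months only; lagged
  (previous autumn) climate effects, which conifers often show, are
  out of scope.
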