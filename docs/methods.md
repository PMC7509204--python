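# Methods

`vagalflex` implements an analysis chain for a psychophysiological paradigm
in which cardiac vagal activity and cognitive inhibition are measured
across a resting baseline and four Stroop-with-auditory-distractor
conditions crossing emotional and social distractor content (LELS, HELS,
LEHS, HEHS).  This note records the models, the numerical choices, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## HRV metrics

**RMSSD.** The time-domain vagal index is the root mean square of
successive interbeat-interval differences, `sqrt(mean(diff(IBI)^2))` (ms).
It is exactly invariant to adding a constant to all intervals and
equivariant under scaling; both laws are property-tested.

**Artifact correction.** An interval is an artifact when it deviates from
an 11-beat centered running median by more than a threshold (default
250 ms, a deliberately strong correction level; configurable).  Flagged
beats are replaced by a cubic spline through the surrounding clean beats
on the beat-index axis.  A segment with at least half of its beats flagged
is refused as unusable rather than silently repaired.  The output length
equals the input length: merged/split-beat resolution (which can change
beat count) is out of scope.

**AR spectrum.** The tachogram is cubic-spline interpolated to an even
4 Hz grid, linearly detrended, and fitted with an autoregressive model of
order 16 by Burg recursion (`statsmodels`' implementation of the standard
algorithm).  The one-sided parametric density `2*sigma^2*dt / |A(f)|^2` is
evaluated on a grid no coarser than 0.001 Hz up to Nyquist.  HF power is
the trapezoidal band integral over 0.15-0.4 Hz; the HF peak (argmax in
band) serves as the respiration-rate proxy.  Resampling rate, order and
grid step follow common HRV-software convention; none is sensitive within
reasonable ranges for the signals involved (the AR peak agrees with a
nonparametric periodogram argmax within one grid step on test fixtures,
and total parametric power matches the resampled signal variance within
15%).  Detrending is linear only; smoothness-priors detrending is not
implemented.

**Log-transform gate.** Positively skewed per-subject metrics are
natural-log transformed when a Shapiro-Wilk test rejects normality at
alpha = 0.05 *and* the sample skewness is positive.  In the analysis
chain, resting RMSSD and Reactivity_SD pass through this gate (matching
the convention of the paradigm); profile columns carry both raw and ln
values.  Reactivity_SD values below 0.01 ms are floored before the log,
with a warning — a zero-spread subject would otherwise produce -inf.

## Derived scores and intraindividual variability

Per condition: Stroop RT interference = mean incongruent RT - mean
congruent RT (censored >5 s responses excluded; incorrect trials retained
by default, `correct_only` optional); accuracy interference = proportion
correct incongruent - congruent; vagal reactivity = task RMSSD - the
immediately preceding baseline RMSSD (positive = increase during task;
the same contract applies to HF-peak reactivity).  Per subject, the IIV
profile is the mean and the sample SD (denominator n-1, configurable to
n) of the four condition scores: Reactivity_SD is "vagal flexibility",
Interference_SD is (inverse) "performance stability".

Outlier screening is a single pass: means and SDs are computed once on
the full sample, and subjects strictly beyond 3 SD on any screened
variable (default: Interference_SD and lnReactivity_SD) are removed with
a logged z-score.  A value at exactly 3.0 SD is retained.  The
vagal-flexibility tertile split is rank-based with cutpoints at the
rounded n/3 and 2n/3 ranks and stable tie-breaking, so 47 subjects split
16/15/16.

## Inference

**Correlations.** Pearson r with a t-based two-tailed p (df n-2) and a
Fisher-z interval `tanh(atanh(r) +/- z_crit/sqrt(n-3))`.  Partial
correlations residualize both variables on the covariates by OLS; df and
the Fisher interval lose one unit per covariate (n-2-k, n-3-k).  The
standard confound set is sex, age, BMI, and the HF-peak analog of the HRV
metric involved (resting HF-peak for resting RMSSD, the SD of HF-peak
reactivity for flexibility, its mean for mean reactivity).

**Mediation.** `MediationModel.fit()` estimates the product-of-
coefficients system with three OLS models sharing the covariate set
{age, BMI, sex, resting HF-peak}: y~x (total effect c), m~x (a), and
y~x+m (c' and b).  Coefficients are unstandardized by default; a
`standardize` flag z-scores all variables for simulation recovery work.
The indirect effect a*b is tested by the Monte Carlo method: a* and b*
are drawn independently (they come from different fitted models, so no
covariance term is available or used) from normals centered at the
estimates with the estimated SEs; the percentile interval of a*b* at the
requested level is the CI and p = 2*min(P(<=0), P(>=0)) with 10,000 draws
by default, reproducible from a seed.  Classification: *full* mediation
when c and the indirect effect are significant but c' is not; *partial*
when all three are; *none* otherwise.

**Mixed ANOVA.** `MixedAnovaModel` aggregates a long table to subject x
cell means (all within factors are 2-level) and decomposes stratum by
stratum: the between stratum tests the group term against
subjects-within-groups; each within effect is a per-subject contrast
score tested, together with its group interaction, against its own
effect-by-subjects error.  The flexibility group enters either as a
single-df linear trend over ordered tertiles (default — this is the
coding consistent with published single-df group terms and error df
n-2) or as a categorical factor (sum coding, Type-III-style SS via RSS
differences, which handles mildly unbalanced groups).  Generalized eta
squared divides an effect's SS by itself plus *every* error SS in the
model, the appropriate effect size for mixed designs.  Simple effects:
paired t contrasts on cell means within a slice, and simple two-way
interaction F ratios within one group using the omnibus model's pooled
error stratum (so df_den matches the full model's error df).

**Power.** The a-priori power analysis for the indirect effect simulates
standardized trivariate data (M = a*X + e, Y = b*M + c'*X + e, residuals
standardizing M and Y), fits both path regressions in closed form across
all replicates at once, and applies either the Monte Carlo CI test
(default, matching the analysis-time inferential test) or joint
significance.  `required_n` bisects the (monotone up to MC error) power
curve.  With a = b = 0.4, alpha = 0.05 and 10,000 replicates, the
simulated Monte-Carlo-CI test reaches 0.8 power near **N = 65** and joint
significance near N = 64.  The widely used analytic shortcut — the
product of the two path powers with z = path*sqrt(n) and no df
corrections — reaches 0.8 at N = 59-60; it is optimistic because it
ignores estimation noise in the SEs and df corrections.  The package
implements the simulation (the analytic shortcut appears only as a sanity
cross-check in the tests), so its answer to "N for 0.8 power" is ~65,
not 59.

## The synthetic cohort

The generator emulates the full session so the pipeline can be validated
against ground truth.  Its defaults are a stated world, chosen once:

* **Latent chain.** T ~ N(0,1) (resting vagal trait); flexibility
  F = a*T + e_m; a performance-variability axis S = b*F + c'*T + e_y
  (negative S = more stable).  Defaults a = 0.65, b = -0.40, c' = 0 with
  residual SDs standardizing F and S.  With b negative, higher
  flexibility yields a tighter interference spread, the direction the
  paradigm reports.
* **IBI segments.** IBI_k = mean + shift + A(tone)*sin(2*pi*f*t_k) +
  AR(1) noise; A(tone) = 90*tone/(1+tone) ms saturating, noise SD
  14*tone ms (capped at 70 ms), phi = 0.4, mean IBI 850 ms, respiratory
  frequency per subject ~ N(0.232, 0.04) Hz (task segments +0.03 Hz).
  Resting tone is exp(0.9*T): because the noise term is linear in the
  log-normal tone, resting RMSSD is positively skewed (~44 +/- 24 ms)
  and the Shapiro-Wilk gate fires, as in real cohorts of this kind.
  An analytic tone->RMSSD map (validated against simulation to ~5%) is
  inverted to hit per-condition task-RMSSD targets.
* **Reactivity.** Target task-baseline shifts are a fixed standardized
  four-condition pattern (shaped like the paradigm's published condition
  means) scaled by sigma_F = 12*exp(0.85*F) ms plus 20% idiosyncratic
  noise.  The fixed pattern keeps ln(Reactivity_SD) close to linear in F
  instead of drowning it in the chi-noise of an iid four-sample SD.
* **Interference.** Per-condition true interference = 120 ms + sigma_S *
  (fixed pattern + 20% noise) with sigma_S = 90*(1 + 0.55*S) ms floored
  at 10 ms (across-subject CV ~0.5, matching published descriptives);
  trials are ex-Gaussian (sigma 70, tau 150 ms), 32 per congruency cell,
  censored at the 5-s deadline (missing RT, scored incorrect).  Inside
  the cohort the high-emotion loading lives in the pattern scaled by
  sigma_S, so the latent chain is the *only* flexibility-to-interference
  pathway (clean path recovery); the standalone trial generator also
  offers an explicit emotion-distraction effect scaled down by
  flexibility.
* **Counterbalancing.** Condition orders are drawn uniformly from the
  permutations in which the two high-emotion conditions are never
  adjacent and the two high-social conditions are never adjacent (4 of
  24 orders survive; the paradigm's exact sequences are unpublished, so
  only the constraint is modeled).

What a green test establishes: that the estimators recover the latent
structure this generator encodes under realistic measurement noise
(segment-length RMSSD error, 32-trial cells, 4-condition SDs).  What it
does not: real ECG artifacts beyond simple outliers, respiration-HRV
coupling beyond a single sinusoid, RT autocorrelation or fatigue drifts,
or missing segments.  Measured Reactivity_SD (~19 ms mean) runs above
its latent base (12 ms) because segment-level RMSSD estimation noise
inflates a four-condition SD — the same inflation a real cohort's values
contain.

## Numerical choices and degenerate inputs

Quantile CIs use linear-interpolation quantiles.  Fisher intervals refuse
|r| = 1 and samples too small for the z variance.  The ANOVA clips tiny
negative SS from floating-point cancellation at zero.  Bisection in
`required_n` assumes monotone power; every evaluated (n, power) pair is
reported so a user can inspect the curve.  All randomness flows through
`numpy.random.Generator` seeds; cohort generation is byte-reproducible.

## Limitations

* The mixed ANOVA supports 2-level within factors (the paradigm's
  design); general k-level within factors would need a contrast basis per
  effect.
* No bootstrap mediation, no SEM/multilevel modeling, no
  moderated-mediation power.
* The package's answer to the a-priori power question differs from the
  published N = 59 for the reason documented above; users wanting the
  analytic approximation can compute it in two lines, but the simulation
  is the honest estimate for the tests implemented here.
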