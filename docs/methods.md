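# Methods

`gibbonsong` re-creates, end to end and on synthetic data, an analysis
chain for male gibbon solo songs: acoustic feature extraction, factor
analysis, a permuted discriminant function analysis of vocal
individuality, excretion-lag matching of fecal androgen levels, and
Gaussian linear mixed models linking acoustic factor scores to androgen
levels, social status and age, with a kernel-based temporal
autocorrelation covariate. This note records the models, the defaults
and why, the numerical choices, and the known limitations — in
particular what the synthetic data do and do not establish about real
recordings.

## Synthetic data (`songsim`)

The generator emulates a wild study population of white-handed gibbons:
~14 adult males across pair-living groups and a few unifemale/multimale
units, each recorded on a burst of 2–4 nearby days (field teams follow a
group for a stretch, so day lags span a few days), one solo song per
recording day, 8–18 calls per song, 3–50 frequency-modulated elements
per call. Elements are rendered as FM sine sweeps at 8 kHz: a monotone
half-cosine rise from the start F0 to the maximum at ~85% of the
element, easing to an end F0 just below the maximum (start ≈ 700 Hz <
end ≈ max ≈ 950 Hz at the population anchors), plus additive white
noise at a configurable SNR (default 30 dB, a clean directional-mic
recording at close range). Waveforms are quantized to 16-bit on
synthesis so that in-memory arrays equal their WAV round trip.

Injected, recoverable structure, all driven by one integer seed:

* **Androgen → pitch, between males** (`effect_androgen_pitch`, default
  0.5): a male's baseline F0 is `700 + 60·(β·z + √(1−β²)·ε)` Hz with `z`
  the standardized log of his mean fecal androgen level, so β is the
  standardized between-male slope and is recoverable by OLS on the truth
  table.
* **Age → call duration** (`effect_age_callduration`, default 0.8):
  senior males' element durations and inter-element intervals are scaled
  by this factor, shortening calls; subadults are scaled up (longer,
  per the descriptive contrasts expected of them).
* **Day-scale residual autocorrelation** (`ac_sigma_true`, default 2
  days): per male, call-level pitch residuals are a Gaussian-kernel
  smoothing of white noise over continuous call times, normalized to
  unit variance, scaled to 15 Hz.
* **Excretion lag**: the androgen level that drives a day's songs is, by
  construction, excreted in a fecal sample exactly 3 days later;
  deterministically ~95% of recording days receive such a sample, and
  extra samples on out-of-window days pad each male's series into the
  realistic 5–29 range. Day levels are log-normal around the male mean
  with expectation exactly equal to it.

Separate light-weight generators produce call-feature tables with
controllable between-male separation and day-level random effects (for
the discriminant analyses), tables with a planted orthogonal factor
structure (for the factor analysis), and observation tables with known
fixed effects, nested random effects and optional kernel-autocorrelated
residuals (for the mixed models). In the mixed-model generator,
`ac_share` sets the fraction of residual variance carried by the smooth
component; the remainder is white. A purely smooth residual would make
the nearest neighbour in time an almost perfect predictor, and the
bandwidth estimate would rightly collapse — real call measurements
always carry independent measurement noise.

What the generator does *not* emulate: gibbon timbre and harmonics,
duets and female great calls, amplitude modulation, reverberation and
transmission loss, overlapping singers, recorder handling noise. Tests
passing on these data show the *statistical machinery* is correct under
the stated model; they do not validate the acoustic front end against
field recordings.

## Acoustic features (`acoustics`)

Spectrograms use a Hamming window, FFT length 256 at 8 kHz (31.25 Hz
bins) and 50% overlap (16 ms hop); other rates are anti-alias resampled
(`scipy.signal.resample_poly`). A frame is *signal* when its
band-limited peak magnitude is within `threshold_db` (default −12.8 dB,
configurable per recording between −5 and −20 dB) of the recording's
peak; maximal runs of signal frames are elements, and per frame the F0
is the highest-magnitude bin inside the 100–2000 Hz search band (valid
for signals whose fundamental carries the most energy, as in gibbon
songs). Contours shorter than 2 frames are discarded as sub-resolution
artifacts. All WAV input/output and signal processing go through
`scipy.io.wavfile` and `scipy.signal`.

Elements separated by a silent gap (next onset minus previous offset)
of at most 5 s belong to one call; the default clears the largest
plausible within-call interval (~4.5 s) while inter-call silences are
≥ 6 s. Per element: start/end F0 (first/last frame), max F0 (first
attainment breaks location ties), mean F0, duration, and the location
of max F0 relative to duration. Per call, 22 parameters: call duration
plus mean, maximum and variation of the 7 element measures; *variation*
is the sample SD (coefficient of variation available). Single-element
calls have undefined intervals and variation: recorded as missing,
flagged, excluded listwise from the factor analysis with a logged count.

## Factor analysis (`factors`)

Per-parameter transforms (natural log, square root, or square root of
the min-shifted value) symmetrize the skewed parameters; shift minima
are estimated on the fitting data and frozen for reuse. The log base is
immaterial for an analysis of the correlation matrix. Adequacy is
screened by Bartlett's sphericity test (χ² = −((n−1)−(2p+5)/6)·ln det R
on p(p−1)/2 df) and the KMO statistic (pseudo-inverse fallback for a
singular correlation matrix, with a warning).

`CallFactorAnalysis.fit()` extracts principal components of the
correlation matrix, retains eigenvalues > 1, applies varimax rotation
with Kaiser normalization, orders rotated factors by explained variance
and fixes each column's sign so its largest loading is positive.
Regression-method scores use weights `R⁻¹Λ` on the standardized data, so
score means are zero on the fitting data. Factors are given semantic
labels (pitch, element duration, pitch variation, location of max F0,
call duration, start F0) by greedy assignment of dominant loading
blocks; unmatched factors keep their index names.

## Permuted DFA (`pdfa`)

Calls from the same day are not independent, so significance comes from
a restricted permutation: whole (male, day) blocks of calls are
reassigned among male labels, each male keeping its original number of
recording days; the observed arrangement counts as one permutation, so
the smallest p is 1/n_permutations and ties count conservatively
against the alternative. Males with fewer than `n_select`+1 calls are
excluded (logged); in permuted datasets, where per-male call counts
fluctuate, a male short of calls trains on all but one call.

Classification is linear discriminant analysis with equal priors
(matching the balanced design): pooled within-class covariance, ridge
regularized (logged ε = 1e−6·tr(S)/p) when its smallest eigenvalue
falls below 1e−10 of the largest; held-out calls go to the class with
the highest linear discriminant score, equivalent to the nearest
centroid in the whitened metric. The observed statistic averages the
cross-validated percent correct over `n_selections` (default 100)
balanced selections of 23 calls per male; permuted datasets use the
same statistic (`perm_selections` can lower their selection count for
speed — Monte-Carlo noise in the null statistic, not bias). The
all-calls DFA report solves the between/within generalized eigenproblem
and reports SSCP-scale eigenvalues and structure loadings (variable ×
discriminant-score correlations), flagging |loading| ≥ 0.5.

One master seed drives everything; child streams are derived with fixed
tags so stages are independently reproducible.

## Hormone matching (`hormones`)

A recording is matched to the fecal samples of its male collected
between the recording day and 7 days later, choosing those that
minimize |lag − 3| (day 3 is the assumed excretion delay) and averaging
exact ties (e.g. lags {2, 4}); the tie rule reads "closest to the
optimal day" as binding, not "anywhere in the window". Lags count
calendar days: samples are collected in daylight, songs around dawn, so
sub-day precision does not exist. Recordings with no in-window sample
are excluded, never imputed. Matched values are z-transformed over
observations and split into a between term (male mean of z) and a
within term (z minus male mean); the decomposition is exact by
construction.

## Mixed models (`glmm`)

For each factor score: fixed effects status (treatment coding,
pair-living primary reference), age (adult reference; subadults are
excluded), androgen between, androgen within, and the autocorrelation
term; random intercepts for group ⊃ male ⊃ date-within-male ⊃ song
(fully nested, fitted as variance components within the group factor)
and an uncorrelated-by-default random slope of androgen-within per male
(13-odd males carry little information about an intercept–slope
correlation; `slope_corr` enables it). Fitted with statsmodels MixedLM,
ML for all likelihood comparisons, REML for the reported variance
components.

**Autocorrelation term.** For observation *i* of male *m*:
`AC_i = Σ_j w_ij r_j / Σ_j w_ij`, `w_ij = exp(−(t_i−t_j)²/2σ²)`, summing
over the male's other observations, on continuous call-start times in
days; the term is z-scored before entering the model. Three numerical
choices matter, all adopted after the naive construction proved
degenerate:

1. *Residuals*: fixed-effect (marginal) residuals of the no-AC model.
   Conditional residuals would already have the day- and song-scale
   structure absorbed into BLUPs; residuals centred per male make the
   average of a male's other residuals a mechanical proxy for −(own
   residual).
2. *Same-date exclusion*: observations from the same recording date are
   excluded from each other's average. Same-day dependence is already
   modelled by the date and song intercepts, and a same-day
   leave-one-out average is an affine function of the own residual
   given the day total — with a free per-date intercept that makes the
   likelihood unbounded (residual variance → 0). The term therefore
   carries specifically the cross-day dependence.
3. *Sign constraint in the bandwidth search*: σ is chosen to maximize
   the ML likelihood of the refitted model over a log-spaced grid
   (default 25 points) between a quarter of the smallest between-day
   lag and the study span, refined by golden section to 1e−3 days — but
   only bandwidths where the term enters with a positive coefficient
   are admissible. At bandwidths wide relative to a male's day span the
   average of the other residuals degenerates toward a negated own-day
   mean, and the likelihood rewards that self-cancellation with a large
   negative coefficient although it models no temporal dependence. If
   no positive-coefficient bandwidth exists the unconstrained profile
   is used and the results object records `ac_constrained=False`.

Caveats, verified by simulation and documented in the tests: the
AC-term t-statistic at the selected bandwidth is *selection-inflated*
and is not an interpretable test statistic (the term is a nuisance
covariate); residuals are orthogonalized against male-level fixed
effects, so in small samples a mechanical negative own-residual
component of order (male-level parameters)/(observations per male)
remains; and when no true temporal structure exists but male variance
does, the search can drift to wide bandwidths where the term behaves as
a redundant male-level covariate — fixed-effect estimates are
unaffected because the residuals exclude the fixed effects. The
bandwidth is recovered within a factor of two (median over replicates)
when day lags actually span the true bandwidth; a design whose
recording days are months apart identifies only "within burst"
vs "across burst", not σ itself.

Fits retry on numerical failure by dropping boundary variance
components (slope, then song, then date, then male) and falling back
from L-BFGS to Powell; likelihood-only fits (σ profiling, LR tests)
never drop components on indefinite-information grounds, so their
log-likelihoods stay comparable, and a likelihood-ratio test whose two
fits ended at different structures is refitted at the common reduced
structure.

**P-values.** The default is a parametric bootstrap of the LR statistic
(simulate from the null fit's estimates — fixed effects plus fresh
draws of every random effect — refit both models per draw, count ties
conservatively; default 1,000 draws). Asymptotic LR and Wald p-values
are provided for simulation studies where the bootstrap is too slow.
Across the factor-score models, p-values are Simes step-up adjusted per
predictor (adj p_(i) = min_{j≥i} (m/j)·p_(j), capped at 1). Stability is
assessed by leave-one-male-out refits reporting the range of each fixed
effect; failures are recorded, not fatal.

## Pipeline

`run_full_analysis(RunConfig)` chains simulate → extract → factor
analysis → pDFA → hormone matching → mixed models → descriptives, with
one seed, per-stage row-count accounting (calls in = calls scored +
calls excluded, with reasons) and SHA-256 hashes of every artifact in a
manifest; identical configs reproduce identical bytes. Inclusion rules:
subadults are excluded from the pDFA and the factor-score models;
descriptive tables keep all age classes. Descriptives report median,
quartiles (linear-interpolation convention), range and counts for 8
parameters × 3 age classes.

## Problem sizes

Default analysis settings follow the study design (23 calls selected,
100 selections, 1,000 permutations, 25-point σ grid, 1,000 bootstrap
draws). The test suite and the verification script run the same code at
smaller problem sizes chosen as the smallest that still exercise every
property (fewer males/calls, reduced selections per permutation, coarser
σ grids, asymptotic p-values in power simulations); each such choice is
visible in the test parameters.

## Known limitations

* Peak-bin F0 tracking quantizes frequencies to 31.25 Hz bins and
  fails if a harmonic outweighs the fundamental (not the gibbon case).
* Amplitude thresholding against the recording peak assumes the peak is
  song, not a transient; a single loud click redefines the reference.
* The factor labels are heuristics over loading blocks; on data without
  the expected block structure they fall back to index names.
* The unbounded-likelihood and self-cancellation guards on the AC term
  are necessary consequences of building a covariate from residuals;
  alternatives (e.g. explicit Gaussian-process residual covariance)
  would model the same dependence without these artifacts but change
  the estimand.
* The parametric bootstrap assumes the null model's Gaussian random
  effects; gross misspecification of the variance structure propagates
  into its reference distribution.
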