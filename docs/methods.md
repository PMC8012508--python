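# Methods

This note documents the models, estimators and design choices behind the
`electrome` package: what each quantity means, which conventions were
adopted where several exist, and what the synthetic-data tests do and do
not demonstrate about real recordings.

## Signal model and data layout

A recording is one channel of extracellular voltage differences ΔV (µV)
between two electrodes in plant tissue, sampled at f_s (default 62.5 Hz;
a standard 2 h segment holds N = 450,000 samples).  Files are delimited
text with a YAML metadata sidecar (`fs` mandatory; plant id, treatment ∈
{bean, wheat, control, synthetic}, phase ∈ {before, after, none},
channel).  Each channel is treated as one independent recording.
Indexing is 0-based with half-open windows.

Windowing for feature extraction cuts a series into `n_windows` equal
windows whose consecutive pairs share `round(overlap_fraction · w)`
samples ("30 % lag" ⇒ step = 70 % of the window length).  The window
length is the largest w fitting that layout,
w = ⌊n / (k − (k−1)·overlap)⌋, decremented by at most a couple of
samples when step rounding would push the last window past the end;
remainder samples at the end of the series are dropped.

## Descriptive statistics

Skewness is m₃/m₂^1.5 and kurtosis m₄/m₂² on biased sample moments; the
**raw** (non-excess) kurtosis convention is the default because
heavy-tailed electrome data are usually reported on that scale (Gaussian
= 3), with `excess` available.  The reported SD uses the n−1
denominator.

The ACF uses the biased (1/n) normalisation — positive semidefinite and
equal to the direct sum — computed via FFT (statsmodels).  The **average
correlation time L** is not uniquely defined in the field; the package
default is the discrete integral of the ACF from lag 0 up to (excluding)
its first non-positive value, which gives exactly 1 for white noise and
≈ 1/(1−φ) for an AR(1) process.  A 1/e-crossing alternative is provided,
and both record when the ACF never reached the stopping condition within
`max_lag` (L is then a lower bound).  L is reported in samples and
seconds.

The slow-undulation detector is a heuristic: it fits a log-log power law
to the full-resolution periodogram and flags a recording when a bin
below 0.05 Hz exceeds the fitted continuum by more than 0.75 decades.
Undulation prevalences are reported as percentages truncated (not
rounded) to one decimal, the convention under which 20 of 23 recordings
print as 86.9 %.

## Spectral estimation

`psd` defaults to Welch's method (Hann window, 50 % overlap, segment
length min(2¹⁴, n/8 rounded to a power of two)) for variance reduction
on long records; a raw periodogram is available as a cross-check.  The
noise-colour exponent β (PSD ∝ 1/f^β) is the negative OLS slope of
log₁₀ PSD on log₁₀ f over 0.01–10 Hz, excluding 4.5–5.5 Hz where EPG
acquisitions carry a constant instrumentation tone; both band and
exclusions are configurable and echoed in the fit result, which carries
the signed slope as well to avoid sign ambiguity.  Colour labels use
±0.25 windows around β = 0/1/2/3 (white/pink/brown/black) with the
0.5–1.5 "reddened" range as a fallback.

Scalograms use the Morlet continuous wavelet on 64 log-spaced
pseudo-frequencies (default: from ~4 cycles per record to f_s/4).

## Complexity measures

ApEn follows Pincus: Φ^m(r) − Φ^{m+1}(r) with Chebyshev distances and
self-matches included; SampEn (Richman–Moorman) excludes self-matches
and returns −log(A/B).  Defaults m = 2, r = 0.2·SD — the
literature-standard choice, recorded in every output.  Units are nats.
Neighbour counting is exact O(N²) (numba-compiled with a chunked numpy
fallback); the test suite verifies equality with brute-force double
loops to 1e−12.  Because the cost is quadratic, series longer than
`max_n = 20,000` samples are reduced to a centred sub-window of that
length before entropy estimation (configurable; the choice trades a
small estimation variance for tractability on 450k-sample records).

Multiscale entropy coarse-grains by non-overlapping block means of
length s and evaluates the entropy at each s with r fixed from the
scale-1 SD (Costa convention; per-scale r available).  Under that
convention white noise shows a monotonically falling profile (the
coarse-grained SD shrinks as 1/√s relative to the fixed r) while brown
noise — nearly regular at scale 1 — shows a rising one; both shapes are
asserted in the tests.  Scales too short for the embedding
(< 10·2^m points) truncate the profile with a warning.

The PDF tail exponent μ (f(|ΔV|) ∝ |ΔV|^−μ) is fitted by OLS of
log₁₀ density on log₁₀ |ΔV| over log-spaced histogram bins (geometric
bin centres) above the 0.90 quantile of |ΔV|.  The series is centred by
a 1 %-trimmed mean — a single extreme spike can displace the plain mean
by many baseline SDs and corrupt every magnitude below it.  Bins with
fewer than 5 events are dropped: near-empty far-tail bins survive only
when their count fluctuates high, which systematically flattens the
slope.  Log-binned regression was chosen over MLE to match how such
exponents are conventionally read off distribution plots; a power-law
fit is declared trustworthy (`ok`) only when r² ≥ 0.9, at least 5 tail
bins remain, and the fitted tail spans ≥ a factor 3 in |ΔV| (steep
μ ≈ 4–5 tails span less than a decade, but a Gaussian tail spans well
under 3×, so light-tailed series fail the gate).

## Synthetic electromes

The generator composes three ingredients, all seed-deterministic and
standardised where noted:

- **Colored noise** by Fourier spectral synthesis: amplitudes ∝ f^{−β/2},
  i.i.d. uniform phases, zero DC, standardised to mean 0 / variance 1.
  Spectral synthesis (rather than AR filtering) gives the exact target
  exponent across the whole band, which is what the recovery tests
  measure.  `gen_brownian` (cumulative Gaussian sums) provides an
  independent β ≈ 2 reference.
- **Undulation**: a sum of 5 sinusoids with frequencies uniform in
  0.002–0.02 Hz (periods ~1–8 min, matching the "long waves" seen after
  a stimulus; the real waves' period/amplitude are not quantified
  anywhere, so the band is a stated assumption) and total RMS = amp ×
  baseline RMS, mean-preserving.
- **Spikes**: Poisson-timed biexponential transients (rise 0.2 s, decay
  2 s — plausible plant-spike kinetics, configurable) whose peak
  amplitudes are 1 + Lomax(μ−1) in baseline-SD units, i.e. PDF tail
  exponent exactly μ.

The four-class experiment emulator gives both *before* classes one
configuration (β = 1.2, undulation amp 0.15, spike rate 0.02 s⁻¹,
μ = 4.5 — pink-like baselines with sparse heavy-tailed spikes, the
reported pre-stimulus regime); `CB-after` (viable host) departs strongly
(undulation amp 2.0, spike rate 0.1) and `CW-after` intermediately with
a raised exponent (amp 0.9, β = 1.4, rate 0.05).  These magnitudes mirror
the *direction and ordering* of the reported host effects — entropy
falls and L rises after the stimulus, more for the viable host; the
between-treatment spectral change is carried by the wheat class — and
were chosen so the two after-classes are well but not perfectly
classifiable.  They are not calibrated to any measured effect sizes.

What passing tests on this synthetic world do **not** show: real
electromes are non-stationary, carry acquisition artifacts (the 5 Hz
tone, drift), have unknown undulation spectra, and differ between
plants; absolute parameter values from real data (kurtosis in the
hundreds, L in the tens-to-hundreds of samples, printed classification
accuracies) are not reproduction targets here — only definitional
values, estimator consistency, and directions of effect are.

## Classification stage

Raw features per window: mean, max, min, variance, skewness and kurtosis
of each of the FFT amplitude spectrum, the Welch PSD and the flattened
CWT magnitudes (18 values), plus the window's ApEn (per-window entropy;
a per-series option exists).  The 18 spectral features are z-scored
column-wise before PCA (they live on wildly different scales); the first
three component scores — signs fixed by making each component's
largest-magnitude loading positive — join the entropy as the final
4-feature vector.  PCA is fitted per comparison, on the windows entering
that comparison.

The battery is decision tree, RBF SVC, linear SVC, Gaussian process,
k-NN, random forest and Gaussian naive Bayes, plus a stratified dummy
baseline; hyperparameters are library defaults (frozen in the model
registry and echoed into every report), with scale-sensitive models
wrapped in a standardising pipeline.  Evaluation is repeated stratified
k-fold (k = 5, a conventional choice; 50 repeats by default), each
repeat reshuffling the folds and averaging fold accuracies; reports give
mean ± SD over repeats in percent, plus per-class sensitivity
TP/(TP+FN) and precision TP/(TP+FP) pooled over one split.  Every
stochastic element (fold shuffles, per-fit random states, the dummy's
sampling) derives from the master seed, so results are bit-reproducible.

By default windows of one recording may land in different folds.  With
overlapping windows this leaks recording identity into the evaluation;
the package therefore also provides a group-aware scheme
(`group_aware=True`, StratifiedGroupKFold) that confines each
recording's windows to a single fold — the recommended setting when
recordings, not windows, are the experimental unit.  On the synthetic
calibration data the leak is mild (null comparisons stay within a few
points of the dummy baseline), which is why the window-level scheme
remains the default.

Five standard condition comparisons are built in: bean before/after,
wheat before/after, before/before, after/after, and pooled bean vs
wheat.

## Group statistics

Paired contrasts use Shapiro–Wilk (α = 0.05) on the paired differences
to choose between the paired t-test and Wilcoxon signed-rank;
independent contrasts require both groups to pass the check for
Student's t (equal-variance), else Mann–Whitney U.  All tests are
two-sided; the chosen test and normality p-values are recorded.  No
multiple-testing correction is applied by default (parameters are
reported per-row, as is conventional in this literature); Holm
adjustment is available.  The empirical type-I rate of the gated
procedure is verified ≤ 7 % at α = 0.05 over 500 null simulations.
Constant-difference inputs short-circuit to a degenerate no-effect
result rather than feeding a zero-variance test.

## Numerical and scale choices

Tests and the acceptance script run at desk scale: β-recovery uses 20
seeds of n = 2¹⁷ samples; tail-exponent recovery 10 seeds of n = 10⁵;
multiscale-entropy shape checks n = 20,000 with S = 20; the
classification calibration 5 recordings per class of n = 8,192 samples
(10 windows of 1,122 samples each) with 50 repeats.  These sizes keep
every check comfortably reproducible on a single CPU while leaving the
estimators' asymptotics clearly visible.  Degenerate inputs (constant
series, zero-variance windows, empty bands) raise or flag explicitly
rather than propagating NaNs silently.

## Known limitations

- ApEn/SampEn sub-windowing means entropies of very long records are
  estimates from 20k contiguous samples, not the full series.
- The undulation detector is a spectral-excess heuristic, not a matched
  filter; its threshold was set against the synthetic generator.
- The PDF tail fit is a binned regression; for publication-grade tail
  inference an MLE (Hill-type) estimator should be preferred.
- Real-data idiosyncrasies (electrode drift, notch-filter shoulders,
  inter-plant variability) are outside the synthetic model; conclusions
  from the calibration tests transfer to real recordings only
  directionally.
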