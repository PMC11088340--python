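# Methods

`amcoding` reimplements, as a tested library, the computational chain used to
study amplitude-modulation (AM) coding in the auditory midbrain under a
pharmacological manipulation that increases AM sensitivity: stimulus
synthesis, single-unit AM-sensitivity metrics, spectrotemporal receptive
field (STRF) and context-gain models, a population threshold-crossing
decoder, and behavioral psychometrics.  All stages are exercised on
synthetic data with known ground truth; this note records the models, the
defaults and why, and what the synthetic tests do and do not establish.

## Stimuli

**SAM noise.** The carrier is band-limited pink (1/f power) noise on
2–48 kHz, synthesized in the frequency domain (1/√f magnitude, random
phases, zero outside the band) and normalized to unit RMS.  A trial is 1 s
of unmodulated (UM) noise followed by 1 s modulated by
`1 + m·sin(2π f_mod t + φ)`, with f_mod ∈ {16, 64, 128, 512} Hz, depth
m ∈ {0, 0.06, 0.125, 0.25, 0.5, 1} and intensity ∈ {45, 60} dB SPL
(48 conditions).  Three measures remove non-AM transition cues:

1. the UM segment is a *second* instance of the modulated noise whose
   spectral phases are randomized (`make_matched_um`), so UM and AM
   segments share power and spectral envelope exactly;
2. the segments are joined by a 20-ms cos/sin cross-fade whose squared
   weights sum to 1, keeping the combined instantaneous power of the two
   uncorrelated noises constant;
3. the modulator starts at a phase offset φ.  The default is
   φ = arcsin(√(1+m²/2) − 1); `mode="power"` provides
   φ = arcsin((√(1+m²/2) − 1)/m), the variant that makes the squared
   envelope at the transition exactly equal the mean AM envelope power
   1 + m²/2.  Both are exposed because the two closed forms differ only by
   the division by m and only the second satisfies the power-continuity
   property it is meant to enforce; the first is kept as the default
   convention of the original analyses.

The playback rate defaults to 97 656.25 Hz (a standard audio-hardware
rate for ultrasonic stimulation); it only scales the sample grid.

**Dynamic random chords (DRC).** Tone pips on a 5-ms × 1/12-octave grid
(2–64 kHz → 60 bins) with levels uniform on 25–70 dB SPL in 5-dB steps and
durations from a discretized exponential (decay 30 ms) truncated to
20–200 ms; 5-ms on/off ramps occupy one time bin each and are represented
at full level.  "Density of two tones per octave" is enforced as the
time-averaged count of *concurrently active* tones per octave: with
ρ = density/12 the target occupancy of one frequency bin, E[d] the mean
duration in bins, and tones forbidden from starting in an occupied bin,
the per-bin onset probability solves the renewal balance
p/(1−p) = ρ/((1−ρ)·E[d]).  (The naive p = density/(12·E[d]) undershoots
the target by a few percent once onset blocking is taken into account;
generated stimuli measure 2.00 ± 0.01 tones/octave.)  Overlap within a
(time, frequency) bin is disallowed so the level matrix is single-valued;
silence is stored as NaN.

**Input scalings.** Tone levels map to model input strength with
70 dB SPL → 1 and silence → 0 on six scales: `pow` = 10^((x−70)/10),
`amp` = 10^((x−70)/20), `dB0/dB20/dB40` = (x−ref)/(70−ref) above the
reference (0 below), and `binary` (presence).  The dB-reference scales are
normalized by (x−ref)/(70−ref) rather than x/(70−ref): only that form maps
the maximum level to 1 for nonzero references, which is the property the
scale family is defined by, and it reduces to x/70 at ref = 0.

**Pure-tone grids.** FRA sets cover 2–64 kHz in ¼-octave steps
(21 frequencies) × 0–60 dB SPL in 5-dB steps (13 levels), 100-ms tones at
200-ms intertrial intervals, 20 repetitions in seeded pseudorandom order.

## Synthetic data

The generators produce data with the statistical structure the analyses
assume — no biophysics (no adaptation, refractoriness, or correlated noise
across units).  Passing recovery tests therefore shows the estimators are
correct and well calibrated for their assumed model class, not that real
recordings satisfy those assumptions.

**SAM units.** Inhomogeneous Poisson spikes with intensity
`r_base` before the transition and
`r_base · g(m) · (1 + tanh(k·m)·sin(2π f_mod (t−t₀−latency) + θ₀))`
after it, sampled exactly by thinning.  The default gain is
g(m) = 1 + 0.8·m (rate coding); the tanh keeps the modulator in [0, 1] so
the rate never needs rectification at any depth or locking strength k.  A
consequence of this design is that the vector strength of a fully
modulated unit saturates at 0.5 (the resultant of a (1+sin) intensity
profile), not 1; per-trial VS_PP values still span [−1, 1].  Condition
multipliers (the drug analogue) scale the *depth-dependent* part of the
gain, g(m)−1, and the locking strength, leaving unmodulated drive
untouched — scaling the whole gain would change catch-trial statistics and
conflate overall excitability with AM coding.

**LNP units.** The per-bin rate is computed exactly by the context-gain
equation (below) on the scaled DRC, rectified at zero (an exponential
output nonlinearity is available), and Poisson-sampled per repetition.
`make_gabor_prf` provides a difference-of-Gaussians PRF (excitation with
delayed flanking inhibition) whose default peak weight (12 with the 15-s
test stimuli, i.e. a strongly driven unit) is chosen so units pass the
signal-power inclusion rule at 10–20 repetitions; `make_suppressive_cgf`
plants negative context weights along the τ = 0 and φ = 0 axes, the
combination-sensitive pattern these models typically recover from real
data.

**Behavioral sessions.** Hit probability
`fa + (1 − fa − lapse)·logistic((20log₁₀m − θ)·β)` with β = 0.5 dB⁻¹ by
default (rodent AM-detection psychometric functions are steep; this slope
also keeps the latency-ROC d′ = 1 point aligned with the psychometric
midpoint θ, so planted and recovered thresholds agree by construction of
the generator/analysis pair).  Latency on responses is
`floor + scale·exp(−(20log₁₀m − θ)·β)` with multiplicative lognormal
noise, reproducing the inverse depth–latency relation; catch trials lick
at the false-alarm rate with floor-distribution latencies.

## Single-unit AM sensitivity

Spikes from the last 500 ms of the AM segment (onset effects excluded) are
reduced per trial to either the phase-projected vector strength
VS_PP,t = VS_t·cos(θ_t − θ_c) (θ_c the pooled mean phase; zero-spike
trials contribute 0) or the firing rate.  Each nonzero depth's per-trial
distribution is compared with the depth-0 (UM) distribution of the same
f_mod × intensity × condition block by rank-based ROC (ties count ½).  The
AUC, clipped to [0.5/N_pairs, 1 − 0.5/N_pairs] to avoid infinities, maps
to d′ = |√2·Φ⁻¹(AUC)| (a config switch selects 2·Φ⁻¹).  The detection
threshold is the lowest-depth upward crossing of d′ = 1 under linear
interpolation in dB re full modulation; a curve that starts above 1 is
censored at the lowest tested depth, one that never reaches 1 has no
threshold.  Where conditions are *compared*, undefined thresholds are
censored at 0 dB (full modulation): a unit with no measurable threshold is
worse than any measured one.

## Pure-tone analysis

Kernel spike densities use a Gaussian kernel (σ = 5 ms for FRA responses,
σ = 2 ms where single-trial timing matters) on a grid fine enough that the
density integrates to the spike count.  Tuning significance is a max-T
sign-flip permutation test: the per-cell statistic is the mean paired
difference between evoked (0–100 ms) and spontaneous (last 50 ms of the
ITI) rates; flipping the per-repetition difference signs yields the null
distribution of the maximum statistic over all 273 cells, controlling the
family-wise error at α exactly under exchangeability.  The mask is then
restricted to the contiguous cluster containing the peak cell.  This is a
deliberate surrogate for frequency-autocorrelation tuning-area methods,
whose published descriptions do not specify a reproducible algorithm; it
preserves the contract (a significance-bounded tuning area with calibrated
false-positive rate).  CF is the frequency of the significant cell at the
lowest significant level (ties → larger response), MT that level.  The
threshold-shift-versus-CF trend is summarized by ordinary least squares on
[1, log₁₀CF, (log₁₀CF)²] with CF in kHz.

## STRF and context-gain models

With s(t, f) the scaled stimulus, the simple model is
r(i) = c + Σ_{j,k} w^tf_{j,k} s(i−j, k); the context model multiplies each
tone's contribution by (1 + Σ_{m,n} w^τφ_{m,n} s(i−j−m, k+n)), where w^tf
is the principal receptive field (PRF, lag × absolute frequency) and w^τφ
the context gain field (CGF, relative time τ × relative frequency φ).
Stimulus bins outside 2–64 kHz or before stimulus onset are silent (0).

**Estimation.** The response is the trial-averaged PSTH in the stimulus's
5-ms bins.  Simple-model weights are the posterior mean under a separable
squared-exponential Gaussian prior over (lag, log-frequency) whose overall
scale, two length constants and the noise variance maximize the marginal
likelihood (automatic smoothness determination).  The evidence is
evaluated via the Kronecker eigendecomposition of the prior — O(p²(J+K))
per evaluation instead of O(p³) matrix products — and ascended by L-BFGS-B
in log-space from two initializations (evidence surfaces are multimodal);
the intercept is unpenalized (handled by centering).  Ill-conditioned
kernels carry a 10⁻⁶ diagonal jitter.

The context model is fit by alternating least squares: exact solve of
(c, PRF) given the CGF under the ASD prior at its optimized
hyperparameters, then exact solve of the CGF given the PRF under a fixed
squared-exponential smoother of bandwidth 0.5 time bin (2.5 ms) × 2
frequency bins (1/6 octave) with unit prior variance.  Each alternation
minimizes the same penalized objective (squared error + both smoothness
penalties) over its block, so that objective is non-increasing by
construction — the monotonicity the tests assert; the raw training error
tracks it in practice.  Iteration stops at a relative objective change
< 10⁻⁵ or 50 alternations (a fixed small iteration count inside
cross-validation folds).  With the CGF at zero the context model's
predictions equal the simple model's exactly.

**Windows.** PRF lag window 0–100 ms (21 bins) by default; CGF window
τ ∈ 0–40 ms (9 bins), φ ∈ ±1 octave (25 bins).  The simulation studies in
the test suite use reduced windows (8–10 lag bins; τ 5 bins × φ ±6 bins)
and 15–60-s stimuli at 10–20 repetitions — sizes at which the studies run
in minutes on one core while leaving the recovery properties comfortably
resolvable (PRF recovery correlation ≈ 0.99 at the full 60-s × 20-rep
setting).

**Predictive power.** Signal power is the unbiased estimator
P̂(μ) = (N·P(r̄) − ⟨P(r⁽ⁿ⁾)⟩)/(N−1) with P(·) the time-variance; noise
power is ⟨P⟩ − P̂(μ), and the two add to the mean per-repetition power
exactly.  Units qualify for model fitting when signal ≥ 2 × noise.  Model
quality is the cross-validated normalized predictive power
(P(r) − P(r−ρ))/P̂(μ) on held-out time bins, 10 random disjoint tenths of
bins per repetition (folds are redrawn across repetitions).  ASD
hyperparameters are optimized once on the full data and held fixed across
folds (per-fold evidence optimization is an order of magnitude more
expensive and changes fold scores negligibly); the context model is
warm-started from the full-data fit and re-solved on training bins only,
so every weight entering a fold's prediction is estimated from training
bins.  The CGF-significance null refits only the CGF block (PRF, design
and Gram matrix fixed) against circularly time-shifted responses — the
statistic that measures context structure at O(ms) per draw, where a full
ALS refit per permutation would cost minutes.

## Population decoder

Trial-averaged PSTHs (bin 1/256 s ≈ 3.9 ms) to all full-depth stimuli and
all UM stimuli are differenced into a units × time matrix; its leading
left singular vector (PCA over the unit dimension, uncentered — the mean
difference is the signal of interest) is the AM-encoding component, signed
so the difference projects positively.  Single-trial kernel spike
densities (σ = 2 ms) projected onto the (baseline-condition) component
give a population signal; the simulated response latency is the first
upward crossing of a detection level after the transition plus a
non-decision time in [100, 200] ms, with no crossing → no response.
Decoder parameters are grid-searched (12 log-spaced levels spanning
0.1–3 × the median peak projection; non-decision times every 25 ms)
against behavioral latencies by the RMS difference of per-stimulus-group
latency CDFs on a 10-ms grid, no-response trials never counting toward the
CDF.  Decoder d′ and thresholds use the same latency-ROC as the behavioral
analysis (shorter latency = stronger evidence; no-responses share the
ceiling rank).

## Behavioral psychometrics

Hit rates per stimulus cell and false-alarm rates from catch trials are
clipped to the exact rationals [0.5/N, 1 − 0.5/N] before any d′
conversion.  Sensitivity per depth comes from the ROC between AM-trial and
catch-trial latency distributions with no-responses at a common ceiling;
thresholds are interpolated at d′ = 1 as above.  The mixed-effects
modeling of d′ and thresholds that typically follows is deliberately out
of scope — the module exports tidy tables suitable for any mixed-model
tool.

## End-to-end drug analogue

The bundled configuration simulates one population (10 units, 25
trials/condition-cell, f_mod 16 and 512 Hz, 60 dB SPL) and one behavioral
session under two conditions, the second multiplying each unit's AM
contrast ×2 and locking strength ×2 and shifting the behavioral threshold
−6 dB.  The full chain (temporal and rate d′, decoder, psychometrics)
reports lower AM thresholds in the high-gain condition in ≥ 18/20 seeds;
the decoder applies the baseline-derived component and detection level to
both conditions.

## Numerical conventions and limitations

* All randomness flows through `numpy` Generators; one global seed expands
  into per-stage substreams by SHA-256 counter hashing (`stage_seed`).
* ROC ties count ½ everywhere; AUC clipping uses half a pair.
* Evidence optimization is capped (default 80 function evaluations per
  restart); the returned model flags `converged=False` when the cap binds,
  and the best iterate is used.
* The decoder's PSTH bin is 1/256 s exactly (the "3.9 ms" of hardware-
  locked acquisition systems).
* Known limitations: generators omit adaptation, refractoriness and
  inter-unit noise correlations; the FRA significance step is a surrogate,
  not the historical autocorrelation method; ASD assumes Gaussian noise on
  PSTH bins (adequate for trial-averaged counts, not for single trials of
  sparse units); the context model's CV warm start reuses the full-data
  CGF as an initial point, which slightly favors the context model when
  ALS is stopped after very few fold iterations.
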