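# Methods

This note documents the models, parameter choices and numerical decisions
behind `fipcouple`, and what the synthetic-data tests do and do not
establish about real recordings.

## Signal model and normalization

Raw fluorescence is modeled (and, in the synthetic generator, produced) as

    F(t) = F_baseline * (1 + bleach(t) + motion(t) + calcium(t) + noise(t))

with a slow multiplicative exponential bleach, a smooth motion artifact
shared between each signal channel and its isosbestic reference, an
event-locked calcium drive, and white sensor noise. Isosbestic channels
carry everything except the calcium component.

**Isosbestic correction** fits `signal ~ a*isosbestic + b` by OLS over the
whole session and subtracts the fit, restoring the session mean. Because
bleaching and motion enter both channels identically, both cancel in one
regression; on synthetic sessions with a dominant artifact the corrected
variance drops by well over 90%. If the isosbestic channel is flat the
routine falls back to subtracting a 0.1 Hz low-pass trend and warns. The
commercial acquisition software's correction is undocumented; this linear
regression is the standard, swappable replacement.

**ΔF/F0** uses behavior-specific windows: digging and licking (−5, 5) s
around onset with F0 the mean raw F over (−4, −2) s; turning (−1, 1) s with
F0 over (−1, 0) s. Windows are half-open sample ranges
`[round(start*fs), round(end*fs))` with the onset snapped to the nearest
sample; F0 ≤ 0 raises rather than producing sign-flipped traces. ΔF/F0 is
exactly invariant to positive raw-gain rescaling. F0 is taken from the
corrected raw trace, per the definition of the quotient.

**Bandpass (0.001–3 Hz, zero-phase).** A direct forward–backward
Butterworth bandpass is numerically treacherous here: the 0.001 Hz corner
implies a settling time of hundreds of seconds, so edge-padding initial
conditions leave order-one drift across any 10–30 s trial (empirically a
10 Hz probe sine emerged larger than it went in). The filter is therefore
realized as a zero-phase 2nd-order 3 Hz low-pass plus subtraction of the
mean and of a zero-phase 2nd-order 0.001 Hz low-pass trend computed with
Gustafsson's minimal-transient forward–backward method. The composite is
zero-phase (lag estimates are unaffected), passes 0.5 Hz with gain ≥ 0.99,
attenuates 10 Hz by > 20 dB and removes DC. Trials are bandpassed first,
then trimmed 1 s at each end (digging/licking only) to drop filter edges;
the pipeline order is fixed as filter → trim.

## Coupling statistics

*Static correlation* is the Pearson r of the bandpassed (and, for
digging/licking, trimmed) trial traces. *Sliding correlation* advances a
4 s window in 0.5 s steps; only complete windows count, giving
`floor((T−4)/0.5)+1` windows.

*Phase lag*: `c(tau)` is the Pearson correlation between `A(t)` and
`B(t−tau)` over the overlapping samples for integer lags within ±2 s, and
τ\* maximizes |c|. Per-lag Pearson normalization keeps every value in
[−1, 1] and makes curves from trials of different lengths averageable. Sign
convention (chosen and documented here, since either is defensible):
**positive τ\* means region B precedes region A**. Ties in |c| break toward
smaller |τ|, then toward negative τ. The estimator is exact for noiseless
shifts; for slowly varying (plateau-like) transients the |c| curve is flat
near its peak, so per-trial estimates scatter by a few samples and the
tie-break pulls weakly toward zero — visible in the README example.

*Amplitudes*: plateau = mean ΔF/F0 over [1, 2) s after digging onset;
peak = mean over [0, 0.5) s after lick initiation.

*Sum-dFF activity*: long epochs are cut into 8 s bins (final partial bin
dropped), each normalized with F0 = its own 20th percentile; a bin is kept
only if the Pearson r between its ΔF/F0 and the raw reference trace is
≥ 0.8 (undefined r or F0 ≤ 0 also exclude). When ΔF/F0 is derived from the
same array used as reference the QC is trivially satisfied (a positive
affine map has r = 1); the check has teeth only when the normalized trace
comes from processed data and the reference is the original raw F, which is
how the pipeline calls it.

*Per-subject aggregation* defaults to the mean of per-trial r
(`mean_trial_r`); correlating the trial-averaged traces is available by
config (`r_of_mean_trace`), since the two differ when trial-to-trial
variability is high.

## Granger causality

Per trial: bandpass → ADF stationarity test (constant term, no trend; lag
length by AIC up to the Schwert bound `12*(n/100)^0.25`) → first
differences until stationary (at most 2; both channels are differenced to
the larger of their individual orders so the bivariate model stays
balanced; still-non-stationary trials are excluded) → lag order by BIC
(AIC by config) over a common estimation sample, with a 1e-12 ridge
guarding the residual-covariance log-determinant against degenerate input →
GC in both directions.

GC(x→y) = ln(RSS_restricted/RSS_full), restricted = y on its own p lags,
full adds x's p lags; nonnegative by nesting. Significance is the nested
F test with (p, n_rows − 2p − 1) degrees of freedom, n_rows = n − p. No
multiple-testing correction across trials; summaries average GC over
significant trials only (p < 0.05) and report the significant fraction.
The default maximum order is 10 (0.25 s at 40 Hz). For unidirectional
coupling `y_t = 0.5 x_{t−1} + e_t` with white x the population GC is
ln(1.25); when x is itself AR(1) with φ = 0.5 the restricted model gains
predictive power from y's induced autocorrelation (ρ₁ = 1/8) and the exact
population value is ln(21/16), not the tempting ln(4/3) — both values are
verified by simulation.

## Motion-energy GLM

Motion energy is the summed absolute frame-by-frame grayscale difference,
linearly interpolated onto the 40 Hz photometry clock (endpoints clamped,
preserving nonnegativity) and convolved with a unit-area Gaussian kernel to
mimic indicator dynamics. The "2.5 s kernel" is read as full width 2.5 s
(σ = 2.5/6 s, truncated at ±3σ); reading 2.5 s as σ is available by flag.
Reflective padding avoids onset transients on short trials. The fit is OLS
with intercept (scikit-learn `LinearRegression`); β scales inversely with
regressor gain while R² is invariant, and per-mouse values are means of
trial-level fits. Zero-variance regressors exclude the trial with a
warning.

## Synthetic generator

The generator emulates the statistical structure the estimators assume —
not the biophysics. The calcium transient is a double-exponential kernel
(rise 0.3 s, decay 1.5 s by default) convolved with a boxcar spanning each
behavioral event and normalized so the mean drive over 1–2 s post-onset is
exactly 1; region amplitudes are therefore plateau ΔF/F0 units (defaults
0.30 / 0.25, a realistic transient size for cortical/striatal bulk GCaMP).
The region-B drive is the region-A drive advanced by `inter_region_lag`
(positive = B leads) and mixed with an independent smooth drive at weight
`1 − shared_fraction`, scale-matched to the shared drive. Defaults: 40 Hz,
10% bleach with 600 s time constant, white sensor noise 0.01 ΔF/F0 units,
smooth motion artifact of 1 raw unit shared bit-for-bit with the isosbestic
channel. Event schedules are rejection-sampled so every digging event
satisfies the inclusion rules (≥ 3 s duration, ≥ 10 s clean baseline, full
window inside the recording); infeasible requests raise a sizing error
naming the constraint. All randomness derives from one seed via named
substreams, so identical parameters give bit-identical sessions.

Stored ground truth: the lag, the per-region plateau implied by the
noiseless components (with zero bleach it equals the amplitude parameter),
and a population trial correlation computed from the noiseless calcium
windows attenuated by the per-channel noise factor
`sd(signal)/sqrt(sd² + noise_sd²)` — an analytic-from-components value, since
no closed form exists for the transient-plus-noise mixture. For tests that
need an *exact* population correlation, `simulate_correlated_pair` builds
Gaussian pairs with correlation ρ by construction (identical filtering of
both channels preserves ρ because their spectra are proportional).

Motion-energy noise is half-normal (|N(0, σ)|): nonnegative without
clipping and independent of the latent drive, so the OLS slope stays
unbiased (the intercept absorbs the noise mean).

What the generator does **not** emulate: spiking or indicator
nonlinearity, dopamine dynamics, hemodynamics, non-Gaussian artifact
bursts, or real inter-animal variability. Passing recovery tests therefore
demonstrates the estimators are correct and calibrated under the assumed
signal structure, not that real recordings satisfy that structure.

## Monte-Carlo study sizes

Recovery and calibration checks use sizes chosen so each property is
measured with comfortable margin: 80 noiseless shifts and 200 noisy seeds
for phase lag; 200 trials per correlation level (tolerance 3× the
Monte-Carlo SE); 300–500 seeds for the GC type-I rate, 100–200 runs at
n = 2000 for direction recovery, and 60–100 runs at n = 5000 for the
asymptotic value (tolerance 0.02 nats); 100 trials for GLM recovery at a
population R² of 0.6; 500–1000 random event streams against brute-force
rule oracles; and 30–50 replicates of the 8-vs-8 cohort contrast.

The cohort contrast ("control": shared fraction 0.95, lag 0, amplitudes
0.30/0.25; "PFF-like": shared 0.70, lag +0.25 s, striatal amplitude 0.15;
5 trials per subject in 200 s sessions, noise 0.02) is designed for power
by construction: the shared-fraction reduction is kept moderate because a
stronger independent drive inflates the per-trial variance of the phase-lag
estimator (a flat |c| peak) faster than it moves its mean, which degrades
the rank test on lag even though the true lag difference is unchanged. Null
calibration compares two independently simulated control cohorts.

## Known limitations

* The phase-lag estimator quantizes to the sample grid (25 ms at 40 Hz);
  no sub-sample interpolation is attempted.
* The ADF-based differencing decision is itself a hypothesis test; on short
  trials (≈ 320 usable samples) its power is limited, and borderline trials
  may enter the GC summary at d = 0.
* `sum_dff` follows the bin-wise 20th-percentile normalization exactly;
  for signals with long silent stretches the percentile baseline can sit
  below the true baseline, inflating the sum.
* The CLI's `glm` subcommand aligns motion-energy tables by sample index
  from the epoch start; hardware-timestamped alignment across devices is
  the caller's responsibility.
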