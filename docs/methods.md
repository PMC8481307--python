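# Methods

This note documents the models, conventions and numerical choices behind
`megfp`, in the spirit of a methods appendix: what each stage computes, the
knobs that matter, and what the synthetic cohorts do and do not emulate.

## Signal model of the synthetic cohort

`megfp.synthetic.generate_cohort` draws, for subject *i*, session *s*,
ROI *r* and frequency band *b*:

```
log-amplitude a[i,s,r,b] = mu_b + u[i,r,b] + v[i,s,r,b]
u ~ N(0, sigma_between_b)        # stable individual trait
v ~ N(0, sigma_within_b)         # session-to-session drift
```

and synthesises the ROI signal as

```
x[i,s,r](t) = sum_b exp(a[i,s,r,b]) * c[i,s,r,b](t)        # band carriers
            + sum_k w[i,s,r,k]     * L[i,s,k](t)           # shared latents
            + noise_sd * eps(t)                            # sensor noise
```

* **Carriers** `c` are white noise shaped by the *same* FIR filter bank used
  by the analysis path, normalised by the filter's theoretical white-noise
  gain `sqrt(sum h^2)`. Normalising by the realised sample SD instead would
  force the power of disjoint time segments of one recording to be exactly
  anti-correlated (their variances must average to one) and plant a spurious
  anti-identity signal in split-half analyses — a real pitfall we document
  here because it silently biased split-half chance levels during
  development.
* **Individual alpha rhythm**: the band named `alpha` uses a narrow ±1 Hz
  carrier centred on a subject-specific peak ~ N(`alpha_peak_mean` = 10 Hz,
  `alpha_peak_sd` = 1 Hz), clipped into (2, Nyquist−2). Peak-frequency
  variability is a strong, stable identity channel, as expected for human
  resting-state rhythms.
* **Inter-ROI coupling**: `n_latents` shared band-limited carriers per
  subject-session are mixed into every ROI with persistent subject-specific
  weights `w[i,r,k] ~ N(0, coupling_sd)`; the session drift added to the
  weights has SD `coupling_sd * mean(sigma_within)`, so one knob controls
  drift for both feature families. Envelope correlations between ROIs
  sharing a latent are stable per subject, giving each individual a
  connectome fingerprint.
* **Band means** `mu_b` follow a coarse high-frequency roll-off
  (`center_freq^-0.5`, alpha doubled). No exact 1/f spectrum, sensor
  geometry, source leakage or artifact waveforms are modelled: passing
  tests show the *statistics* behave correctly under the assumed structure,
  not that the generator reproduces real MEG data.

**Demographics.** A latent score `z` is a fixed unit-norm linear
combination of `n_planted` (default 5) randomly chosen (ROI, band)
log-amplitude traits. Age and clinical status load on `z` with strength
`demographic_effect` (`covariate = (effect*z + e)/sqrt(effect^2+1)`,
`e ~ N(0,1)`; age mapped affinely into 18–73 years, clinical status
median-split); sex and handedness are independent Bernoulli(½). With
`demographic_effect = 0` demographics are fully independent of the signal,
which is the null used to calibrate PLS honesty. The planted indices,
weights and per-subject latent ride on `DemographicsTable.attrs["planted"]`.

**Artifacts.** Cardiac/ocular/motion RMS values are log-normal draws
independent of identity; scan duration is jittered uniformly within
92–100 % of the nominal duration. Their correlations with differentiability
are therefore nulls by construction.

**Empty-room analog.** One pseudo-recording per subject-session slot with a
*deterministic* band-amplitude profile chosen to match the cohort's mean
PSD exactly in expectation: amplitude
`exp(mu_b + sigma_between_b^2 + sigma_within_b^2)` (the log-normal power
mean) with latent power folded in as `n_latents_b * coupling_sd^2`, and the
alpha carrier placed at the population mean peak. Because nothing random
persists per recording, no identity signal exists and identification sits
at chance. The empirical per-band PSD match holds to <10 % once the number
of subject × ROI amplitude draws is a few hundred (the log-normal mean
converges slowly) and the individual alpha windows stay inside the alpha
band; the comparison test uses 16 subjects × 16 ROIs with
`sigma_between = 0.3` and `alpha_peak_sd = 0.5` for that reason.

## Feature extraction

* **Filter bank**: symmetric (linear-phase) FIR band-pass designed with
  `scipy.signal.firwin` (Hamming window), applied once with centred FFT
  convolution on odd-reflection-padded signals — exactly zero-phase, output
  length equals input length. Transition width is
  `min(2, max(0.5, f_lo/2))` Hz, giving ~53 dB stop-band attenuation and
  <0.1 dB pass-band ripple; the contract tests check ±1 dB in-band and
  ≥40 dB one octave outside. Signals must be longer than the filter
  (e.g. ≥6.6 s for the delta band at 600 Hz).
* **AEC**: Hilbert envelope magnitudes of the band-passed signals,
  Pearson-correlated over all ROI pairs. Pairwise orthogonalization
  (leakage-corrected variant) exists behind `orthogonalize=True` but is
  **off** by default — plain AEC is the pinned convention. Zero-variance
  envelopes yield NaN entries with a warning, never silent zeros.
* **Welch PSD**: Hann windows of 2 s with 50 % overlap, one-sided,
  0–150 Hz at 0.5 Hz (301 bins). Values are raw power per Hz; `log_psd`
  switches to log10 before correlation-based matching (off by default).
* **Vectorization**: connectome → upper triangle excluding the diagonal in
  lexicographic (i < j) row-major order (2278 edges for 68 ROIs); PSD →
  ROI-major concatenation of bins, restricted to a band's bins when one is
  given (per-bin values, not band means).
* **Segmentation**: `within_halves` (two equal halves per session),
  `segments_30s` (three 30 s segments from the recording start, leftover
  discarded — placement at the start is a pinned convention), `sessions`
  (full sessions). Challenge pairing: within/within-short pair datasets
  inside a session; between pairs full sessions; between-short pairs every
  day-1 segment with every day-2 segment (3 × 3 = 9 ordered pairs).

## Identification and differentiability

`similarity` correlates dataset-1 rows with dataset-2 rows; `identify`
takes the row-wise (or column-wise) argmax with deterministic lowest-index
tie-breaking (ties counted and logged; they are measure-zero on continuous
features but must reproduce on synthetic edge cases). Subjects with an
all-undefined probe row are reported unidentifiable and excluded from the
accuracy denominator. Both probe directions are always computed; the
headline number is the row direction.

`D_self(i) = (A[ii] − mean_{j≠i} A[ij]) / sd_{j≠i} A[ij]` with the sample
(n−1) SD and the diagonal excluded from the null — the literal reading of
"all *other* individuals"; `include_self_in_null=True` preserves the
inclusive variant. σ = 0 or fewer than two finite off-diagonal values give
NaN, reported as missing.

## Reliability metrics

* **ICC(1,1)**, one-way random effects with subjects as targets and the two
  datasets as k = 2 repeated measures:
  `(MSB − MSW) / (MSB + (k−1) MSW)`. This is the "each participant as their
  own rater" form; it is invariant to common affine transforms and matches
  `pingouin.intraclass_corr`'s ICC1 to 1e−10 (used as an independent
  cross-check in tests).
* **Group consistency** Φ(e) and **differential power** DP(e) operate on
  per-subject feature vectors normalised to unit Euclidean norm per
  dataset. `P_i(e)` is the fraction of other subjects whose cross product
  strictly beats the within-subject product in either pairing direction,
  clipped below at `1/(2(N−1))`; `DP(e) = Σ_i −ln P_i(e)` (sum, not mean).
  Clip floor and sum aggregation are pinned conventions of this package.

## PLS correlation

Columns of both blocks are z-scored (binary demographics first recoded to
centred ±0.5), `R = X'Y/(n−1)` is decomposed by SVD. Permutation inference
shuffles the rows of the demographic block and uses the add-one estimator
`p_k = (1 + #{S_perm,k ≥ S_obs,k}) / (n_perm + 1)`, which cannot return 0
and is valid by construction. Bootstrap resamples subjects with
replacement; each resample's saliences are aligned to the original by an
orthogonal Procrustes rotation before standard errors (sign/order of SVD
components is arbitrary, so unaligned SEs would be meaningless). Neural
bootstrap ratios are salience / SE, capped at ±1e6 with a warning when the
SE collapses (degenerate deterministic links); demographic CIs are 2.5–97.5
percentile intervals and may be asymmetric. Resamples that produce a
constant column are dropped and counted.

## Problem sizes and numerical choices

Defaults mirror a realistic resting-state study: 68 ROIs, 600 Hz sampling,
300 s sessions, the six canonical bands. The test and acceptance
simulations run scaled-down cohorts — 300 Hz, 3–16 ROIs, 20–90 s, the
mid-frequency bands (θ/α/β, whose filters are short) — chosen so each
property is measured with adequate Monte-Carlo resolution while the whole
suite stays fast; the properties under test (oracle equivalence, chance
calibration, monotonicity, planted-structure recovery) do not depend on the
full problem size. Notable regimes:

* perfect-identification regime: `sigma_between = 1`, `sigma_within =
  0.01`, `noise_sd = 0.05`, 20 subjects — identification must be 100 %;
* chance regime: empty-room analogs across two independent pseudo-sessions
  — pooled accuracy must sit in the 95 % binomial band around 1/N.
  (Split-half empty-room comparisons are avoided for the chance test: with
  zero between-subject signal, even the faint noise shared across the
  split boundary by the filter's impulse response measurably exceeds
  chance);
* reliability gradient: per-band `sigma_between` = {0.05, 0.1, 0.2, 0.4,
  0.8} at `sigma_within = 0.1` — median ICC must recover the rank order;
* PLS recovery: n = 100, `demographic_effect = 2` (a strong coupling;
  correlation ≈ 0.89 between latent and covariate), a 9-feature band-power
  space with the latent-coupling channel off so the amplitude-to-feature
  map is uniform. The salience-cosine criterion is limited by the
  `sqrt(E)/sqrt(n)` sampling noise of the cross-correlation matrix, not by
  the method, which is why the recovery experiment keeps E small.

Degenerate inputs are rejected or flagged, never silently patched:
non-finite config values name the offending field; bands reaching Nyquist,
too-short recordings and undersized cohorts raise with the required vs
available quantity; undefined statistics (zero variance, zero spread) are
NaN plus a warning.

## Limitations

The generator's stationary Gaussian carriers lack 1/f shape, bursts,
non-stationarity, artifacts and spatial leakage, so passing tests validate
the analysis machinery and its statistical calibration — not performance
claims on real recordings. Orthogonalized AEC is provided but untuned.
Network-level aggregation of reliability maps expects an externally
supplied ROI→network label table; no atlas tooling is included.
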