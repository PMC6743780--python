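# Methods

## The model in brief

The pipeline treats a raga excerpt as a pair of stimulus descriptors —
tonality (continuous) and rhythm mode (binary) — and a listener's emotion
rating as a noisy linear function of those descriptors plus the listener's
familiarity with the idiom. Group differences in *which* cue carries the
emotion are summarized by a ratio of variance shares (the odds ratio).
This document records the concrete operationalizations, defaults, and the
design decisions taken where the procedure was genuinely open.

## Tonality estimation

Melodic pitch is referenced to the tonic drone (Sa, default 261.5 Hz) in
cents, `1200·log₂(f₁/f₀)`. Voiced frames are collated into 100-cent bins
labelled −1200…2400 cents; each bin spans label ± 50 cents, so
just-intonation deviations (|offset| < 50 cents) map to the intended swara.
Frames outside [−1250, 2450) are dropped and counted. The three octaves are
folded by summing corresponding bins (the +2400 bin folds to the tonic
class), and the tonality ratio is

    m/M = Σ occupancy{100,300,600,800,1000} / Σ occupancy{0,200,400,500,700,900,1100}.

"Mean frequency of occurrence" is implemented as occupancy proportion; the
m/M ratio is identical under means or sums. A zero major-bin mass makes
the ratio undefined; it is flagged, not returned as infinity.

Pitch input is either a ground-truth track from the synthesizer (the
default path: the analysis of interest starts at the pitch track) or, for
real recordings, a deliberately simple autocorrelation estimator: 2048-
sample Hann frames at a 30 ms hop, strongest normalized autocorrelation
peak in 80–1200 Hz with parabolic refinement, voicing gated on periodicity
(> 0.5) and on an adaptive RMS floor (0.75 × median frame RMS), which also
suppresses drone-only frames between melody notes. It is a monophonic
melody-over-drone estimator, not a polyphonic melody extractor.

## Rhythm descriptors

Both descriptors are computed from a spectral-flux onset envelope (STFT
1024/256 at 22 050 Hz, log-compressed magnitudes, half-wave-rectified
frame-to-frame increase), smoothed with a 60 ms moving average and
detrended by a 2 s local median.

* **Event density** — peaks of the conditioned envelope above 0.5 × its
  98th percentile, minimum gap 150 ms, divided by duration (onsets/s).
* **Pulse clarity** — Welch power spectrum of the conditioned envelope
  (24 s segments, 50% overlap), restricted to 0.25–10 Hz, normalized to a
  distribution q; clarity = 1 − H(q)/log(nbins) ∈ [0, 1].

These are concrete readings of verbal definitions ("entropy of the
fluctuation spectrum", "onsets per second"); absolute values are **not**
comparable to MIRtoolbox's, so analyses assert only orderings and
contrasts (gat > alaap), never absolute levels. The Welch averaging
matters: on short excerpts the raw periodogram of a sparse, aperiodic
alaap envelope is so variable that its entropy rivals a genuinely periodic
gat spectrum; averaging over ≥ 7 segments (i.e. ≥ ~2 minutes of audio)
flattens the aperiodic case and restores the intended ordering. The
stimulus default of 180 s — the duration of the excerpts in the emulated
survey design — gives 14 segments.

## Synthetic stimuli

Each excerpt is a continuous tonic drone (fundamental + sub-octave +
octave, low amplitude) with a monophonic melody of harmonic tones (5
partials, attack 10 ms in gat / 120 ms in alaap) and, in gat, a damped
percussive click on each onset. Onsets are an exponential (free-rhythm)
point process at 0.5 events/s for alaap, IOIs clipped to [0.25, 4]×mean,
and a 1.5 events/s isochronous grid with 4% Gaussian jitter for gat —
reproducing the direction of the measured mode contrast (higher regularity
and tempo in gat).

Swaras are assigned to note slots by an exact **time quota**: target frame
counts per swara are `weights × total_frames` (largest remainder), slots
are assigned longest-first to the largest remaining deficit, and slot
lengths are nudged by whole 30 ms frames so each swara's total occupancy
hits its target exactly. The rationale: a raga prescribes how much its
swaras are dwelt upon, and the pipeline's tonality measure is exactly
time occupancy; iid sampling at alaap note counts (~90 per 3 minutes)
would leave sampling noise far above the intended alaap/gat tonality
invariance. Note order, onset times and octave placement (weights over
{−1, 0, +1}; octaves fold out of the tonality) remain random per seed.
Regenerating with the same seed is byte-identical.

The default stimulus set is 12 synthetic ragas whose swara sets follow
well-known Hindustani scales (Bilawal … Malkauns) — synthetic stand-ins,
not transcriptions — with implied m/M ratios spanning 0 to ≈ 1.7, each
rendered in both modes (24 excerpts).

## Simulated survey

Ratings follow `r = β₀ + β_t·tonality + β_r·rhythm + β_f·familiarity + ε`,
ε ~ N(0, 0.8 rating units), rounded and clipped to the 0–4 integer scale
(an `integer_scale=False` switch exists for calibration studies that need
the continuous response). Group sizes default to 143 E / 112 NE;
familiarity is N(2.86, 1.09) for E and N(1.99, 1.02) for NE, clipped to
0–4. 30% of participants rate only a random half of the design (6 ragas
per mode), so per-excerpt rater pools — and hence excerpt-level mean
familiarity, the regression covariate — vary across excerpts, as in a
survey with an early opt-out.

The default cue weights make E tonality-dominant for 7 of 8 emotions
(devotional stays rhythm-led) and NE rhythm-dominant for 7 of 8 (angry
stays tonality-led), with signs following the valence gradient in which
komal-heavy (high m/M) material reads as plaintive:
happy/romantic/devotional/calm decrease with tonality,
angry/longing/tensed/sad increase with it. Intercepts and slopes are laid
out so each region of the design (low/mid/high tonality × mode) has one
clearly dominant emotion — as real ragas do — which keeps modal labels
well defined under rating noise; without such separation the modal label
of a near-tied excerpt is a coin flip in each group and cross-group label
agreement degenerates. These weights are invented — no survey data are
deposited — and they exaggerate cross-group contrast: the default
simulation yields ~36% significant intensity comparisons where a real
survey of this kind reported ~9%. Passing pipeline outputs on this
simulation therefore demonstrates that the machinery detects the encoded
structure, not that real listener groups behave this way.

## Rating analysis

Mean matrices are 24 × 8 per group; cells with no raters are an error.
Modal labels use per-participant argmax by default (within-participant
ties split the vote; excerpt-level ties return the tied set, and
cross-group "agreement" means the tied sets intersect); a mean-rating
variant is available. Intensity comparisons run Welch's t and the Wilcoxon
rank-sum with continuity correction (the normal approximation, matching R's
`wilcox.test` defaults) per cell, Hochberg-corrected **jointly across each
192-member family**. KS uses the asymptotic two-sample statistic; with
5-point discrete ratings, ties make the p-value approximate (the D
statistic is exact). The universality rule is strict: more than half of
the family's adjusted p-values must exceed α = 0.05.

## Robust regression and variance partition

IWLS with Tukey bisquare (c = 4.685), scale re-estimated each iteration as
1.4826 × MAD of residuals, OLS start, convergence when the largest
coefficient change < 1e-8 (max 50 iterations; a near-zero scale, i.e. a
(near-)perfect fit, terminates with weights as-is; if the weights would
reject more points than parameters, they are reset to 1 for that step).
Agreement with an independent reference implementation is ~1e-3 on
coefficients.

"% variance explained by a predictor" is not uniquely defined under robust
regression. The adopted definition is the **leave-one-predictor-out drop
in robust R²**: both full and reduced R² are computed by WLS under the
full model's final weights, and the difference (×100, clipped at 0) is the
predictor's unique contribution. The model F is reported with df =
(4, 20) — number of estimated parameters, and n − parameters for the
24-row design; per-predictor p-values come from the weighted information
matrix with a robust residual variance. These are documented alternatives,
not claims of equivalence to any particular published table.

Permutation importance (mean increase in the summed bisquare loss at the
fitted coefficients when one predictor column is permuted, ≥ 100 seeded
permutations) is an internal, model-agnostic cross-check on the
partition's ranking.

Calibration (200 simulated 24-row matrices per group profile, response
noise SD 0.2, familiarity drawn N(2.4, 0.4)): coefficient bias ≤ 0.02,
tonality-vs-rhythm ordering recovered in ≈ 99% of fits. The calibration
familiarity spread is wider than the survey-emulation value (~0.11, the
standard error of a ~100-rater pool mean) because with a near-constant
covariate the intercept/familiarity pair is unidentified and no estimator
could be meaningfully calibrated against it.

## Odds ratios

Point estimate as above; any non-positive variance share flags the result
undefined rather than producing infinities. CIs: percentile bootstrap over
excerpts (default 2000 replicates in the API, 500 in the pipeline config),
resampling the same excerpt rows for both groups, refitting both robust
regressions and recomputing the OR per replicate; replicates with
degenerate designs (e.g. one mode drawn, collinearity) or non-positive
shares are dropped and counted, with a warning above 20% dropped. The
percentile interval is clamped to contain the point estimate. The
two-sided p-value is the bootstrap tail probability of log-OR crossing 0
(floored at 2/n_boot), Hochberg-adjusted across the eight emotions.
Heterogeneity: Cochran Q on log-ORs weighted by inverse bootstrap
variances, χ²(k−1); pooling a common OR is only permitted at p > 0.05.
The CI/p-value machinery is a package design choice — the upstream
paradigm does not state one — so published CI bounds are out of scope.

## Pipeline determinism

A single global seed fans out to stages via
`SeedSequence(seed, spawn_key=(stage_index,))`; per-excerpt render seeds
are spawned from the audio-stage seed. All stage outputs are pure
functions of (inputs, config, seed); the manifest records the config hash
and stage seeds, and re-running a config reproduces byte-identical CSVs.

## Known limitations

* Timbre is schematic (harmonic tones, damped clicks); no meend/ornament
  modelling, so pitch-estimator performance on real sarod recordings will
  be worse than on synthetic stimuli.
* Pulse clarity and event density are simple operationalizations; only
  their orderings are meaningful, and pulse clarity needs ≳ 2 minutes of
  audio for a stable fluctuation spectrum.
* KS and Wilcoxon p-values on 5-point scales rely on asymptotic
  approximations in the presence of heavy ties.
* The bootstrap resamples excerpts (n = 24), not participants; it captures
  stimulus-sampling uncertainty, not rater-sampling uncertainty.
* Synthetic ratings are conditionally independent across cells given
  familiarity; real raters have correlated response styles.
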