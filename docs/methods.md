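# Methods

`crysig` studies how an infant's individual vocal signature interacts with the
acoustic expression of distress: discomfort cries carry a strong,
classifier-readable identity signature, while pain cries converge across
babies, so identity read from discomfort cries does not transfer to pain
cries. The package implements the full analysis chain — feature extraction,
modulation power spectra, identity classification, acoustic-space statistics,
and a Bayesian model of listener recognition — together with a synthetic cry
generator that provides ground truth for every stage.

## Synthetic cry generator

Each baby is a parameter vector ("profile"): mean fundamental `f0_mean`,
sinusoidal pitch-modulation depth and rate, two vocal-tract resonances (F1,
F2), amplitude-modulation rate and depth, and a jitter SD. Profiles are drawn
from Gaussian population distributions (means: f0 400 Hz, F1 1100 Hz, F2
3300 Hz, AM 3.5 Hz) truncated to plausible infant ranges (f0 in 250–600 Hz,
F1 850–1500 Hz, F2 2500–4200 Hz); the between-baby SDs (`IdentityDispersion`,
default f0 70 Hz, F1 120 Hz, F2 250 Hz, modulation depth 10 Hz, AM rate 1 Hz)
set the strength of the identity signal and are the main generator dial.

A cry is rendered as 2–6 expiratory bursts (Tukey envelopes, 150–400 ms
silences) of an additive harmonic stack (20 harmonics, 1/h rolloff) whose
instantaneous fundamental is `f0_mean` (with a small per-cry lognormal scatter
proportional to the profile's jitter) plus sinusoidal modulation plus smoothed
jitter. The source is shaped by two unity-peak-gain second-order resonators
in parallel (F2 de-emphasized by 0.7, the standard formant-synthesizer
topology) and mixed with resonance-filtered Gaussian noise at an RMS fraction
of 0.08; a −45 dB background noise floor is added and the waveform is
peak-normalized. Durations are Normal(6.3 s, 1.1 s) truncated at 2 s.

The pain condition applies four effects (`PainEffect`, defaults in
parentheses): the pitch-modulation depth is multiplied (×2.0); the noise
fraction rises by 0.6·`saliency_drop` (0.4) and jitter by 1.5·`saliency_drop`,
lowering measured pitch saliency — a surrogate for the nonlinear phenomena
(chaos, subharmonics) of real pain cries that reproduces their measurable
consequence, reduced tonality, not their mechanism; AM depth increases (×1.4);
and `shrinkage` (0.6) convexly pulls the identity parameters toward the
population mean before synthesis, directly realizing between-baby convergence.
The random stream is consumed identically in both conditions, so a neutral
effect yields bit-identical waveforms — the null-effect control every
downstream test relies on.

The default corpus mirrors the study design: 22 babies (sexes balanced), 4
pain sequences each, 2–19 discomfort sequences. `study_profile()` fixes the
discomfort counts so that exactly 18 babies have ≥ 6 sequences (the
leave-one-out eligibility bar), matching the 18-of-22 composition of the
reference corpus. Defaults were chosen once to land the analysis in the
reference regime (strong within-condition identity, degraded cross-condition
transfer); the synthetic corpus is cleaner than real recordings — no
background noise, no recording-session drift, no true nonlinear phenomena —
so classification accuracies run higher than real-data values, and passing
tests certify orderings and sign patterns, not real-world effect sizes.

## Acoustic features (22 PAFs)

Envelope: full-wave rectification, 4th-order Butterworth low-pass at 20 Hz,
resampled to 1 kHz (the envelope rate); summarized by mean, SD, skew,
kurtosis, entropy, RMS, max. Entropy here and for the spectrum is Shannon
entropy of the normalized distribution divided by log N, hence in [0, 1].
Spectrum: periodogram treated as a distribution over frequency; moments,
entropy, and the 25/50/75% energy quantiles (Q1–Q3) in Hz.

Pitch and saliency: 33 ms frames every 10 ms; the biased autocorrelation is
corrected by N/(N−lag), normalized at lag 0, and searched in 150–1200 Hz.
The fundamental is the *first* local maximum whose height reaches 0.9 of the
tallest in-band peak (guarding against octave-down errors), with parabolic
lag interpolation; saliency is that peak's height clipped to [0, 1]. Frames
below 5% of the maximum frame RMS are skipped; frames with saliency < 0.5 are
unvoiced and excluded from meanF0/MaxF0/MinF0/cvF0 (cvF0 = SD/mean over
voiced frames); mean saliency averages all analyzable frames.

Formants: resample to 10 kHz, single 0.97 pre-emphasis, gate to the
energetic bursts, Hamming window, order-10 LPC (autocorrelation method,
Toeplitz solve); roots with bandwidth < 500 Hz in 750–4500 Hz are resonance
candidates, the lowest two giving F1 < F2. Order 10 was selected because
higher orders admit a spurious pole near the strong low harmonics of
high-pitched voices. When fewer than two strict candidates exist the
estimate falls back to unfiltered roots with `confident=False` — infant
formant estimation from widely spaced harmonics is intrinsically fragile, and
the flag makes that visible. On synthetic cries both formants are recovered
within 15% across all babies and conditions.

The per-feature condition contrast fits `feature ~ sex * condition` with a
per-baby random intercept (statsmodels MixedLM, REML) and reports Wald z per
fixed coefficient — the same model family and test used in the reference
analysis.

## Modulation power spectrum

Narrow-band spectrogram: Gaussian analysis window with frequency-domain width
50 Hz (= 6 SD), hop 1 ms, FFT length padded to a fast size; the frequency
axis is subsampled to ~25 Hz steps (spectral-modulation Nyquist ≈ 20 cyc/kHz)
and limited to 11 kHz, then log power is normalized to a 0 dB maximum and
floored at −50 dB (subsampling precedes normalization so the stored grid
attains 0 dB exactly). The MPS is the amplitude of the 2D FFT of this log
spectrogram in 1 s (= 6 SD) Gaussian windows advanced at 50% overlap,
averaged over windows, cropped to |temporal modulation| ≤ 100 Hz and spectral
modulation ≤ 10 cyc/kHz. Because the spectrogram is self-normalized, the MPS
is exactly invariant to waveform scale. Harmonic structure at fundamental f0
appears at k/f0 cyc/kHz; as with autocorrelation, the pitch ridge is
identified as the first prominent spectral-modulation peak (≥ 0.8 of the
tallest beyond 0.5 cyc/kHz), which lands within one bin of 1/f0 for f0 in
250–600 Hz. A windowless code path (`taper="none"`) exists solely so tests
can verify equality with a brute-force 2D DFT.

For vectorized analyses each MPS is flattened on a dB scale relative to its
own peak, floored at −100 dB; difference maps are computed the same way
(average first, then dB), making them exactly antisymmetric.

Corpus-scale runs in the test-suite and acceptance script use a 2 ms
spectrogram hop and, for replicate ensembles, 8 kHz synthesis with ~2 s
cries — the temporal-modulation crop (±100 Hz) is far below either Nyquist,
so the analysis is unchanged while the cost drops several-fold. Problem
sizes per run are stated in the scripts.

## Acoustic space

PCA (scikit-learn) with a fixed sign convention (largest-magnitude loading
positive) in two scopes: a visualization basis fitted on per-baby average
discomfort MPS, and a classification basis fitted on per-cry training MPS.
Per-baby × condition averages are projected to (PC1, PC2); the shrinkage
statistic is each baby's Euclidean distance to its condition's centroid,
compared across conditions with a two-sided paired t (df = n−1; the
degenerate all-equal case returns t = 0, p = 1). The condition discriminant
is a two-class LDA (eigen solver, auto shrinkage) on the 20-PC projections,
unit-normalized and oriented so pain projects positive. Trajectory
statistics are Pearson correlations (standard t-based test) between per-baby
axis projections and PC coordinates for discomfort means, pain means, and
their differences. The reference analysis labels these correlation p-values
"Fisher's exact test"; we report the standard Pearson test and note the
naming discrepancy rather than guess at the intended variant.

A constructed-configuration control distinguishes true contraction from
rotation of signatures: when pain signatures merely move to new acoustic
dimensions (dispersion preserved), the discomfort-fitted basis shows apparent
shrinkage but the pain-fitted basis shows none; genuine contraction shows in
both bases.

## Identity classification

Eligibility: ≥ 5 discomfort cries for training (+1 when discomfort cries are
held out one at a time), ≥ 4 pain cries, ≥ 10 total. Four regimes:
within-discomfort (leave-one-out), mixed (LOO over both conditions),
cross-condition (single fit on all discomfort, tested on all pain), and
within-pain (LOO). Models: LDA (lsqr solver, ridge 0.01), QDA (eigen solver,
shrinkage 0.1 — keeps 4-sample classes well-posed), random forest (100
trees, seeded). Feature spaces: 20 MPS principal components, the 22 PAFs, or
the 10-feature spectral subset; PAF spaces are standardized on the training
fold, the MPS space is not (its dB values share a scale).

The 20-PC projection is refitted on every training fold to avoid leakage.
For LOO this is done exactly and cheaply through the Gram matrix: with n
samples in d ≫ n dimensions, each fold's centered PCA follows from the
eigendecomposition of the double-centered (n−1)×(n−1) Gram submatrix, and the
held-out cry is projected using the corresponding row of the full Gram
matrix — numerically identical to a per-fold PCA refit (validated to 1e−14)
but touching the d-dimensional data only once, which also makes LOO runs
deterministic.

Reports follow the posterior-confusion convention: rows are per-true-baby
mean posterior vectors (each summing to 1), the headline number is the mean
diagonal posterior ± 2SE across babies, and hard counts use the
maximum-posterior rule (ties, which are recorded, break toward the lowest
label). Regime comparisons use the exact two-sided Fisher test on
correct/total counts; comparison against chance (1/n babies) uses the exact
upper-tail binomial test.

## Listener experiment

The design: two training sessions of 5 discomfort cries from an assigned
"familiar" baby, then 20 pain-cry test trials — 4 familiar, 16 from four
unknown babies (2 boys, 2 girls) — answered yes/no; chance is 4/20 = 20%.
The simulated cohort has 100 subjects, 25 per sex × parentality cell,
familiar babies drawn from the 9-baby training pool; responses are Bernoulli
in a logit model with target hit and false-alarm rates, group offsets, and
subject (intercept + status) and stimulus-baby (intercept + status +
parentality) random effects (default SDs 0.4/0.3 and 0.4/0.3/0.15 on the
logit scale — moderate listener heterogeneity, chosen so marginal rates stay
within ~2 points of the targets).

The analysis model is the Bernoulli-logit mixed model
`response ~ status * parentality * sex + (status + parentality | baby) +
(status | subject)` with ±1/2 sum-to-zero covariate coding, Normal(0, 1)
priors on effect coefficients, and Normal(logit(0.20), 1) on the intercept —
the chance-level prior is placed on the logit scale because that is where the
linear model lives. It is fitted by a Pólya-Gamma-augmented Gibbs sampler:
PG(1, ψ) auxiliaries (truncated sum-of-gammas representation, 128 terms plus
an analytic tail-mean correction; the sampler's mean matches tanh(c/2)/(2c)
to 2%) make every coefficient and random-effect update a conjugate Gaussian
draw; random-effect variances are per-component Inverse-Gamma(2, 0.5)
(weakly informative, prior mean 0.5) with conjugate updates. Defaults mirror
the reference analysis (2 chains × 3000 iterations, 1000 warmup); a fast
profile (2 × 600, 200 warmup) serves quick runs. Split-Rhat on the fixed
effects (arviz) flags non-convergence explicitly.

Posterior quantities are reported on the probability scale as marginal rates
over the observed trials (posterior-predictive means with the fitted random
effects), summarized by medians and 95% credible intervals; contrasts
(familiar vs unknown, sex, parentality) are flagged "credible" when the
interval excludes zero. An independent cross-check in the test suite
compares the status effect against statsmodels' variational Bayes logistic
mixed model.

The machine listener replays the human protocol: per familiar baby, a
two-class LDA (on 20 training-fitted MPS PCs, balanced class priors — the
listener has no base-rate information) separates 10 of that baby's discomfort
cries from the other babies' discomfort cries and is applied to the 20 pain
test cries. On the default synthetic corpus its hit rate is low: parameter-
level shrinkage moves a baby's pain cries toward the population centroid,
i.e. toward where "unknown" babies live, which is exactly the identity loss
the generator encodes — more severe than in real recordings, where human and
machine listeners still recognize the familiar baby about half the time.

## Numerical and scope notes

- All randomness flows through numpy Generators seeded from explicit integer
  seeds; corpus generation, classification, and MCMC are reproducible
  end-to-end.
- Synthesis guards: f0 must stay below a quarter of the sample rate;
  harmonics above 0.95 × Nyquist are dropped; silence cannot be normalized.
- MPS persistence is provided as `.npz` (axes + matrix + provenance); no
  plotting is shipped — maps and matrices are returned as pandas/numpy
  objects for the caller to render.
- Stereo audio, physiological vocal-fold modelling, explicit
  chaos/biphonation synthesis, and reproduction of supplementary-table
  numbers are out of scope.
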