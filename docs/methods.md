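# Methods

This note documents the models, defaults and numerical choices behind
`catdecode`, and what the synthetic benchmark does and does not show
about real EEG.

## Decoding pipeline

Per participant, time point and category pair: raw trials of each
category are randomly partitioned into `n_bins = 4` bins of
approximately equal size (sizes differ by at most one) and averaged
into pseudo-trials. A binary linear C-SVC (hinge loss, `C = 1`, no
kernel, no feature standardization) is trained on 3 pseudo-trials per
class; the held-out pseudo-trial pair is tested, giving a per-fold
accuracy in {0, 50, 100}%. The held-out bin rotates over all 4 folds
(a `full_rotation=False` flag restricts testing to a single held-out
fold), and the whole procedure repeats `n_reps = 100` times with a
fresh random partition per repetition; one partition per repetition and
category is shared across all time points. Averaged accuracies
therefore lie on a lattice of 100/(2·4·n_reps). Accuracy matrices are
symmetric (each pair computed once, stored twice) with NaN diagonals.

The SVM is solved in the dual by a two-variable SMO working-set scheme
(the libsvm algorithm family), JIT-compiled and batched over all
(time × pair × fold × repetition) problems of a participant at once;
KKT tolerance 1e-3, decision values agree with libsvm to <0.05 with
>99% prediction agreement on random fixtures (tested). An exactly tied
decision value (degenerate training set) counts as accuracy 1/2 — the
expectation of an arbitrary prediction — keeping results deterministic.
Decision values are otherwise unused; only hard-label accuracy enters
the results.

Temporal conventions everywhere: selections are half-open `[t0, t1)` in
ms; bin-downsampling averages complete bins, labels them by bin center,
and drops a trailing partial bin, so the global mean over complete bins
is conserved. Temporal generalization expects ~50 Hz input (20 ms bins)
and warns above 100 Hz. The searchlight uses Euclidean distance on the
3-D montage, includes the center channel in its own neighbourhood, and
breaks distance ties by channel index; defaults are k = 5 for
infant-tagged montages and k = 10 otherwise, with 200 ms output bins.

## Time–frequency decomposition

Complex Morlet wavelets of *fixed duration* 2,600 ms at every frequency
(30 log-spaced bins, 2–30 Hz): the Gaussian envelope SD is length/6
(support trimmed at ±3 SD), so the cycle count grows with frequency
and spectral resolution is constant (~0.37 Hz SD). Wavelets are
L1-normalized on the envelope — unit gain for a complex exponential at
the center frequency; a cosine of amplitude A yields magnitude A/2.
Per trial/channel/frequency, power is the coefficient magnitude |z| by
default (`output="power"` switches to |z|²), baselined as
10·log10(P/mean P over −300..−100 ms) per trial, then averaged in
20 ms bins (output rate 50 Hz). Under this rule a doubling of a tone's
amplitude adds +3.01 dB in magnitude mode and +6.02 dB in squared
mode (both tested as closed forms). Time points within half the
wavelet support of an epoch edge are flagged (`edge_mask`), not
removed: with the study's −500..+1000 ms epochs *every* sample is
edge-flagged, which is inherent to a 2.6 s wavelet and matters when
interpreting absolute power near the edges. A related, physically real
effect (exercised in the tests): the wavelet smears signal into the
pre-stimulus baseline window, so per-trial dB baselining partially
cancels amplitude contrasts when the response is strong relative to
baseline noise.

## Synthetic cohort generator

The generator produces the data structure the analyses assume, with
every parameter explicit:

- **Category geometry.** The target RDM (K×K, symmetric, zero
  diagonal) is embedded by classical MDS (negative eigenvalues
  clipped) and rotated into channel space by a fixed orthonormal basis
  that depends only on the montage size — category means are therefore
  identical across seeds, and realized pairwise pattern distances are
  proportional to the target (exactly, for Euclidean-realizable
  targets). The default geometry is equidistant categories.
- **Response envelope.** env(x) = (x/x_p)^a · exp(a(1−x/x_p)) with
  x = t − onset, x_p = peak − onset and a = x_p/decay: zero before
  onset, unimodal with its maximum exactly at `signal_peak`
  (defaults onset 250 ms, peak 400 ms, decay 150 ms). For a < 1 the
  rise is steep at onset, which keeps onset recovery well-posed.
- **snr** anchors the *Mahalanobis* amplitude of the category contrast:
  patterns are scaled so the mean pairwise distance between category
  means, whitened by the noise covariance, equals `snr` at the envelope
  peak. This makes snr the single-trial discriminant amplitude,
  invariant to the spatial correlation of the noise — a per-channel-RMS
  anchoring would let a linear classifier exploit low-variance noise
  directions and saturate at nominally modest snr. snr = 0 removes the
  signal; snr = inf removes the noise.
- **Noise.** Gaussian, unit SD per channel, spatially correlated by an
  exponential kernel over montage distances (parameter = correlation at
  the mean nearest-neighbour spacing, default 0.5) and temporally AR(1)
  with a 50 ms time constant. Temporal correlation matters: white noise
  would hand 20 ms bin-averaging an unrealistic √10 SNR gain.
- **Between-participant variability** (default 0.2): latency shifts of
  SD 0.2·50 ms applied to onset and peak, and topography perturbations
  drawn with the noise covariance, scaled to 0.2 of the patterns'
  whitened RMS — perturbing geometry without inflating the whitened
  contrast.
- **Oscillatory carrier.** With `carrier_freq` set, a per-channel
  offset first makes the amplitude patterns nonnegative (pairwise
  distances unchanged), then the envelope amplitude-modulates a cosine
  with a fresh uniform phase per trial. Category information then lives
  in single-trial oscillatory power at the carrier frequency and is
  largely invisible to broadband trial averaging. Carriers must stay in
  the 2–30 Hz analysis band for two-group spectral designs.
- **Stimulus images**: white noise band-pass filtered into per-category
  spatial-frequency bands (Butterworth, below the image Nyquist in
  cpd), scaled to a target luminance SD and clipped to [0, 1]; 32 per
  category by default.

Reproducibility: a dataset is bit-identical under its seed; noise,
jitter and phases derive from per-participant substreams of the seed.

**Latency recovery.** `fit_envelope_latency` estimates injected
onset/peak from a group accuracy curve by mapping accuracy through the
inverse normal CDF (undoing the ceiling compression) and least-squares
fitting b·env over a grid of onsets, rise times and gamma shape
exponents. The free shape exponent is the load-bearing choice: a power
of a gamma envelope is again a gamma envelope with the same onset and
peak, so the estimates are robust to the nonlinear mapping from signal
amplitude to accuracy. Significance-based onset readouts
(`peak_onset_offset` on a cluster mask) are systematically late at
realistic snr — at snr = 1 a single bin's between-participant SD is
~9 accuracy points, so the curve must climb well above chance before
the cluster threshold is reached; both readouts are provided, the
curve fit for parameter recovery, the cluster readout for descriptive
latency tables.

## Group inference

Sign-permutation tests flip each participant's map by ±1
(`n_perm = 10,000` by default); the identity permutation is part of the
null set, so p ≥ 1/(n_perm+1). Two-tailed tests use |group mean| with a
single null. For cluster correction, *every* permutation's map is
converted to p values against the same stack (rank-based), thresholded
at the cluster-defining alpha (.005), and its largest suprathreshold
cluster recorded; an observed cluster is significant when its size
exceeds the 95th percentile of that null max-size distribution, and its
corrected p is the proportion of null maxima at least as large. 1-D
maps use run contiguity; 2-D maps edge adjacency (4-neighbourhood,
8 optional). NaN cells are excluded. Point-wise families (searchlight
channels, per-model correlations) route through Benjamini–Hochberg FDR
instead. Bootstrap latency CIs are percentile intervals over 1,000
participant resamples; estimators may be undefined on a resample (no
significant cluster) — such resamples are recorded and reported as a
missing fraction rather than silently dropped. Onset/offset bootstraps
that re-run the cluster inference per resample use a reduced
permutation count at the caller's discretion (the estimator is a plain
callable), trading exactness for tractability.

## RSA conventions

All comparisons operate on the 6 lower-triangle entries (K = 4) with
average ranks on ties. A rank-constant vector makes Spearman undefined:
the whole time point is recorded as NaN and excluded from statistics —
never pairwise-deleted, for determinism. The peak-window and
frequency-template aggregations apply the ≥50% mean-accuracy inclusion
criterion per participant (and per cell); participants with no
qualifying time point are excluded and listed. Partial rank correlation
regresses rank-transformed vectors on the rank-transformed covariate
(with intercept) and correlates residuals; an exactly zero residual
(participant ≡ covariate) is defined as 0; exact rank orthogonality on
6 entries requires tied ranks, which the tests exploit. Variance
partitioning fits OLS with intercept on the two group-*mean* RDMs:
total R² per group, unique = R²(both) − R²(other), shared = total −
unique (identical for both groups up to 1e-10, tested). Noise ceilings
are the mean Spearman of each participant's RDM with the grand mean
(upper) and the leave-one-out mean (lower). On 6-entry rank vectors
both bounds converge onto the true-model score as the cohort grows, so
the bracketing property (lower ≤ true-model R ≤ upper) has slack only
at high signal-to-noise with modest cohorts — the property test states
and uses that regime.

## Problem sizes used in the test and calibration suite

Chosen so the full suite and the calibration script each run in minutes
on one CPU: chance calibration uses 20 participants × 100 repetitions
(× 10 seeds in the calibration script); family-wise error, 200 null
datasets of 20×60 Gaussian curves at 1,000 permutations; bootstrap
coverage, 200 groups × 1,000 resamples; latency/geometry recovery,
3 seeds × 20 participants at snr = 1; the two-cohort frequency-shift
study, 10 participants per group, 16 channels at 250 Hz, 30 trials per
category, a reduced 15-bin frequency grid and 20 repetitions. The
Monte-Carlo permutation p is checked against exhaustive 2^10
enumeration on 20 fixtures.

## Limitations

No biophysical forward model (no dipoles or leadfields), no ocular or
muscle artifacts, no preprocessing stage — the generator produces
*clean* epoched data, so passing tests demonstrate correctness and
calibration of the analysis stack, not robustness to artifacts or
preprocessing choices. Noise is Gaussian AR(1), not 1/f, and trial
counts are balanced across categories by default (per-category counts
are configurable). The Gabor pyramid is a fixed filter bank (6
log-spaced frequencies, 8 orientations, quadrature magnitude, grid
positions scaling with wavelength), not a fitted model; network
activations enter only through the matrix adapter. Raw vendor EEG
formats are not read — data enter through the HDF5 epoch container or
in memory.
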