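# Methods

## Task and behavior model

A session alternates encoding blocks (12 fresh images at a 2.5 s onset
asynchrony) with recognition blocks in which those images (OLD) are
pseudo-randomly interleaved with as many unseen images (NEW), under the
constraint that the same novelty label never repeats more than three times
in a row (enforced by rejection sampling of the interleave; the constraint
is checked property-style over hundreds of seeds).  Seven block pairs
consume 168 distinct images.  Blocks are separated by a 60 s gap standing in
for the distractor video; both the gap and the onset asynchrony are
configurable since their exact values do not affect any downstream
statistic beyond total recording length.

Behavior: correctness is Bernoulli with rate 0.8953 (the default session
accuracy), and response times are lognormal with per-condition mean/SD
(0.7191/0.1624 s OLD, 0.7650/0.1912 s NEW), rejection-sampled below the
1.5 s response deadline.  Drawing correctness directly (rather than deriving
it from truncated RTs) makes the configured accuracy the net observed rate,
which is the contract the generator's consumers rely on.  Incorrect trials
flip the sign of the condition-differential source activity — a wrong
novelty judgment is modeled as the wrong internal evidence — which gives
the correct-trials-only filter operational meaning in simulations.

## Forward model

The head is a single homogeneous sphere (radius 90 mm, conductivity
0.33 S/m).  Scalp potentials of a current dipole are computed from the
Legendre expansion of the infinite-medium potential plus the interior
harmonic correction enforcing zero radial current at the surface:

    V(R, γ) = K/R² [ p_r Σₙ (2n+1) f^(n-1) Pₙ(cos γ)
                     + p_t cos φ Σₙ (2n+1)/n f^(n-1) sin γ Pₙ'(cos γ) ]

with f = b/R the source eccentricity and K = 10³/(4πσ) giving microvolts
per nA·m at millimetre distances.  The series is truncated when the term
magnitude falls below 1e-14 (≤ 300 terms; eccentricities above 0.95 are
rejected).  The radial sum has an independent closed form via the Legendre
generating function, used as a test oracle.  Depth contacts are embedded in
the volume and use the infinite-medium dipole potential with a 3 mm
source–contact distance clamp; its 1/r² falloff is verified by log-log
regression.  Both models are linear in the dipole moment and superpose.

Sources default to two deep dipoles (30–50 % of the head radius) with a
condition-independent Hann-pulse response at 100–450 ms and an OLD−NEW
differential Hann pulse confined to a configurable effect window (default
300–500 ms, amplitudes 30 and 20 nA·m).

## Noise and SNR

Sensor noise is white Gaussian filtered to a 1/f amplitude spectrum and
mixed through a random spatial matrix per modality, so channels share
correlated low-frequency structure.  SNR is defined per modality as the RMS
of the trial-averaged evoked response over the RMS of noise within the
effect window, averaged over channels.  Defaults: scalp 0.25, depth 2.5.
The ten-fold ratio encodes the physical premise of simultaneous recordings:
depth contacts sit millimetres from the generators (near field), scalp
sensors centimetres away behind a volume conductor, and single-trial scalp
ERP SNR is well below one.  A scalar `snr` argument therefore sets the
scalp level and scales depth by ten; both levels can be set explicitly.
Realized per-channel SNR is recorded in the ground-truth object.

## Preprocessing

Resampling is polyphase with built-in anti-aliasing (downsampling only, to
256 Hz by default).  The 0.5–45 Hz band-pass is a 4th-order Butterworth
applied forward–backward (zero phase); only the band edges are contractual,
the realization is a package choice.  Scalp data are re-referenced to the
common average; SEEG to the bipolar montage (deeper contact minus
shallower, i.e. lower contact index minus higher).  Epochs span −0.2 to
+1.0 s around recognition onsets with pre-stimulus baseline subtraction,
keeping correct trials only.  Artifact rejection replaces manual inspection
with a deterministic rule: channels with variance below 1e-12 are excluded
as flat, and trials whose peak |z| (z computed across trials per channel
and sample) exceeds 6 are dropped; every removal is listed with its
statistic in the rejection report.

## LCMV virtual SEEG

The source grid is a cubic 5 mm lattice clipped to a brain radius (default
78 mm).  The data covariance is estimated over the whole epoch (the window
is configurable; per-condition covariances are not used) from concatenated
samples, with diagonal loading C ← (1−λ)C + λ·mean(diag C)·I, λ = 0.05 by
default — necessary because common-average scalp data are rank-deficient.
At each selected grid point the max-power scalar orientation is the
eigenvector of the smallest informative eigenvalue of LᵀC⁻¹L (null-space
orientations of a rank-deficient lead field are ignored), and the filter is
w = C⁻¹l/(lᵀC⁻¹l), which satisfies the unit-gain constraint by
construction and equals the constrained quadratic-programming solution
(verified against an SLSQP oracle).  Bipolar midpoints map to the nearest
grid point, ties broken toward the lowest grid index.  When the scalp data
are common-average referenced, the lead field columns are re-referenced the
same way before filter computation.

## SOBI

Epochs are concatenated along time, whitened at lag zero (full rank — no
dimensionality reduction, so component count equals channel count; an
epsilon can regularize the whitener for rank-deficient data), and the
whitened lagged covariances (symmetrized, lags 1–50 samples at 256 Hz by
default) are jointly diagonalized by Jacobi sweeps; each Givens angle is the
closed-form minimizer of the summed squared off-diagonals for its index
pair, and sweeps terminate when the largest rotation sine falls below 1e-9.
Components are ordered by descending back-projected variance with the
maximum-magnitude mixing loading made positive, making the decomposition
reproducible.

## Decoding

Features at each timepoint are the instantaneous multichannel sample
vector.  Folds are stratified and seeded (stratification is required so
ROC-AUC is defined in every fold).  Standardization (per-channel z-scoring)
is fitted on each training fold and applied unchanged to its test fold;
constant channels are dropped with a warning.  The classifier minimizes the
L2-penalized logistic loss (penalty on weights only, default strength 1.0)
with scipy's L-BFGS-B; the regularization strength is exposed because the
affine-invariance property — decoding scores unchanged under any invertible
channel mixing, which is why component-space scores match sensor-space
scores — holds exactly only for the unpenalized maximum-likelihood fit.
ROC-AUC uses the Mann–Whitney midrank formula (ties count ½).  Pooling
concatenates channels after scaling each space to unit mean channel
variance, so microvolt-scale differences between modalities do not dominate
distance-based diagnostics (the in-fold standardization already equalizes
channels for the classifier; the scaling is belt and braces, recorded in
the config).  Regional analysis subsets channels by a label table over a
declared vocabulary (Hc, ACC, ITG, F, Ins-Op, P, T, O); in simulations,
labels derive from proximity of bipolar midpoints to the true sources.

## Cluster inference

Fold scores are tested against chance (0.5) with per-timepoint one-sample
*t* statistics, thresholded at the one-sided t quantile (forming p = 0.05
across folds; one-sided "greater" matches the scientific question).
Contiguous suprathreshold runs form clusters with mass = summed *t*; the
null is the maximal cluster mass under per-fold sign flips of the
deviations.  All 2^folds flips are enumerated exactly when they fit in the
permutation budget (default 1024), otherwise flips are sampled and
p = (1 + #{null ≥ observed})/(1 + n_perm), which keeps p strictly positive.
The observed statistic goes through the identical vectorized computation as
the null (identity flip row), so exactness holds even in numerically
degenerate columns.  Cross-validation folds share training data and are not
independent samples; the test treats them as exchangeable — standard
practice for fold-score inference — and every report carries this caveat.

## Activation patterns

For each fold and timepoint the pattern a = Σₓw/(wᵀΣₓw) is computed from
the standardized training data covariance; folds are sign-aligned to the
first fold before averaging (decoder weights are sign-arbitrary across
folds only up to the labels, but alignment stabilizes averages at
near-chance timepoints).  Timelines average patterns in 200 ms bins, with
either the signed mean or the mean magnitude; the last partial bin is
included, and the signed-mean display sign is fixed so the strongest
channel at the peak bin is positive.  Patterns, unlike weights, do not
invert on noise-cancelling channels — verified by a distractor-channel
regression test.

## Problem sizes

The test suite and the acceptance script run scaled sessions — 3–4 block
pairs, 5 s inter-block gaps, 16 scalp channels and 4 shafts × 8 contacts,
decoding restricted to a window spanning the effect window — which preserve
every contract of the full-size session (7 pairs, 60 s gaps, 32+ scalp
channels, 10+ shafts) while keeping a complete multi-space study to a few
seconds per simulated subject.  The multi-simulation headline study uses 20
seeds in the test suite and 10 in the acceptance script.

## Known limitations

* The conductor models are analytic (homogeneous sphere / infinite medium);
  no realistic cortical geometry, skull layers, or BEM/FEM conduction, so
  absolute microvolt scales are only indicative.  The template-vs-patient
  anatomy mismatch of real studies can be emulated with a lead-field
  perturbation, not with true anatomical error.
* Noise is stationary 1/f with fixed spatial mixing; no ocular/EMG
  artifacts, line noise, or electrode drift — artifact rejection is
  exercised by construction, not by realistic contamination.
* Encoding-phase neural activity is not modeled; only recognition trials
  carry evoked responses.
* Fold scores are treated as exchangeable in the permutation test (see
  above); the type-I calibration reported by the acceptance script is for
  simulated independent fold scores, not for the dependence structure CV
  induces.
* Passing tests demonstrate internal consistency and correct implementation
  of each method on data matching the generator's assumptions; they do not
  certify performance on clinical recordings.
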