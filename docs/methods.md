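# Methods

This note documents the models, estimators and numerical choices behind
gigglekit, in the order data flows through the package.

## The scientific setting

Spotted hyenas emit "giggle" calls in bouts of short (~70 ms), high-pitched,
harmonically structured notes, mainly during food competition. Analyses of
captive-colony recordings have shown that giggle notes carry information
about the emitter: individual identity (classifiable far above chance from
13 acoustic parameters), age (the mean fundamental falls by roughly
14.7 Hz/yr), and dominance status (subordinate animals vary the spectrum
mean of their notes more from note to note than dominants, a difference of
about +0.082 in the cross-note coefficient of variation). Because such
recordings are not redistributable, gigglekit pairs the analysis chain with
a forward model that synthesises giggle-like bouts with those effects
injected at known strength, so every stage of the chain can be validated
end to end.

## Synthetic bout generator (`gigglekit.synth`)

Each note is a harmonic stack: components k = 1..8 at k times the
fundamental, with power falling at a per-note spectral tilt (default
-6 dB/octave, giving a spectrum-mean-to-fundamental ratio of ~1.78), a Hann
amplitude envelope, and white noise added at bout level at a configurable
SNR (default 25 dB re the note RMS). The fundamental follows a rise-fall
parabola f(u) = f_c (1 + c[(1 - u^2) - 2/3]), u in [-1, 1], whose depth c
(mean 0.52, SD 0.2, clipped to [0.05, 0.9]) sets the within-note CV of F0.

Population structure enters through per-animal latent parameters drawn once
at population creation:

* target F0 = 547 - 14.7 (age - mean age) + N(0, 100) Hz, plus per-note
  jitter N(0, 75) Hz — together with the age spread of the default colony
  this reproduces an overall per-note SD of ~146 Hz;
* spectral tilt offset N(0, 1.5) dB/oct and duration offset N(0, 8) ms —
  the remaining components of the individual signature;
* a cross-note spectral-envelope multiplier, lognormal on the ideal
  centroid ratio, whose dispersion is solved per animal so that the
  cross-note CV of the spectrum mean equals 0.31 for dominants and
  0.31 + 0.082 for subordinates (totals chosen to average to the observed
  ~0.35). The dispersion is calibrated by quadrature against the *clipped*
  multiplier distribution, using each animal's actually invertible tilt
  range, so the injected CV survives clipping by construction.

Age affects only the mean fundamental; dominance affects only the CVMeanS
target. All other structure is individual or note-level noise.

The default population is a built-in reference colony: 17 animals (7 males,
10 females), ages 2-20 years, housed in 7 dominant/subordinate dyads plus
one triad, with per-animal analysed-note counts (20-98, total 695) matching
the study population the defaults emulate.

Numerical choices worth knowing:

* **Mean-preserving truncation.** Durations (min 20 ms) and notes-per-bout
  (min 2) are drawn from truncated normals whose location is re-solved so
  the *post-truncation* mean equals the configured mean (69 ms, 7.1). Naive
  resampling above the floor would inflate the notes-per-bout mean to ~7.9.
* **Window-smearing compensation.** A short-time tracker effectively
  weights the instantaneous frequency by the amplitude envelope inside its
  analysis window, so edge frames of a Hann-enveloped note report
  frequencies pulled toward the louder interior; the tracked mean of the
  parabolic contour is biased upward by a factor (1 + cB). B is computed by
  quadrature from the envelope/window geometry (with an effective envelope
  exponent of 1.6, between amplitude and power weighting, matching the
  ridge estimator's behaviour on this forward model), and the synthesised
  contour is centred on f_target / (1 + cB). Residual bias of the tracked
  per-note mean is below ~3 Hz.
* Per-note realized mean F0 is clipped to [120, 960] Hz and the contour
  depth capped so the contour peak stays under the tracker's 1 kHz prior
  ceiling; both clips bind only in the far tails.
* RNG substreams are derived from the master seed by (animal, bout)
  counters, so datasets are byte-identical under a fixed seed and animal i
  is unchanged when other animals are regenerated.

`simulate_note_features` is a statistical twin of the acoustic model: it
draws the 13 features directly from the same latent structure (identical
F0/duration/envelope draws; the purely spectral shape features generated
from plausible conditional distributions). It exists for Monte-Carlo
studies — permutation-test calibration, coverage and power — where
synthesising and re-tracking thousands of datasets would add hours of
compute and no information about the statistics under test.

What the generator does **not** emulate: vocal-tract resonances (formants),
whines and transitional sounds, any ordering structure of notes within a
bout (notes are exchangeable draws), and reverberant/overlapping recording
conditions. Passing tests therefore validate the estimators and the
statistical machinery under a clean harmonic model, not robustness to real
field recordings.

## Fundamental-frequency tracker (`gigglekit.pitch`)

Frames are taken every 1 ms with Gaussian windows of 3.2 ms time-SD
(50 Hz frequency-SD), zero-padded FFTs of length 4096. Two estimators
propose candidates per frame:

* **Cepstrum**: peaks of the Fourier transform of the frame's log spectrum
  in the quefrency band for F0 in [50, 1000] Hz; likelihoods proportional
  to peak heights, scaled by a confidence that compares the top peak with
  the band's SD. Two refinements matter in practice: the Gaussian window is
  offset-subtracted so truncation adds no sidelobe ripple for the log
  scale to magnify, and each frame's log spectrum is clamped to a 50 dB
  dynamic range for the same reason. Cepstral peaks ride a decaying
  envelope that displaces them toward smaller quefrency; the local envelope
  decay is estimated and the first-order shift (lambda q^2 / 4 pi^2)
  undone, which matters for near-sinusoidal frames.
* **Peak spacing**: major spectral peaks (>= 10 dB above the band median,
  band limited to 10 kHz) with a peak prepended at 0 Hz; successive
  spacings are clustered (10% tolerance) and each cluster becomes a
  candidate weighted by how often its spacing recurs, damped when the frame
  offers few peaks. The headline candidate is the smallest in-band spacing.

Fusion: both candidate sets are expanded into densities on a 1 Hz grid
(Gaussian bumps of 15 Hz SD plus a uniform floor carrying the remaining
mass) and multiplied with the prior — uniform on (0, 1 kHz] until three
frames have been accepted, then 0.9 N(prediction, 50 Hz) + 0.1 uniform,
where the prediction extrapolates the line through the last three accepted
estimates. The heavy uniform tail lets the track recover from octave locks.
The guess is the posterior mode; its probability is the posterior mass
within +/-50 Hz of the mode; frames below probability 0.5, or where neither
estimator clears a minimal confidence, are dismissed as lacking clear
periodicity. An all-dismissed signal yields an empty track with a warning.

On clean 8-harmonic stacks at 30 dB SNR the tracker achieves frame RMSE of
a few Hz with no octave errors; white noise is dismissed on essentially all
frames.

## Note features and profiles (`gigglekit.features`)

Thirteen parameters per note: MeanF, MaxF, MinF, CVF (sample SD/mean) from
accepted pitch frames; Q1, Q2, Q3 (smallest frequency whose cumulative
energy reaches 1/4, 1/2, 3/4), MeanS, SDS, Skew, Kurt (standardised third
and fourth moments of the normalised spectrum; kurtosis non-excess, so a
Gaussian scores 3), Ent (-sum p log2 p / log2 N, in [0, 1]) from a Welch
average periodogram (23.2 ms Hann windows, 50% overlap, band-limited to
15 kHz, the recording chain's response); and Dur, the segment length.
Notes with fewer than two accepted pitch frames are dropped and logged.
Per animal, the cross-note mean and SD of MeanF and MeanS give GrandMeanF,
SDMeanF, CVMeanF, GrandMeanS, SDMeanS, CVMeanS (one row per animal, which
is also what removes pseudo-replication from the regressions).

## Discriminant pipeline (`gigglekit.discriminant`)

Features are z-scored (training statistics only, inside every CV split).
The discriminant functions are the eigenvectors of within^-1 between
(generalised symmetric eigenproblem, solved with a small ridge if the
within-scatter is singular), scaled to unit within-class variance.
Sequential Wilks'-lambda tests with Bartlett's chi-square approximation
determine the number of significant functions (alpha = 0.05);
classification is nearest class centroid in the significant subspace (all
functions when none is significant; equidistant ties break to the lowest
class index).

Cross-validation follows the balanced design: per iteration, each animal
contributes 19 random training notes and 1 held-out test note; percent
correct is averaged over 100 iterations with its SE taken across
iterations, and pooled guess-vs-truth counts form the confusion matrix.
With a uniform truth marginal, percent correct equals 100 x the mean
diagonal of p(guess|truth), and the mutual information between guesses and
truth is computed from the joint; the Miller-Madow correction (subtracting
(#nonzero cells - #nonzero guess rows - k + 1)/(2N ln 2)) is applied by
default when fewer than 50 tests per class are available — an approximate
but standard small-sample bias control. Dividing MI by the mean note
duration gives an information rate in bits/s.

## Permutation DFA (`gigglekit.pdfa`)

Group effects (sex, dominance, treatment) are tested against the nested
individual effect by permuting group identity at the *individual* level
(group sizes preserved; all of an animal's notes inherit its permuted
label; dyad information is destroyed along with identity). The observed
statistic is the balanced cross-validated percent correct; p = (1 + #{null
>= observed}) / (1 + n_perm), the add-one Monte-Carlo convention that never
returns exactly zero.

Defaults: 1000 permutations; 100 CV iterations for the observed statistic
and 10 inside each permutation (full-depth CV inside every permutation is
computationally wasteful and changes little). For Type-I **calibration**
studies the observed statistic must be exchangeable with the null draws, so
matched iteration counts are used there — with unmatched counts the test is
conservative by construction (the observed statistic has less CV-sampling
noise than the null draws). Calibration on 200 null populations puts the
rejection rate at alpha = 0.05 inside its binomial band while the observed
group classification still averages ~58% against a 50% chance level — the
signature of individual structure leaking into arbitrary groupings, which
is exactly what the permutation corrects for.

## Covariate statistics (`gigglekit.regression`)

Per-animal profile responses are regressed on age (years), sex (male = 1),
dominance (subordinate = 1) and treatment. Treatment supports three
codings — four raw groups; gonadectomised animals folded into the hormone
groups by sex; control vs treated — mirroring groupings that trade
resolution for power at n = 17. Least squares via statsmodels OLS; the
robust variant is IRLS with Tukey bisquare weights (c = 4.685). ANCOVA
age x factor interactions are type-II F-tests of the separate-slopes term,
run only where age is a significant main effect, Bonferroni-adjusted across
the factors tested. Model p-values across the six profile responses are
adjusted with Benjamini-Hochberg step-up FDR. The dyad test pairs each
housing group's dominant with its (triad-averaged) subordinate and runs a
paired t on subordinate - dominant differences, so the injected dominance
effect appears as a positive mean difference with df = pairs - 1 = 7 in the
default colony.

Small-sample caveat: with ~40 notes per animal the sample CV of MeanS
underestimates the generator's asymptotic CV by a few percent (SD-estimator
bias on a skewed distribution), so recovered dominance differences sit
slightly below the injected 0.082 at study-sized datasets; recovery is
unbiased as notes per animal grow.

## Problem sizes

The shipped test-suite and acceptance-script runs use: full audio datasets
of 17 animals x 40 notes; 100-note tracker accuracy studies; 100-120
replicate populations for coverage/recovery; 200 null populations x 200
permutations (10 matched CV iterations) for pDFA calibration. These sizes
give Monte-Carlo standard errors comfortably inside the asserted bands
while keeping a full run in minutes on one core.
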