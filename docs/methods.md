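# Methods

## Problem and model

The package decodes, from multichannel EEG, whether a 1.5 s segment of
signal comes from *focused anticipation of a visual cue* (the window
immediately before the cue onset) or from the *reaction to that cue* (the
window starting at the onset).  The setting it emulates is a low-density
consumer headset (14 channels, 128 Hz) worn during hour-long monitoring
sessions in which cues arrive at random intervals; each cue yields exactly
one trial of each class, so classes are balanced by construction and
chance accuracy is 50%.

The decoding model is filter-bank CSP with log-bandpower features:

1. **Filter bank.** The continuous recording is split into ten bands —
   delta (1–4 Hz), theta (4–8), alpha (8–12), four beta strips (12–16,
   16–20, 20–24, 24–28), two low-gamma strips (32–36, 36–40) and the broad
   sensorimotor 8–30 Hz band.  Each band filter is a 466-tap Kaiser-window
   FIR band-pass applied forward and backward in time
   (`y = flip(h * flip(h * x))`), giving an effective magnitude response
   |H(ω)|² and exactly zero phase.  Filtering precedes epoching: the filter
   is more than twice as long as a 192-sample epoch, so per-epoch filtering
   would be pure edge transient.
2. **Spatial filtering.** Per band, Common Spatial Patterns: per-trial
   covariances X Xᵀ are trace-normalized, averaged within class, and the
   projection W solves C₁w = λ(C₁+C₂)w.  Eigenvalues lie in [0, 1]
   (fraction of composite variance explained by the pre-event class) and W
   whitens C₁+C₂.  Either all N components are kept per band (default,
   giving K = 10 × 14 = 140 features) or 3 pairs from the spectrum ends
   (K = 60); both conventions appear in the study this package follows —
   its feature count implies all components while its spatial-filtering
   description prescribes 3 pairs — so both are implemented behind
   `csp_components`.
3. **Features.** Natural log of the per-component sample variance
   (band-limited EEG is zero-mean, so variance is band power; the log
   symmetrizes the distribution).  Columns are standardized with training
   statistics.
4. **Feature selection.** Features are ranked by mutual information with
   the class label, estimated by the Kraskov-style k-nearest-neighbor
   entropy estimator adapted to a discrete target (k = 3); the top-N
   columns are kept, N tuned jointly with the classifier (grid
   {3, 6, 9, 12, 15}, preliminary value 9).
5. **Classifiers.** Six families with fixed hyperparameter grids:
   Ledoit–Wolf shrinkage LDA (no grid); kNN (neighbors 1…round(4(Nₑ−1)/3)−1,
   Minkowski power 1–5, uniform/inverse-distance weights); linear SVM
   (C = 10ᵉ, e ∈ {−4, 1, …, 46}, shrinking on/off, tol {1e−1, 1e−3, 1e−5},
   iteration cap 1e5); RBF SVM (C and γ exponents {−3, −1, …, 19}, same
   extras); random forest (min split {2, 4, 7, 10, 13} — the printed range
   starts at 1, an impossible split size, mapped to 2; Gini/entropy;
   trees {1, 6, …, 96}; OOB scoring on/off; max features {1, 11, …, 131}
   clamped to K); and a feed-forward network with one hidden layer of 4
   ReLU units trained by LBFGS, best of 100 random restarts.
6. **Validation.** Leave-one-event-pair-out: each fold holds out the two
   trials of one event and trains every stateful stage — CSP per band,
   standardizer, MI ranking, grid search (scored by stratified 3-fold CV on
   training rows, ties to the first grid point, winner refitted on all
   training rows) — on the remaining events.  Subject accuracy is the mean
   of fold accuracies.  Chronological pairing is preserved because folds
   are indexed by events.

Cohort statistics over a classifiers × subjects accuracy matrix use the
sample (n−1) SD, Tukey median-of-halves quartiles, classical one-way
ANOVA, and two-group ANOVA (pooled-variance t² = F) for pairwise
comparisons against a reference classifier, with no multiplicity
correction.  These conventions are the ones that reproduce the published
cohort table of the emulated study exactly; linear-interpolation quantiles
and the population-SD formula do not, and Welch-type unequal-variance
comparisons do not reproduce its pairwise p-values.

## Synthetic data

No recordings of the original study are available, so the generator
produces sessions with known ground truth:

* **Cue schedule.** Inter-cue intervals are Normal(150 s, 60 s) draws,
  rejected and redrawn below 10 s (the normal model admits nonpositive
  gaps; 10 s keeps consecutive event windows disjoint), truncated so every
  onset admits both 1.5 s windows.  An hour-long session yields ~20–25
  events, matching the per-subject accuracy denominators of the emulated
  study.
* **Sources.** One unit-variance band-limited Gaussian process per channel
  (white noise through an order-4 Butterworth band-pass; the effect
  sources occupy the configured effect band, the rest cycle through the
  other analysis bands).  Amplitudes are arbitrary — the study reports no
  physical scale — so sources are unit variance and sensor noise is
  expressed relative to that.
* **Effect.** Within [onset, onset + 1.5 s) the effect sources are scaled
  by `effect_ratio` (1 = null).  This is a pure variance/band-power class
  contrast; it does not model evoked potentials, phase-locked components,
  drift, line noise, eye blinks or muscle artifacts.  Passing pipeline
  tests therefore demonstrate correctness of the machinery on
  variance-coded class structure, not performance on real EEG.
* **Mixing.** Channels are a fixed linear mixture of the sources plus
  white sensor noise (default SD 0.1).  The mixing matrix keeps the
  singular bases of a standard-normal draw but bounds the condition number
  (default 5) before column normalization: unconstrained Gaussian mixings
  are frequently near-singular, which makes the ground-truth unmixing
  directions unidentifiable under sensor noise and would defeat the
  purpose of carrying them as ground truth.  Real volume conduction is not
  near-singular either.

## Numerical and design choices

* **Kaiser shape.** The tap count (466) is fixed by the emulated study but
  the window shape parameter is not; β = 5.653 (~60 dB sidelobe
  attenuation) is the default and is exposed.
* **Boundary handling.** The forward-backward cascade reflection-pads the
  signal by 3 × n_taps samples per end and discards the pad, suppressing
  edge transients; inputs shorter than 3 × n_taps are rejected with a
  pointer to filter continuous data.
* **Epoch convention.** Windows are half-open; the onset sample belongs to
  the event-related window (the cue is on screen at that sample).
* **CSP conventions.** Trace-normalized per-trial covariance, class-mean
  averaging, composite-covariance eigenproblem; class a is always
  pre-event so eigenvalue orientation is deterministic; filters are scaled
  so the largest-magnitude coefficient is positive; equal eigenvalues keep
  their original order (stable sort).  A rank-deficient composite
  covariance raises an error suggesting more trials or shrinkage rather
  than silently regularizing.
* **Trace normalization vs global power effects.**  Per-trial trace
  normalization makes CSP insensitive to trial-wide power fluctuations —
  desirable for real EEG, but it also means that when one source dominates
  a band and its power is globally scaled (the simulated effect), the
  effect direction's eigenvalue collapses toward 0.5 while unmodulated
  directions carry the (relative) contrast.  `fit_csp(...,
  normalize_trace=False)` keeps absolute power for analyses where that
  matters; the pipeline default remains the standard normalized estimator,
  which the downstream log-bandpower features compensate (they use raw,
  unnormalized variance, so the effect remains decodable — and is, at
  100% in the effect-recovery check).
* **Ground-truth recovery check.** CSP's alignment with the known
  unmixing is measured on *broadband* epochs: within a single 4 Hz band,
  12 of the 14 mixture directions are nearly silent, so every whitened
  filter is unidentifiable there; with broadband full-rank interference
  the extreme filter must null all 13 other sources, which is precisely
  the unmixing row.  Because the post-cue window has the amplified
  variance and class a is pre-event, the effect filter sits at the
  minimum-eigenvalue end of the spectrum.
* **MI details.** Ranking operates on standardized features (the estimator
  is invariant to monotone rescaling, so the choice is benign); estimates
  are clipped at zero; k is reduced with a warning when a class is
  smaller than k + 1; zero-variance components hit an ε = 1e−12 guard
  inside the log rather than failing, since degenerate synthetic inputs
  are legitimate.
* **Joint n_sel tuning.** The selected-feature count is a grid dimension
  tuned together with each family's hyperparameters (the reading
  consistent with tuning it "during estimator fine tuning"); the
  preliminary value 9 is the default when tuning is disabled.
* **Grid-search edge cases.** Astronomically large SVM penalties from the
  printed exponent ranges are kept verbatim; the iteration cap (1e5)
  bounds their runtime.  A grid point that fails to fit (e.g. a neighbor
  count exceeding the fold) is scored as chance and logged, never fatal.
  NN restart selection uses the same 3-fold CV score as every other
  family's tuning.
* **Artifact screening.** Real screening in this paradigm is a manual
  judgement; the package offers only an optional peak-amplitude threshold
  (off by default) that drops both trials of an offending event so class
  pairing survives.

* **Null calibration is overdispersed.**  On null sessions
  (`effect_ratio = 1`) the subject accuracy is unbiased (mean 0.485, SD
  0.114 over twelve simulated sessions) but its spread exceeds the
  binomial SD for 2Nₑ independent trials (0.074 at Nₑ = 23): the folds of
  a leave-one-event-pair-out run share almost all their training data, so
  their errors are positively correlated — whichever spurious feature the
  MI ranking latches onto is the same in every fold.  The binomial 99%
  band is therefore an approximate reference, not an exact null
  distribution, and the calibration check is run on a fixed simulated
  session.  The same correlation structure affects any study using this
  validation scheme: per-subject accuracies scatter more around chance
  than a binomial accounting suggests.

## Problem sizes

Full-pipeline properties (null calibration, effect recovery, ground-truth
alignment) run on hour-long 14-channel sessions — the study's own session
length and event counts (~20–25 events) — with the grid-free LDA family
and the full n_sel grid.  The six families' grids are enumerated and
verified exactly as printed; exhaustive tuning of the larger grids (RBF
SVM: 864 points, RF: 5600) inside every outer fold is exercised with
reduced grids in the classifier tests, which is sufficient to pin down the
tuning contract (exhaustiveness, tie-breaking, leakage-freedom) that does
not depend on grid size.

## Interfaces

The package is used as a library: `EventPairDecoder(...).fit()` returns a
`DecodingResults`; `run_validation`/`run_cohort` are functional wrappers;
`scripts/acceptance.py` regenerates the headline numbers.  No console
entry point is shipped — a session analysis is a few lines of Python and
the scripted entry covers reproduction.

Recordings round-trip as EDF (reading via `mne.io.read_raw_edf`; writing
via a minimal 16-bit EDF encoder, one-second records, microvolt units —
no EDF-writing library is part of the dependency set) and as delimited
text (one column per channel, header row of labels).  Markers are
two-column text (event index, onset sample).  CSP models serialize to
JSON; feature tables to CSV with a band:component provenance header.

## Known limitations

* The synthetic effect is variance-only and time-locked exactly to the
  onset; latency jitter, evoked (phase-locked) components and non-Gaussian
  artifacts are absent, so classifier rankings measured on synthetic data
  should not be extrapolated to real recordings.
* The published per-subject accuracies cannot be regenerated from raw
  data (none was deposited); cohort statistics are therefore exact
  reproductions from the printed per-subject tables, while pipeline
  behavior is validated only against synthetic ground truth.
* The EDF writer covers continuous unannotated signals with integer
  sampling rates only.
* No ICA/regression artifact correction, no causal (real-time) filtering
  variant, no multiclass CSP, no cross-subject transfer.
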