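# Methods

## Scope

`fingerdec` re-implements, as a tested and reusable pipeline, a
single-subject MEG decoding analysis built around a compact interpretable
convolutional network (LF-CNN) applied to response-locked sensor epochs
from a serial reaction time task (SRTT): four-finger keypress decoding,
reconstruction of interpretable spatial/temporal/spectral signatures from
the trained weights, and learning-phase analyses (cross-phase decoder
transfer and cluster statistics on latent sources).  Because no public
recordings accompany the analysis, the package ships a synthetic SRTT-MEG
generator with full ground truth; every quantitative claim the test suite
makes is made about that generator's output.

## Generative model of the simulator

Sensor epochs follow the standard linear instantaneous mixing model

    X_t = A S_t + eps,     eps ~ N(0, sigma^2 I),

with one source (by default) per finger class.  Topographies are spatial
Gaussians (sigma = 0.22 in unit-disk coordinates) on a deterministic
sunflower-spiral layout of 204 planar positions, centred over "central"
sensors contralateral to the moving hand (x < 0 is the left hemisphere by
convention); columns of A are unit norm.  Each class's source carries:

- a movement-evoked low-frequency transient: a Gabor with 3 Hz carrier,
  100 ms Gaussian width, centred +50 ms after the button press,
  amplitude 1.0 (arbitrary units; the sensor noise SD is 0.1);
- alpha (10 Hz) and beta (20 Hz) oscillations, amplitude 0.5, with
  uniformly random phase per trial (so they are induced, not evoked);
- event-related desynchronization: a Gaussian-windowed amplitude drop
  (depth 0.7, centred +50 ms, sigma 150 ms, i.e. starting roughly 200 ms
  before the press) applied to the active class's oscillations only, plus
  a beta rebound (gain 0.5 around +400 ms).

Oscillations of the *inactive* classes stay at baseline amplitude in
every trial, so class information is carried by the evoked transient and
by which topography desynchronizes — a deliberately simple stand-in for
contralateral motor ERD.

The task structure is the 12-item key sequence 1 2 1 3 4 2 3 1 4 3 2 4
(keys → left middle, left index, right index, right middle fingers),
repeated 10 cycles per block for 12 blocks: 120 keypresses per block,
1,440 in total, 338 ms inter-stimulus interval.  Reaction times follow a
block-level exponential decay, mean(block b) = 0.35 + 0.20·exp(−0.25·(b−1))
seconds, plus trial-level Gaussian noise (SD 50 ms) truncated at the
0.35 s floor — the simplest monotone curve with the qualitative shape of
SRTT learning.  Responses are correct with probability 0.975; error
trials press one of the other three keys and carry the pressed key's
finger label, flagged incorrect.

The optional "phase shift" models a change in motor dynamics once the
sequence is learned: in blocks 10–12 the evoked transient arrives 50 ms
later and 1.2× larger.  These values produce a detectable but not
trivial cross-phase transfer effect; they make no claim about real
effect sizes.

What the generator does **not** emulate: magnetometers, continuous raw
data with drifts and head movement, ocular/cardiac/muscle artifacts,
1/f background spectra, inter-source correlations, or anatomically
realistic field spread.  Passing tests therefore demonstrate the
correctness and calibration of the pipeline's machinery, not performance
on real MEG.

## Preprocessing

High-pass filtering is zero-phase FIR: a Hamming windowed-sinc low-pass
spectrally inverted (h = δ − lp, which nulls DC exactly regardless of
length) and applied forward–backward, so the lock point is never
shifted.  On short epoched signals the tap count is capped at one third
of the epoch length so the filtfilt edge padding stays valid; the
resulting transition band is recorded in the provenance string.
Downsampling is polyphase resampling with the built-in anti-alias
filter.  Epochs are the half-open window [−0.5, +0.5) s around the
button press, which is exactly 200 samples at 200 Hz; z-scoring uses the
scalar mean and SD pooled over all channels and samples of each epoch
(a per-channel variant is available behind a flag).  The high-pass is
conceived as acting before epoching when continuous data exist; on
simulated data it is applied to the epochs directly.

## The decoder

Four layers: (1) spatial demixing, S = WᵀX + b, with k = 32 components
by default; (2) one FIR kernel of p = 7 samples per component, applied
depthwise with zero-padded same-length output (so the pooled grid does
not depend on p); (3) non-overlapping max-pooling by a factor 10 along
time; (4) affine softmax readout of the flattened pooled features.
There is no other nonlinearity.  Training minimizes softmax
cross-entropy with L2 penalty (3e-2) on the spatial and readout weights,
by mini-batch Adam (batch 100).  The learning-rate default is 3e-3:
at 3e-4 the network needs many hundreds of epochs to converge even on
cleanly separable data, which makes nested cross-validation needlessly
slow; 3e-3 converges within a few tens of epochs with no observed
instability.  All of these are configurable; p is configurable because
published parameter totals cannot be reproduced from architecture
descriptions alone.

Validation is nested: 6 stratified outer folds (5/6 train ≈ 83.3%, 1/6
test ≈ 16.6%); within each outer training portion a stratified 5-fold CV
drives early stopping (patience 3 on validation loss), and the fold's
final model is retrained on the whole outer-training set for the mean
selected epoch count.  Everything is seeded and bit-reproducible.  The
forward and backward passes are written directly in numpy (the model has
only tens of thousands of parameters); gradients were verified against
central finite differences to ~1e-9 relative error.

Ablations replace one layer by a fixed surrogate without retraining:
spatial → channel mean broadcast to all components, temporal → unit
centre tap, readout → nearest class centroid on the pooled features.

## Interpretation

Spatial filters are made interpretable through the forward-model
(activation-pattern) transformation A = Kxx·W·Kss⁻¹, with covariances
pooled over trials and time (mean removed) on the outer-training trials
of the fold that produced W.  The equation leaves per-component sign and
scale free, so reported patterns are unit-norm with the
maximum-magnitude coefficient positive; the raw solution is also kept
because the algebraic identities (A·Kss = Kxx·W) hold for it.  A ridge
of 1e-6·trace(Kss)/k is added only when Kss is ill-conditioned
(condition number > 1e10); a singular Kss beyond that raises an error
reporting the condition number.

A caution that the tests encode: a softmax-trained network identifies
the class topographies only up to an invertible linear mix across
components (the readout absorbs any such mix), so individual pattern
columns need not align one-to-one with true topographies.  What pattern
reconstruction does guarantee — and what is asserted — is that the true
topographies lie in the span of the reconstructed patterns.  One-to-one
recovery holds when W is an actual source-recovering decoder (the
least-squares construction used in the Haufe oracle test).

Latent temporal sources are the temporal-layer output (spatial
projection then FIR).  Time–frequency maps average *single-trial* Morlet
wavelet power (grid 5–40 Hz in 1 Hz steps, n_cycles = f/2 bounded below
by 3), so induced activity survives; the grid starts at 5 Hz because a
≥3-cycle wavelet below that does not fit a 1-s epoch.  Spectral profiles
are Hann-window periodograms averaged over trials, alongside the
squared-magnitude DFT of each FIR kernel on the same frequency grid; the
temporal layer's additive bias is excluded from output spectra since it
only shifts DC.

## Phase statistics

Learning vs learned phases default to blocks 1–3 vs 10–12.  Cross-phase
transfer trains a nested-CV decoder set within each phase; same-phase
accuracy is the held-out accuracy, cross-phase accuracy applies each
outer-fold model to all trials of the other phase (averaged over folds).
Across subjects, four paired t-tests compare same- vs cross-phase cells.

The latent contrast computes, per component and time point, the
two-group one-way F statistic between phases on per-trial temporal-layer
outputs.  Clusters are runs of adjacent samples with F above the
F(1, n−2) upper-0.05 quantile, scored by mass (sum of F); the null is
the per-permutation maximum cluster mass within the same component
(1,000 random phase-label permutations by default, or exhaustive
enumeration of all assignments on small instances).  Correction is
across time within each component only — components are reported
individually, matching per-component counting — so no correction spans
components.  For each significant cluster the spatial-pattern similarity
between the two phases' pattern reconstructions of that component is
attached as a normalized scalar product (cosine), keeping values in
[−1, 1]; the raw scalar product is available behind a flag.

## Null calibration of the decoding pipeline

The label-shuffling null deserves a note.  Shuffling all labels once and
scoring held-out folds against the *same* shuffle leaves a finite-sample
association between true class clusters and their majority shuffled
label (a max-of-multinomial-shares bias of roughly one CI width for four
classes, at any n), so that procedure sits systematically above chance.
Scoring against the *true* labels removes the bias but a single global
shuffle still over-disperses the null: every fold shares the sign of the
shuffle's accidental cluster-to-label majority.  The package's null
therefore shuffles the training labels independently within each outer
iteration and scores held-out predictions against the true labels: the
learned cluster→label maps are independent of the truth and of each
other, so the mean accuracy is exactly chance with near-binomial
dispersion.  This is the quantity the acceptance script reports.

## Problem sizes

The default configuration (204 channels, 1,440 trials, k = 32) is the
simulated study condition; the test suite exercises the same code paths
at reduced sizes chosen once (48 or 32 channels, 240–576 trials, k = 3–8,
epoch budgets of 25–60) so the full suite runs on a single CPU in
minutes.  The acceptance script uses the default simulator at 204
channels with a mid-sized model (k = 16, epoch budget 30).

## Known limitations

- The RT model and phase-shift parameters are plausibility choices, not
  fits to data.
- Single-subject decoding only; no across-subject random-effects
  statistics.
- No FIF reader/writer; epochs are exchanged as documented HDF5 (an
  `mne.EpochsArray` converter is provided for interoperability).
- The amplitude-threshold trial-rejection hook is a crude stand-in for
  visual artifact inspection and is off by default on synthetic data.
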