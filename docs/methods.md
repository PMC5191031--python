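# Methods

## The model

The package implements a sensorimotor-rhythm brain–machine interface for
binary exoskeleton control. Its scientific core is the classical
ERD/ERS–CSP–classifier chain:

**ERD/ERS quantification.** Event-related desynchronization (ERD) and
synchronization (ERS) are the percentage change of band power relative to a
pre-event reference window,

    ERD/ERS% = (A − R) / R × 100,

where `A` is the band power of a post-cue segment and `R` the mean band
power over the reference window (trial seconds 0–1; the cue appears at
second 3 of the trial-internal clock). Power comes from non-overlapping
100 ms Hann-windowed FFT segments, averaged over trials before the percent
transform (classical ERD methodology; a per-trial mode is available).
Segments are zero-padded to 1 s before the FFT so band edges fall on a 1 Hz
bin grid; note that zero-padding interpolates the spectrum but cannot
narrow the ~±20 Hz mainlobe of a 100 ms Hann window. Two consequences are
handled explicitly: (i) neighbouring bands share leaked contrast, so the
automated band-selection routine uses 0.5 s segments internally (±4 Hz
mainlobe) while ERD/ERS maps keep the 100 ms grid; (ii) broadband noise
inside the effective noise bandwidth (~15 Hz) dilutes the measured percent
change — with the default generator settings an injected −75 % band-power
modulation is measured at about −68 to −71 %, a known property of the
estimator rather than a defect.

**Common spatial patterns.** For a band-passed trial `V` (N channels × T
samples) the normalized covariance is `W = V Vᵀ / trace(V Vᵀ)`. Class means
`W̄1, W̄2` are averaged over trials; the composite `Wc = W̄1 + W̄2` is
eigen-factored, whitened by `M = λc^{-1/2} Ecᵀ`, and the whitened class
covariances are jointly diagonalized by a common rotation `U` with
eigenvalue pairs summing to one. The projection is `B = Uᵀ M`; rows are
ordered by descending class-1 eigenvalue, each row's largest-magnitude
entry is made positive (bit-reproducible fits), and the first and last `m`
rows (default `m = 2`) are retained. Per-trial covariance defaults to the
mean of per-200 ms-segment normalized covariances over the feature window
(seconds 4–7); a whole-window mode exists. Rank-deficient composites are
regularized with `1e-10`-scaled identity. Features are normalized
log-variances `F_j = log(D_j / Σ_k D_k)` over the 2m retained projections
(retained-only normalization).

**Decoding.** Classifiers are LDA, a linear-kernel SVM (cost chosen from
{0.1, 1, 10}) and a one-hidden-layer backpropagation network (width chosen
from {5, 10, 20}, lbfgs). Hyperparameters are selected by stratified
10-fold cross-validation *inside* the training set and the winner refit on
all training trials; CSP is always fitted on training trials only, so
held-out metrics are leakage-free. (The inner CV itself sees features
derived from CSP filters fitted on the full training set — the standard
practice, and the reason permutation-null checks are done on held-out
trials.) The strategy grid crosses the three classifiers with train–test
ratios 50/50, 60/40, 80/20 (stratified, per-class floor rounding); the best
strategy maximizes the cross-session average accuracy, ties going to the
simpler model class and then the larger training fraction.

**Metrics and statistics.** Reports carry the 2×2 confusion matrix,
accuracy, and per-class precision, recall and F = 2PR/(P+R) on the percent
scale, with a 0-convention (flagged) for empty predicted classes. The
2×2 within-subjects ANOVA uses the textbook repeated-measures
sums-of-squares decomposition with subject × effect interactions as error
terms; a zero error variance returns an `inf` F sentinel (p = 0) for a
non-zero effect rather than failing. statsmodels' AnovaRM serves as an
independent oracle in the test suite.

**Closed-loop simulation.** An online session streams cued trials, decodes
the seconds 4–7 window with a pre-trained decoder, and maps the predicted
class to a binary action (left hand → flexion, both feet → extension by
default). The one-DOF elbow model moves 10° per action, clamped to 0–120°,
and a feedback angle mirrors the elbow after every step; the action log is
sufficient to replay the state trajectory.

## The synthetic generator

Because no public recordings accompany the study design, a generator
produces continuous 28-channel EEG (512 Hz) whose ground truth every stage
can be tested against. Narrowband mu (10–12 Hz) and beta (20–24 Hz)
oscillators sit at C3, C4 and Cz and are mixed into the montage by a
Gaussian distance-decay matrix (σ = 2·`mixing_spread` electrode spacings);
per-channel 1/f noise plus a spatially common 1/f component form the
background. Per trial, task-window amplitudes are scaled by class:
contralateral hand-area ERD (left hand → C4), a weak ipsilateral ERS,
foot-area ERS at Cz for hand movements, and the opposite pattern (Cz ERD,
bilateral hand-area ERS) for both-feet movements. An optional beta rebound
(amplitude overshoot in the last task second) models post-movement ERS.

Key defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `mu_amp_uv` / `beta_amp_uv` | 5.0 / 2.5 µV | typical sensorimotor-rhythm amplitudes; keeps the in-band noise floor ≲10 % of source power so percent-change estimates are only mildly diluted |
| `erd_depth` / `ers_gain` | 0.5 / 0.4 | a −75 % / +96 % band-power modulation, the magnitude range of clear motor-execution ERD/ERS |
| `depth_jitter_sd` | 0.4 | lognormal trial-to-trial modulation-strength variability (vigilance/effort), mean-power-preserving (`E[a²]` exact) so trial-averaged ERD stays unbiased; calibrated so offline decoding lands in the realistic 85–95 % band instead of a 100 % ceiling |
| `amp_jitter_sd` | 0.3 | whole-trial amplitude variability (electrode/vigilance drift) |
| `noise_rms_uv` / `common_noise_rms_uv` | 3.0 / 1.5 µV | broadband background typical of band-limited scalp EEG |
| `mi_depth_scale` | 0.6 | motor imagery simulated as attenuated execution; direction (ME stronger than MI) is the established finding, the scale is a free choice |
| `passive_arm_contamination` | 0.6 (wearing-exoskeleton scenario) | see below |
| pause | uniform 2–5 s | the protocol specifies the range but not a distribution |

**Passive-arm contamination.** Wearing the exoskeleton on the right arm
makes the arm move with the device, generating hand-area rhythms unrelated
to the cued class. This is modelled as an *additive*, class-independent
mu/beta oscillation at C3 and C4 during the task window (amplitude =
contamination × source amplitude). A purely multiplicative amplitude factor
was rejected: it shifts both classes' hand-area log-power by the same
constant and leaves the decoder almost untouched. The additive component
raises hand-area power, which mimics the feet class's hand-area ERS and
therefore pulls left-hand trials across the boundary — reproducing both the
accuracy drop and its asymmetry (left-hand recall suffers most) seen in
closed-loop use. At 0.6 the without-vs-wearing ordering holds in ≳8 of 10
seeds on per-seed marginal means.

**Artifacts.** Blink-like transients are monophasic 0.4 s Hann bumps,
strongest frontally, with per-channel peak `max(25 × RMS, 150 µV) × row
weight` — the size of real ocular artifacts, and high enough that the
injected peak stays ≥5× background RMS after superposition.

**Trial exclusion.** The study screened trials by visual inspection; the
package substitutes two automated criteria evaluated from 2 s pre-cue to
task end on *unfiltered* epochs (blinks live below the 8–30 Hz analysis
band): a 100 µV peak-amplitude threshold, and a robust (median/MAD)
z-score of log-variance exceeding 10 on at least two channels. The robust
scale prevents heavy artifacts from masking themselves; the two-channel
corroboration reflects that ocular/muscular artifacts project broadly. The
threshold of 10 sits between the largest z that ordinary lognormal
amplitude variability produces on clean data (≈8 across seeds) and the
smallest blink value observed (≈14), so clean synthetic sessions yield zero
exclusions while every artifact-bearing trial is caught via the amplitude
rule or the variance rule.

**What the generator does not emulate.** No biophysical head model or
realistic forward solution (a planar Gaussian mixing stands in for volume
conduction), no non-stationary background (alpha blocking, drowsiness), no
EMG spectra, no electrode drift or re-referencing effects, and sources are
pure sinusoids with trial-constant frequency rather than broadband
rhythms. Passing tests therefore demonstrate the correctness and internal
consistency of the pipeline under the stated statistical structure — not
performance on real recordings.

## Preprocessing numerics

The analysis band-pass (8–30 Hz) is a 1025-tap linear-phase FIR applied
once with its integer group delay removed exactly — i.e. zero-phase, so
cue-locked latencies are preserved — with reflection padding and an IIR
notch (filtfilt) at 50 Hz. The FIR was chosen over Butterworth variants
because zero-phase IIR designs of any order up to 8 change the RMS of an
already-filtered signal by ~3 % on re-application (transition-band
re-attenuation), while the sharp FIR is idempotent to <1 % and loses <0.3 %
at 10 Hz. EDF output uses 1 s records, 16-bit samples and a symmetric
physical range sized to the signal maximum (quantization `max|x|/32767`);
reading goes through MNE, which doubles as an independent check of the
writer. Epoching flags cues whose window spills outside the recording
(reason "edge") instead of dropping them, keeping trial indices aligned
with the event list.

## Problem sizes used in validation

The validation studies run on deliberately moderate sizes chosen to give
stable statistics: parameter recovery uses 100 trials/class (80/20 split,
40 test trials); the ordering study trains one decoder per motor mode on
50 trials/class per seed and runs four 60-action online sessions for each
of 10 seeds; CSP oracle checks use 2–6 channel Gaussian instances where the
generalized eigendecomposition is unambiguous.

## Known limitations

* The ERD/ERS% estimator with 100 ms segments systematically
  underestimates deep narrowband modulations (noise-bandwidth dilution,
  quantified above); longer segments trade temporal for spectral fidelity.
* Band selection among candidates narrower than ~2 Hz apart is unreliable
  even with the 0.5 s internal segments.
* The BPNN is deterministic only for a fixed seed and lbfgs; different
  BLAS builds may flip rare borderline predictions.
* The closed-loop simulation scores decoding accuracy; it does not model
  actuator dynamics, timing jitter or user co-adaptation.
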