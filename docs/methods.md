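# Methods

This note documents the models, conventions and deliberate design choices
behind `soundease`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and where the genuinely open decisions
were made.

## 1. The filter engine

All processing operates on float waveforms in [−1, 1] at 44,100 Hz
(channel-major; stereo is processed identically per channel). Chains clip to
[−1, 1] once at the output; intermediate stages stay unclipped so gain
staging composes linearly.

**Base-volume correction.** The device volume setting `o ∈ [0, 1]` maps to a
gain `A = 2.0·(0.5 − o)/0.0625 = 32·(0.5 − o)` dB, i.e. 0 dB at the
reference setting 0.5 and ±16 dB at the endpoints — the same ±16 dB span
used to normalize `A` as a model covariate. The correction is applied as a
linear factor `10^(A/20)` before any other stage.

**Chain order.** Stages run in palette order: Recollection — Amplify(All),
Amplify(Low/Medium/High), Noise, Tinnitus, Band reject, Echo, Flanger, Water;
Easing — three-band volume crossover, Pitch shift, Change suppression,
Volume(All), then the shared palette. Any stage at its default parameters is
an exact identity, so chain composition is unambiguous for untouched filters.
An alternative order can be passed explicitly to `apply_chain`.

**Peaking amplifiers.** The Amplify(Low/Medium/High) and Water stages are
RBJ-cookbook second-order parametric peak/notch biquads at fixed
center/bandwidth pairs (100/100, 1,100/900, 11,100/9,000; Water: boost
260/240, cut 4,400/3,600 Hz scaled ±12 dB by one 0–1 control). The gain
parameter is a *linear* amplitude ratio with 1.0 = identity (converted to dB
internally). This reading keeps the identity-at-default invariant, matches
the unity-default parametric EQ convention of mobile audio frameworks, and
makes the 1.0–5.0 range a 0–14 dB boost.

**Band reject.** Second-order Butterworth band-stop with *geometric* edge
placement (`lo·hi = center²`, `hi − lo = width`), so the notch zero lands
exactly on the requested center frequency. Widths below 1 Hz bypass the
stage: such a notch is inaudible, numerically marginal (poles essentially on
the unit circle), and the registry default width of 0.1 Hz denotes "filter
untouched".

**Three-band volume crossover (Easing).** Implemented as a delta crossover
`y = x + (g_L−1)·LP(x) + (g_M−1)·BP(x) + (g_H−1)·HP(x)` with second-order
Butterworth band extractions (cutoffs 200 / 2,000 Hz; band 1,100 Hz center,
900 Hz width) run zero-phase (forward–backward). Rationale: unity gains are
an *exact* identity (a causal LP+BP+HP sum is not allpass), and zero-phase
extraction keeps the subtraction phase-true so gain 0 removes a band instead
of phase-smearing it.

**Change suppression.** The signal is analyzed in consecutive 1,024-sample
frames; 16 frame-to-frame differences span 16·1,024/44,100 ≈ 372 ms. Frame
amplitude is the mean absolute sample value by default (an RMS variant is
exposed via `mode=`); the trigger statistic is the *signed* mean of the last
16 differences — a rise detector that telescopes to
`(a_t − a_{t−16})/16`. When it exceeds the threshold, gain drops to the
`suppression` value for that frame, then relaxes *linearly* back to 1.0 over
`back_time` seconds; re-triggering restarts the relaxation. The gain
trajectory is exposed (`change_suppression_gain`) for inspection and testing;
it never exceeds 1. Audio shorter than 17 frames passes through with a
warning.

**Other stages.** Echo is a Schroeder reverb (four parallel feedback combs,
delays 1557/1617/1491/1422 samples, feedback 0.84, into two allpasses,
225/556 samples, g = 0.5) exposed through a dry/wet mix only. The flanger
adds a copy delayed 5 ms ± 2 ms, sinusoidally modulated at the given LFO
frequency, with linear-interpolated fractional delay. Pitch shift is a phase
vocoder (2,048-point frames, hop 512): time-stretch by the semitone ratio,
then resample back onto the original sample grid, so output length equals
input length exactly. White noise is uniform with the given peak amplitude,
drawn from an explicit seed carried by the chain call (default 0).

**Registry quirks.** The tinnitus amplitude default is documented upstream
as 0.1 while its own range is 0.0–0.05; the registry clamps the default to
0.05 and the discrepancy is surfaced in the code rather than silently
resolved. Tinnitus is consequently the one filter whose default is audible;
identity tests assert at amplitude 0.

## 2. Feature construction

**Audio frontend.** Stimuli are loop-padded/trimmed to exactly 20 s,
resampled to 16 kHz, and embedded as 41 frames × 1,024 features. The
pretrained YAMNet frontend defines this geometry but requires downloaded
weights, which are not bundled; selecting it raises an error naming the
fallback. The default (fallback) frontend reproduces the geometry
deterministically: 64 HTK-mel bins (125–7,500 Hz), 25 ms Hann windows, 10 ms
hop, patches of 96 frames hopped by 48 frames (0.96 s / 0.48 s), each
flattened patch projected to 1,024 dimensions through one fixed
seeded Gaussian matrix (seed 909, scaled 1/√d). Standard framing yields 40
patches from 20 s; the waveform is right-padded by one patch hop (0.48 s of
silence) to produce the 41st. The downstream pipeline is frontend-agnostic:
everything consumes (41, 1024) matrices.

**Covariates.** All scalar covariates are min-max scaled with fixed,
instrument-defined bounds: sleep 0–1,440 min; fatigue 1–7; age 20–64 (the
recruitment range); AQ 0–50; AASP quadrants 15–75 (15 items × 1–5); AASP
auditory total 11–55 (11 items); volume correction −16…16 dB. Sex and
Bluetooth profile (A2DP/HFP) are two-column one-hots. The component order is
fixed and published (`COVARIATE_SCHEMA`). Instrument bounds were chosen over
observed sample min/max because they are data-independent and keep scaling
identical across cohorts; sample-based bounds can be imposed by rescaling
upstream. Easing-task inputs append the 13 normalized Recollection
parameters and the 5 Recollection ratings scaled from 1–7 onto [0, 1].

## 3. The predictors

One joint model per task predicts all outputs at once: the task's filter
parameters (13 or 17) plus the five ratings, all on the unit scale.
Architecture: a bidirectional LSTM over the 41 feature frames (final forward
and backward hidden states concatenated), concatenation with the covariate
vector, dense layers (Linear → BatchNorm → SiLU → Dropout), and a linear
output layer with sigmoid. The sigmoid head plus inverse min-max scaling
makes every prediction range-respecting by construction; ratings are
returned on the continuous 1–7 scale.

Training uses MSE loss and Adam (defaults: 300 epochs, batch size 24,
learning rate 1e-3). Hyperparameters not fixed by the protocol are declared
defaults, exposed in `ModelConfig`: 128 LSTM units per direction, dense
widths (256, 128), dropout 0.2. Batch norm uses batch statistics during
training and running statistics at prediction; dropout is disabled at
prediction.

The network is implemented directly on numpy with hand-written
backpropagation (verified against central finite differences in the test
suite) and two engineering choices that make CPU training practical: all
trials sharing a stimulus share the LSTM computation exactly (unique-stimulus
deduplication with scatter-added gradients), and float32 arithmetic
throughout. Training is bit-for-bit reproducible for a fixed seed on one
thread. Trials whose filters were never touched still contribute
default-valued targets — usage counts are descriptive, not a training
filter.

**Split.** The dataset is always partitioned by stimulus (Training +
Training-reserve vs Test + Test-reserve), never by listener; repeated
presentations are excluded from both sides. At the default design this gives
1,709 training and 683 test points per task.

## 4. Evaluation statistics

Pearson correlation for filter parameters, Spearman for the ordinal ratings,
both with two-sided p-values over all test trials (including default-valued
targets; restricting to touched-only trials would make many cells
uncomputable). MAE is reported after inverse scaling, in native units. A
zero-variance side yields `NA` rather than an error or a dropped row. Stars:
\* p<0.05, ** p<0.01, *** p<0.005.

The **reproducibility value** compares which filters were touched on first
vs second presentations of the repeated stimuli: per listener,
`C_both / C_one` (filters changed in both presentations over filters changed
in exactly one; the literal reading) with `C_both / (C_both + C_one)`
selectable. Zero denominators are flagged and excluded from the group
mean ± SE with the flag preserved.

The **task comparison** pairs trials by (listener, stimulus), runs
Shapiro–Wilk on the paired differences, and reports a paired t-test as the
primary statistic alongside a Wilcoxon signed-rank for the non-normal
branch. The **RMS comparability** check computes per-clip frame RMS (frame
2,048, hop 512, mean over frames) and a two-sample KS test between training
and test stimuli; the standard KS null (equal distributions) is reported and
interpretation left to the caller. **Group profiles** are compared with
Mann–Whitney U (Shapiro–Wilk reported alongside).

## 5. The synthetic experiment

The generator emulates the study conditions: 62 stimuli (30 Training, 10
Training-reserve, 12 Test, 10 Test-reserve) of 20 s at 44.1 kHz spanning
four stress-inducing sound characters — sudden bursts, steady broadband
noise, multi-source mixtures, strong sounds — plus low-stress fillers;
28 DD + 29 TD listeners with trait scores from truncated normals inside
instrument bounds (DD shifted upward on AQ, low registration, sensory
sensitivity, sensation avoiding and the auditory total; zero shift on
sensation seeking; ages uniform 20–64); 42 scored trials per listener per
task with skip probability 31/2,394 (skips replaced from the matching
reserve set), three repeated Training stimuli per listener, and a
missing-data event that removes one Training and one Test stimulus of one
listener (2,394 → 2,392 trials per task, 1,709/683 after the split).

The response model is deliberately the simplest recoverable structure:
latent stress `L = aversiveness(stimulus) × sensitivity(listener) +
noise_sd·ε`. Aversiveness is a fixed clipped combination of loudness
(dB-scaled RMS), onset count and high-frequency energy share; sensitivity a
fixed logistic read-out of AQ, sensory sensitivity and the auditory total
into (0.4, 1.6). Ratings discretize `1 + scale·w_item·L` (rounded, clipped
to 1–7); Easing ratings subtract a planted `easing_effect` (default 1.5
rating points) before discretization. Each filter is touched when
`α_f + 0.8·(L−1) + 3·noise_sd·ε > 0`, with `α_f` anchored to realistic
per-filter usage rates (volume-type filters near one half, tinnitus/flanger
rare); touched parameters follow linear links in `L` (Recollection links
rise with stress, Easing volume links fall), clipped to the unit interval.
Second presentations of repeated stimuli redraw the usage noise
independently, which lands the reproducibility value in the ~0.4–0.7 band
typical of this protocol. At `noise_sd = 0` every link becomes a
deterministic threshold or line, so the full generative mapping is an exact
function of (waveform, traits) — the basis of the recovery tests.

**What the generator does not emulate:** real acoustic scenes (stimuli are
parametric tone/noise constructions), per-listener idiosyncratic filter
taste, learning/fatigue across the session, or diagnosis subtypes. Passing
recovery tests therefore demonstrates that the pipeline can extract a
signal that is genuinely present in audio + covariates; it does not certify
performance on human data.

## 6. Numerical conventions and problem sizes

- Settings/ratings normalization is exact min-max over declared ranges;
  round-trips are tested to 1e-12.
- Spectral test contracts use a steady-state tone-projection oracle rather
  than comparing IIR outputs bit-wise.
- Recovery tests and the acceptance script train at the full 57-listener
  design but reduced network width (4 LSTM units per direction, dense
  (32, 16)) — the package's chosen desk-scale configuration; the noise-
  degradation curve uses an equal, shorter budget (40 epochs) per noise
  level so levels are comparable.
- Seeds: every stochastic component (generator, weights, shuffling, dropout,
  chain noise) is an explicit argument; library-level determinism assumes a
  single BLAS thread.

## 7. Known limitations

- The DSP stages are spectrally faithful but not bit-compatible with any
  mobile audio framework's implementations; contracts are spectral.
- The fallback frontend is a fixed random projection of log-mel patches: it
  preserves energy/spectral structure linearly but is not a semantic audio
  embedding; models trained on it cannot be transferred to the pretrained
  frontend without retraining.
- The numpy network targets this problem scale (~2k trials, 41-step
  sequences); it is not a general-purpose deep-learning stack (no GPU, no
  autodiff beyond what is implemented).
- Real-time/streaming filtering is out of scope; chains process whole
  buffers.
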