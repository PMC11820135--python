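# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `miglove`, in the spirit of a methods appendix.

## Signal model and preprocessing

Recordings are continuous multichannel EEG in microvolts at a default
125 Hz (the native rate of the 16-channel OpenBCI Cyton+Daisy stack the
montage is modeled on), with phase annotations `(onset_s, duration_s,
phase, trial, session)`; sample index ranges are half-open `[start, end)`.

The filter chain is a 4th-order Butterworth bandpass 0.5–45 Hz plus a
second-order IIR notch at 60 Hz with quality 30, both applied
forward–backward (`sosfiltfilt`/`filtfilt`) so the chain is zero-phase and
epochs stay time-aligned. The cutoffs are the published preprocessing
band; the realization (Butterworth, order 4, zero-phase) is this package's
choice, the conventional one for EEG. Featurization uses 1–45 Hz (the
band the classifier sees); 0.5–45 Hz governs filtering only.

Phase cropping removes 3 s from each end of every 16 s phase to discard
task-transition transients. The crop is *annotation-level*: the continuous
signal is untouched, so filters never see artificial discontinuities, and
the filtfilt edge transients at the recording ends fall outside every
eligible interval. Epochs are 1 s windows at 0.25 s hop (0.75 s overlap);
the count per eligible interval of T seconds is `floor((T − 1)/0.25) + 1`
— 37 for a trimmed phase, hence 666 per class for the full 18-trial
protocol — computed in integer samples to avoid float-boundary surprises.

Because neighbouring windows share 75% of their samples, a random
epoch-level split would leak test data into training. The split therefore
assigns whole trials (default) or sessions to one partition, stratified by
the group's majority class, deterministic in the seed, and errors out if
either partition would lose a class.

## Spectral features

A 1 s epoch at integer fs has a DFT on an exact 1 Hz grid; the feature is
the magnitude spectrum at 1…44 Hz per channel — shape (44, 16), spanning
[1, 45) Hz. No taper is applied by default (a Hann window is available);
for the band-limited oscillators and 1/f noise used here the rectangular
window keeps pure integer-frequency tones confined to single bins, which
the tests exploit. Features are z-normalized per epoch and channel across
bins before entering the model; normalization is required for stable
training of the small transformer and is part of the decoder, not of
`featurize`.

Band powers are **sums** of squared magnitudes over each band's integer
bins, with shared edges assigned to the upper band (4 Hz → theta, 13 Hz →
beta, 30 Hz → gamma) so the five canonical bands partition the bins 1–44
and their powers sum exactly to total in-band power. Delta is truncated to
[1, 4) Hz because the 1 Hz grid has no 0.5 Hz bin; a longer analysis
window would be needed to resolve it. Condition contrasts are Cohen's d
(pooled SD) per channel × band, sign convention `a − b`.

## Decoder

The classifier maps the (44, 16) feature to P(rest), P(fist), treating
the 44 bins as sequence positions. Fixed sinusoidal positional encoding
(`sin/cos(pos / 10000^(2i/16))`) is added; the encoding is non-learned,
consistent with its zero parameter count in the reference layer summary.
The default graph follows that summary literally, including its
asymmetry: block 1 is attention → dropout → residual → layer-norm →
FFN(16→128→16, ReLU) → residual → layer-norm; block 2 is attention →
dropout → residual only, feeding global average pooling over the bin axis
and a dense head 16→128→64→2 with ReLU, batch-norm, dropout and layer-norm
between stages. `ModelConfig.symmetric_blocks=True` restores a
conventional symmetric second block. Per-layer weight counts under the
default configuration match the reference summary cell for cell (total
50,354, with batch-norm counting its running statistics).

Attention is the standard parameterization that reproduces the published
17,168-parameter count from (embed 16, 4 heads, head size 64): per-head
Q/K/V projections of width 256 with biases, concatenation, and an output
projection back to width 16 with bias.

The network, backpropagation and Adam are implemented directly in NumPy
(float64). Correctness is established by a central-difference gradient
check over every layer's parameters (tolerance ~1e-7) rather than by
trusting a framework. Training uses Adam (lr 1e-3), batch size 32, up to
100 epochs with early stopping (patience 10) on validation focal loss and
restoration of the best weights; it is bit-deterministic for fixed seeds
on a single thread. Unstated training details (optimizer, rates, dropout
0.1 attention / 0.3 head, ReLU) are declared configuration, not claims.

Focal loss uses the standard form `−α_c (1 − p_c)^γ log p_c` with γ = 2
and α proportional to inverse class frequency normalized to mean 1; γ = 0
with unit α recovers cross-entropy exactly, which the tests assert. Batch
normalization uses momentum 0.9 for its running statistics — with only a
few dozen batches per epoch a slower constant (0.99) leaves evaluation-mode
statistics stale long after the weights have converged.

Class convention: index 0 = rest, 1 = fist. `decode_intent` emits
s_t = 1 iff P(fist) ≥ 0.5, with the exact tie decoding as fist
(the actionable class; documented tie-break).

## Synthetic EEG

Each channel is 1/f-amplitude Gaussian noise (flat below 1 Hz, default
5 µV) plus alpha (10 Hz, 6 µV) and beta (20 Hz, 3 µV) oscillators with
random phase and a slow lognormal amplitude envelope. During motor-imagery
and motor-execution phases the oscillator amplitudes on the sensorimotor
set {C3, C4, F3, F4} are multiplied by (1 − effect_size) — the ERD
contrast the decoder must find. `rest_alpha_gain` (default 1.0, i.e.
disabled) can additionally boost rest-phase alpha; the default is 1 so
that `effect_size = 0` is an *exact* null: motor-imagery and rest segments
are then draws from the same distribution, which the calibration tests
(two-sample test on alpha power; chance-level AUC end to end) rely on.

The generator emulates the three-phase protocol (16 s phases, 6 trials ×
3 sessions = 864 s task data per subject) with every sample covered by
exactly one annotation, and is bit-deterministic in (profile, protocol,
seed). It does **not** model ocular/muscle artifacts, volume conduction,
inter-channel correlation, non-stationary drift, or realistic spatial
topography — so a passing end-to-end test shows the pipeline recovers a
planted spectral contrast, not that the decoder handles real-EEG
nuisance structure. The discriminative channel set is a configurable
stand-in, not a claim about any subject population.

Default study conditions used by the tests and the acceptance script:
strong-ERD subject effect_size 0.8 with 200 epochs per class (held-out
accuracy ≥ 0.9 expected), null subject effect_size 0.0 (AUC ≈ 0.5), both
split at the trial level. These sizes keep a full training run in tens of
seconds on one CPU while leaving the stochastic margins wide.

## Evaluation

All metrics are implemented from their definitions: accuracy = trace /
total; F1 with positive class = fist (the minority, actionable class —
the published tables do not state the convention); Kappa =
(p_o − p_e)/(1 − p_e) with p_e from the confusion marginals; ROC built
from the distinct score thresholds, AUC by trapezoidal integration, which
equals pair-counting with ties credited ½. The test suite checks every
metric against independent brute-force oracles (and sklearn) on hundreds
of random small cases at 1e-9. Degenerate single-class truth makes AUC
undefined; it is reported as `None`, never silently as 0 or 0.5.

## Controller and plant

One control step corresponds to one decoder epoch hop (0.25 s). The intent
branch: s_t = 1 with P_min ≤ P_t < P_max → pressurize (+ΔP target);
s_t = 1 with P_t ≥ P_max → vacuum pump; s_t = 0 → pumps off (or vent,
`rest_behavior: hold | vent` — both published descriptions of the rest
branch are exposed). A safety layer runs after the branch: P_t > P_max
vents and enters an absorbing `vented_stopped` state cleared only by
`reset`, which also re-derives P_min from the sensor reading at reset
time; P_t < P_min opens the vent to stabilize upward. The lower bound of
the pressurize branch is inclusive: P_min is defined as the *initial*
sensor reading, so a strict inequality could never fire from the start
state and the loop would deadlock; inclusivity preserves liveness while
changing behavior only on the measure-zero boundary. The pressurize/vacuum
pumps are mutually exclusive by construction (the command type rejects
both-on).

The plant is first-order: ±`gain` kPa per commanded step, a bounded leak
toward ambient, exponential relaxation toward ambient while venting
(`vent_retain` per step), Gaussian sensor noise. ΔP = 5, P_max = 50,
gain = 2 kPa are simulator conventions — no pressure numbers are published
— and live in config. Under constant intent the closed loop regulates in
the band [P_max − gain − ΔP, P_max + gain] (bang-bang alternation), and
with zero sensor noise pressure can never exceed P_max + gain.

## Known limitations

- The synthetic generator's simplifications (above) mean reported
  accuracies characterize the pipeline, not human performance; per-subject
  results on real recordings depend on data that is not distributed.
- The NumPy decoder is single-threaded and CPU-sized (~50k parameters);
  it is not intended for large-scale training.
- EDF output is a minimal EDF+ writer (16-bit, 1 s records, whole-second
  recordings; non-integer durations are zero-padded to a full record);
  reading uses mne and accepts general EDF files.
- The controller models no valve/pump dynamics beyond first order and no
  glove kinematics; trajectories are control-logic validation, not
  hardware prediction.
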