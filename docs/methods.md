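# Methods

`seizkd` implements a causal, streaming student network for joint seizure
*detection* (is this 2-s window ictal?) and *prediction* (is a seizure
coming within the preictal horizon?), trained by multi-teacher knowledge
distillation, together with the preprocessing, alarm post-processing and
evaluation statistics that surround such a system, and a synthetic EEG
generator that makes the whole pipeline testable without clinical data.
This note records the model, its assumptions, the parameters that matter,
and the design choices made where the design was genuinely open.

## Signal model of the synthetic generator

Each channel is a sum of

1. **1/f background**: Fourier-shaped Gaussian noise with spectral exponent
   1, partially shared across channels — channel c mixes a private and a
   shared pink-noise source with weights `sqrt(1-m)` / `sqrt(m)`, where the
   synchrony fraction `m` (default 0.2) rises during the preictal period
   (by `synchrony_rise`, default +0.4);
2. **alpha rhythm**: a sinusoid drawn from 8–12 Hz with a random phase walk,
   amplitude 0.8 relative to the noise scale;
3. **preictal slow activity**: drifting 2 Hz and 5.5 Hz tones whose
   amplitude follows the preictal effect envelope (below), peaking at
   `preictal_lf_gain` (default 2.0) at seizure onset, while the alpha
   amplitude attenuates to `alpha_atten` (default 0.3) of its baseline;
4. **ictal discharge**: a ~3 Hz spike-and-wave train (sharp biphasic spike
   followed by a dominant half-sine slow wave, zero-mean per cycle) at
   `spike_gain` (default 5) times the noise scale, common to all channels.

The preictal effect envelope is a *state transition plus intensification*:
inside the `preictal_len` window before onset it jumps to `preictal_floor`
(default 0.5) and ramps linearly to 1 at onset.  The floor makes the
labelled preictal class separable from interictal throughout the labelled
interval — with a pure ramp from zero, the early preictal windows are
indistinguishable from interictal *in principle* (a band-power oracle tops
out near AUC 0.93), which would contradict the strong regime separation the
self-tests presume.  All effect sizes are free parameters of the simulation
with no empirical ground truth; they were fixed once from that oracle
separability check.

What the generator does **not** emulate: artifacts (EMG, electrode pops,
movement), inter-channel propagation delays, realistic topographies, state
changes of vigilance, or the statistics of any real data set.  Passing the
end-to-end tests therefore demonstrates that the pipeline recovers planted,
well-separated regime structure through the full causal machinery — not
clinical-grade performance.

## Preprocessing

0.5–40 Hz 4th-order Butterworth band-pass, applied forward-only (causal),
plus optional band-stop notches for mains harmonics; then per-channel mean
subtraction and per-channel unit-variance scaling.  The mean and variance
are per-recording statistics and are the only non-causal elements — they
stand in for the fixed gain calibration of a deployed amplifier.  Windows
are 2 s with 50 % overlap (one decision per second); consecutive seizures
closer than `merge_gap` (default 30 min, 5 min in the desk-scale profile)
are merged with the earlier onset kept.  Detection label: the window
overlaps an ictal interval.  Prediction label: positive if entirely inside
the preictal interval, negative if the whole window is at least
`interictal_gap` from every seizure, otherwise excluded.  Class balancing
(duplication + undersampling toward the geometric mean of the class counts)
applies to training data only.

## Student architecture

Per window: depthwise(k=3)+pointwise conv stem to 16 maps → two
inverted-residual MBConv blocks (expansion 4) to 24 and 32 channels, time
length preserved → average-pool with stride `fs·win/64` so every window
yields exactly 64 tokens at any sampling rate (8 samples/token at 256 Hz,
16 at 512 Hz) → linear to d=64 + fixed sinusoidal positions → 2 pre-norm
Transformer layers (4 heads, feed-forward 128, dropout 0.1) → token mean =
window feature `F_t`.  Across windows: a GRU consumes `F_t`; its hidden
state is written into a ring buffer of length L=10 (pointer modulo L,
cold-start fill on the first write) whose uniform mean is the temporal
summary; FiLM generators (2-layer MLPs, zero-initialised so modulation
starts as the exact identity) modulate the summary per channel — the
detection branch conditioned on the previous detection probability, the
prediction branch on the self-feedback prior `s_t = λ·s_{t-1} +
(1-λ)·y_det` (λ=0.9, stop-gradient, clipped to [0,1]) — and two 2-logit
softmax heads produce the outputs.  Strict causality holds by
construction, and per-step cost is independent of stream length.

Sizing: with the Transformer dimensions fixed (2×64/128/4 ≈ 67 k
parameters) and the conv front end ≈ 9 k, the recurrent tail is sized at
`gru_hidden=32`, `film_hidden=16`, bias-free attention projections, giving
**89,294** trainable parameters (0.0893 M; 0.357 MB at 32 bit) — inside
the intended 0.06–0.09 M / 0.24–0.36 MB envelope.  A 64-unit GRU would
push the total to ~0.112 M, outside it.

Numerical choices: GRU update-gate bias initialised to −1 so a fresh state
tracks its input (hidden states on long streams are otherwise prone to
freezing at a fixed point); dropout active only in training; inference is
deterministic; the SFPM is a plain numpy scalar so the stop-gradient is
structural.

## Teachers

Two trainable reference teachers give complementary supervision: a
*prediction* teacher (token embedding → Transformer encoder layer →
parallel LSTM‖GRU over tokens → sigmoid-gated convex fusion → linear head)
and a *detection* teacher (strided 1-D CNN → LSTM → single-query
self-attention pooling `α_j = softmax(q·k_j/√d_k)` → linear head).  At the
default width (d=128) the prediction teacher is ~6× the student; the
desk-scale profile uses d=64 for runtime.  Detection training uses
inverse-class-frequency-weighted cross-entropy; both use a chronological
25 % validation split with patience-10 early stopping, and are frozen
afterwards (pure functions; checksums asserted in tests).

## Distillation objective and training scheme

`L = α(CE_det + CE_pred) + β(KD_det + KD_pred) + γ·TimeReg` with defaults
α=1, β=0.5, γ=0.1, τ=2, alignment sub-weight 0.5 and prior-coefficient L2
weight 1e-4.  Each KD term is temperature-softened KL (scaled by τ²) plus
an MSE alignment between the post-FiLM branch feature and a trainable
linear projection of the teacher's penultimate feature, per-sample
down-weighted by teacher confidence (max softened probability, rescaled to
mean 1).  TimeReg matches the student's prediction-probability increments
to the teacher's over 64-window contiguous chunks.  One teacher per task is
drawn uniformly per batch; windows lacking a prediction label contribute
zero to every prediction term.

The training loop is built for a single CPU and a recurrent model:

* **Gradient truncation.** Gradients stop at each window boundary
  (truncated backpropagation, horizon 1).  Chunk gradients are computed by
  unrolling the recurrence once without a tape to record each step's state
  constants, then rebuilding all steps in one batched differentiable pass —
  exact under the truncation (verified to float32 epsilon against the
  sequential loop).
* **Two batch kinds per epoch.** Class-balanced single-window batches
  (8×32 windows) carry most of the supervision; two 64-step stream chunks
  (drawn from ictal-transition and preictal pools) expose the heads to
  evolved ring-buffer/GRU states and carry TimeReg.
* **Conditioning decorrelation.** At training-batch starts the FiLM
  conditioning scalars (previous detection probability, SFPM prior) are
  drawn uniformly in [0,1]: on contiguous streams their true values
  correlate with the labels, and training on them lets the modulation
  generators latch onto the feedback signal instead of the EEG — the
  runaway self-feedback the amplitude regulariser exists to suppress.
* **Model selection.** Early stopping tracks the *supervised* loss
  component on the chronologically last quarter of each chunk pool
  (distillation terms measure teacher match, not generalisation);
  best-epoch weights are restored.
* **Stream-dynamics gate.** Occasional runs still collapse into frozen
  stream dynamics (near-constant probabilities on long streams).  This is
  visible on the training streams, so after training the harness streams
  one training segment and retrains once with a different initialisation if
  its detection AUC is below 0.9.  No test data is involved.

Adam is the optimizer throughout (global-norm gradient clip 5).  The
published configuration (lr 0.01, batch 32) is the library default; the
desk-scale profile uses lr 0.003, which is stabler for the very short
schedules used there.

## Alarms and evaluation

Prediction alarms: k-of-n voting (k=8, n=10 by default) over the 1-Hz
probability stream with a refractory period (default = SOP); warm-up
windows (the first L steps) are never counted positive but remain in the
FPR denominator.  Detection alarms: trailing 5-s moving average against a
threshold.  An alarm is valid iff a seizure onset falls in
`[alarm+SPH, alarm+SPH+SOP)`; sensitivity is the fraction of events hit,
FPR/h counts invalid alarms over the full unedited duration, and
significance uses the standard random-predictor construction
`P = 1 − exp(−FPR·SOP)` with a binomial tail over events.  Evaluation is
leave-one-pair-out per subject: each merged seizure contributes one pair
(preictal block + ictal interval, plus an equal-duration interictal block
carved deterministically from the regions far from every seizure);
per-subject metrics are unweighted means over folds and cohort metrics
unweighted means over subjects.  Window-level AUC uses midrank ties; the
evaluation partition is never rebalanced.

## Problem sizes of the bundled studies

The desk-scale profile used by the self-tests and examples keeps the full
channel count (22) and sampling rate (256 Hz) but shortens the horizons:
50-minute recordings with three 30-s seizures per subject, a 5-minute
preictal/interictal horizon, 1-minute SPH and 5-minute SOP; training
budgets of 5 epochs × (8 window batches + 2 stream chunks) for the student
and 4 epochs on ≤128 balanced windows per teacher.  The cross-validated
study runs 4 subjects × 3 pairs × 3 training seeds; the distillation-mode
comparison runs 5 seeds × 3 modes on one subject at a further reduced
budget.  These sizes are the package's standard small-study configuration;
all horizons scale back to the clinical defaults (30-minute preictal/SOP,
5-minute SPH) through `WindowingSpec`/`EvalProtocol`.

## Known limitations

* The numpy autodiff engine is single-threaded and tuned for these model
  sizes; it is not a general-purpose deep-learning stack.
* Gradient truncation at window boundaries means long-range credit
  assignment across windows relies on the architecture (ring buffer, GRU)
  rather than backpropagation through time.
* Only two reference teachers are implemented; the registry accepts
  additional ones behind the same interface, but none of the published
  eight-teacher zoo is reproduced at full fidelity.
* Synthetic-data results bound what the pipeline can recover under planted
  structure; no claim transfers to clinical recordings without retraining
  and re-evaluation on real EEG.
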