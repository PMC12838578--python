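# Example run configuration for the `seizkd` CLI.
# Any omitted key falls back to the documented default; dotted-key
# overrides on the command line (--set section.key=value) win over this file.

seed: 0
n_subjects: 4
mode: multi            # multi | single_pred | single_det | none

synth:                 # synthetic cohort generator
  n_channels: 22
  fs: 256.0
  duration: 3000.0
  preictal_len: 300.0
  spikewave_hz: 3.0
  spike_gain: 5.0
  preictal_lf_gain: 2.0
  synchrony_mix: 0.2
  noise_scale: 10.0

filter:
  band: [0.5, 40.0]
  notch_bands: []      # e.g. [[57.0, 63.0], [117.0, 123.0]] for 60 Hz mains
  order: 4
  causal: true

windowing:
  win_len: 2.0
  overlap: 0.5
  preictal_len: 300.0  # 1800 for the clinical 30-min convention
  interictal_gap: 300.0
  merge_gap: 300.0
  sph: 60.0
  sop: 300.0

model:                 # student architecture
  d_model: 64
  n_layers: 2
  ff_dim: 128
  n_heads: 4
  gru_hidden: 32
  buffer_len: 10
  sfpm_lambda: 0.9

weights:               # training objective
  alpha: 1.0
  beta: 0.5
  gamma: 0.1
  tau: 2.0
  align_w: 0.5
  prior_reg_w: 1.0e-4

budget:                # desk-scale training sizes
  teacher_epochs: 4
  student_epochs: 5
  window_batches: 8
  chunk_batches: 2
  lr: 0.003

policy:                # alarm post-processing
  k: 8
  n: 10
  prob_threshold: 0.5
  refractory: 300.0
  smooth_len: 5.0
  det_threshold: 0.5

protocol:
  sph: 60.0
  sop: 300.0
  alpha: 0.05
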