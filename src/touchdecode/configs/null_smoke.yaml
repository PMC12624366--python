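# Noise-only smoke run: no injected effects, so every decoder must land at
# its chance level.  Scaled down (12 base videos, 4 subjects, 32 channels,
# 512 Hz) to finish in well under a minute.
seed: 7
output_dir: touchdecode_null_smoke
design:
  n_base: 12
  category_spec: {object_type: 6, material: 4, touch_type: 3}
simulate:
  n_subjects: 4
  n_sequences: 4
  repetitions: 1
  sampling_rate: 512.0
  n_channels: 32
  noise: {white_sd: 1.0, pink_scale: 1.0, pink_exponent: 1.0}
  effects: []
decode:
  features: [orientation, valence]
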