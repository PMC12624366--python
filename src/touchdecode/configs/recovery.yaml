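# Parameter-recovery run: a strong four-class orientation effect switched
# on at 100 ms for 150 ms.  The group evidence curve should report an onset
# within 25 ms of the injected 100 ms.
seed: 11
output_dir: touchdecode_recovery
design:
  n_base: 8
  category_spec: {object_type: 4, material: 3, touch_type: 2}
simulate:
  n_subjects: 6
  n_sequences: 4
  repetitions: 1
  sampling_rate: 512.0
  n_channels: 32
  noise: {white_sd: 1.0, pink_scale: 1.0, pink_exponent: 1.0}
  effects:
    - feature: orientation
      kind: categorical-pattern
      onset: 0.10
      duration: 0.15
      amplitude: 8.0
      seed: 5
decode:
  features: [orientation]
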