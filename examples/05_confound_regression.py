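"""Remove visual-confound variance from the decoded signal.

A continuous effect encodes the arousal rating of each stimulus.  When the
per-stimulus confound passed to the decoder IS that rating, fold-wise OLS
residualization removes exactly the variance the decoder would otherwise
exploit, and the cross-validated prediction correlation collapses to
chance.  Also shown: the image-feature helpers (entropy, mean luminance)
that build real confound matrices from stimulus frames.
"""

import numpy as np

import touchdecode as td
from touchdecode import simulate as sim
from touchdecode.confound_features import (
    assemble_confounds, frame_entropy, frame_mean_luminance,
)
from touchdecode.decoding import decode_time_continuous, trial_labels
from touchdecode.preprocessing import preprocess

rng = np.random.default_rng(0)
frame = rng.integers(0, 256, (144, 256, 3)).astype(np.uint8)
print(f"example frame: entropy {frame_entropy(frame):.2f} bits, "
      f"mean luminance {frame_mean_luminance(frame):.1f}")

design = td.build_design(8, {"object_type": 4, "material": 3, "touch_type": 2}, seed=3)
n = len(design)
confounds = assemble_confounds(design, rng.uniform(4, 8, n), rng.uniform(50, 200, n))
print(f"confound matrix: {confounds.shape[0]} stimuli x "
      f"{confounds.shape[1] - 1} features (deep_pc1 {confounds.attrs['deep_pc1']})")

effect = sim.EffectSpec("arousal", kind="continuous-amplitude", onset=0.10,
                        duration=0.15, amplitude=5.0, seed=2)
plan = sim.generate_sequence_plan(design, n_sequences=4, repetitions=1,
                                  targets_range=(1, 2), min_gap=2, seed=5)
raw = sim.simulate_subject(design, plan, effects=[effect],
                           noise=sim.NoiseSpec(1.0, 1.0), seed=6,
                           sampling_rate=512.0, n_channels=32)
ep = preprocess(raw)
ratings = trial_labels(ep, design, "arousal")

plain = decode_time_continuous(ep, ratings)
nt = ~ep.trials["is_target"].to_numpy()
leaky_confound = ratings.astype(float)[nt, None]
controlled = decode_time_continuous(ep, ratings, confounds=leaky_confound)

window = (plain.axis >= 0.14) & (plain.axis <= 0.22)
print(f"\nmean prediction correlation at the effect latency, no control: "
      f"{plain.fold_mean[window].mean():.2f}")
print(f"after residualizing the rating-valued confound: "
      f"{controlled.fold_mean[window].mean():.2f} (chance 0)")
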