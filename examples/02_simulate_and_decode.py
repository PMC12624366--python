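"""Simulate a small cohort with a known effect and recover its onset.

A four-class hand-orientation effect is switched on 100 ms after stimulus
onset for 150 ms.  Each subject's epochs are preprocessed (common average
reference, 0.1-100 Hz band-pass, 200 Hz resampling, baseline correction,
50 ms smoothing) and decoded with a sliding shrinkage-LDA estimator under
leave-one-sequence-out cross-validation; the group Bayes-factor curve
(half-Cauchy prior r = 0.707, excluded interval d in [0, 0.5]) should
report a sustained-evidence onset near the injected 100 ms.
"""

import numpy as np

import touchdecode as td
from touchdecode import simulate as sim
from touchdecode.decoding import decode_time_categorical, trial_labels
from touchdecode.inference import evidence_curve
from touchdecode.preprocessing import preprocess

design = td.build_design(8, {"object_type": 4, "material": 3, "touch_type": 2}, seed=3)
effect = sim.EffectSpec("orientation", onset=0.10, duration=0.15, amplitude=8.0, seed=5)

results = []
for si, seed in enumerate(sim.cohort_seeds(77, 6)):
    plan = sim.generate_sequence_plan(design, n_sequences=4, repetitions=1,
                                      targets_range=(1, 2), min_gap=2, seed=seed)
    raw = sim.simulate_subject(design, plan, effects=[effect],
                               noise=sim.NoiseSpec(white_sd=1.0, pink_scale=1.0),
                               seed=seed, sampling_rate=512.0)
    ep = preprocess(raw)
    res = decode_time_categorical(ep, trial_labels(ep, design, "orientation"),
                                  subject_id=si)
    results.append(res)
    print(f"subject {si}: peak balanced accuracy "
          f"{res.fold_mean.max():.2f} (chance {res.chance})")

curve = evidence_curve(results)
peak_i = int(np.argmax(curve.mean_metric))
print(f"\ngroup peak accuracy {curve.mean_metric[peak_i]:.2f} "
      f"at {1000 * curve.axis[peak_i]:.0f} ms")
print(f"sustained-evidence onset (BF > 6): {1000 * curve.onset:.0f} ms "
      f"(injected: 100 ms)")
print(f"metric peak: {1000 * curve.peak:.0f} ms "
      f"(envelope peak of the injected effect: 175 ms)")
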