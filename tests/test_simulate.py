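"""Sequence plans, confound simulation, and epoch generation."""

import numpy as np
import pytest

import touchdecode as td
from touchdecode import simulate as sim
from touchdecode.simulate import raised_cosine_envelope, validate_plan


class TestSequencePlan:
    def test_full_scale_defaults(self):
        design = td.build_design(90, seed=0)
        plan = sim.generate_sequence_plan(design, seed=1)
        nt = plan[~plan["is_target"]]
        assert plan["sequence_index"].nunique() == 32
        assert len(nt) == 2880
        assert (nt["stimulus_id"].value_counts() == 8).all()
        validate_plan(plan, design, repetitions=8)

    def test_target_constraints_full_scale(self):
        design = td.build_design(90, seed=0)
        plan = sim.generate_sequence_plan(design, seed=2)
        for _, grp in plan.groupby("sequence_index"):
            flags = grp.sort_values("position")["is_target"].to_numpy()
            n_targets = flags.sum()
            assert 1 <= n_targets <= 9
            tpos = np.flatnonzero(flags)
            if len(tpos) > 1:
                assert (np.diff(tpos) - 1).min() >= 12

    def test_arithmetic_infeasibility_raises(self, small_design):
        # 4 sequences x 8 base videos != 2 repetitions x 32 stimuli
        with pytest.raises(ValueError, match="infeasible"):
            sim.generate_sequence_plan(
                small_design, n_sequences=4, repetitions=2, seed=0
            )

    def test_invariants_hold_over_many_seeds(self, small_design):
        for seed in range(100):
            plan = sim.generate_sequence_plan(
                small_design, n_sequences=4, repetitions=1,
                targets_range=(1, 2), min_gap=2, seed=seed,
            )
            validate_plan(
                plan, small_design, repetitions=1,
                targets_range=(1, 2), min_gap=2,
            )

    def test_deterministic_under_fixed_seed(self, small_design):
        p1 = sim.generate_sequence_plan(small_design, 4, 1, (1, 2), 2, seed=9)
        p2 = sim.generate_sequence_plan(small_design, 4, 1, (1, 2), 2, seed=9)
        assert p1.equals(p2)


class TestConfounds:
    def test_zero_spec_is_near_orthogonal(self):
        design = td.build_design(90, seed=0)
        conf = sim.simulate_confounds(design, seed=1)
        assert len(conf) == 360
        for col in ("valence", "arousal", "threat", "pain"):
            for c in ("entropy", "mean_luminance", "deep_pc1"):
                r = np.corrcoef(conf[c], design[col])[0, 1]
                assert abs(r) < 0.1

    def test_requested_correlation_is_realized(self):
        design = td.build_design(90, seed=0)
        conf = sim.simulate_confounds(
            design, {"mean_luminance": ("valence", 0.5)}, seed=2
        )
        r = np.corrcoef(conf["mean_luminance"], design["valence"])[0, 1]
        assert abs(r - 0.5) <= 0.1

    def test_deterministic_and_shaped(self, small_design):
        c1 = sim.simulate_confounds(small_design, seed=5)
        c2 = sim.simulate_confounds(small_design, seed=5)
        assert c1.equals(c2)
        assert len(c1) == len(small_design)

    def test_constant_feature_is_unreachable(self):
        design = td.build_design(
            4, {"object_type": 1, "material": 1, "touch_type": 1}, seed=0
        )
        with pytest.raises(ValueError, match="constant feature"):
            sim.simulate_confounds(
                design, {"entropy": ("material", 0.5)}, seed=0
            )


class TestSimulateSubject:
    def test_null_construction_is_all_zero(self, small_design, small_plan):
        ep = sim.simulate_subject(
            small_design, small_plan,
            effects=[sim.EffectSpec("hand", amplitude=0.0)],
            noise=sim.NoiseSpec(0.0, 0.0),
            seed=0, sampling_rate=256.0, n_channels=8,
        )
        assert not ep.data.any()
        assert ep.n_samples == int(round(0.9 * 256))

    def test_categorical_class_difference_matches_generative_equation(
        self, small_design, small_plan
    ):
        eff = sim.EffectSpec(
            "hand", onset=0.1, duration=0.2, amplitude=3.0, seed=4
        )
        ep = sim.simulate_subject(
            small_design, small_plan, effects=[eff],
            noise=sim.NoiseSpec(0.0, 0.0), seed=0,
            sampling_rate=256.0, n_channels=8,
        )
        env = raised_cosine_envelope(ep.time, eff.onset, eff.duration)
        tpk = int(np.argmax(env))
        labels = td.trial_labels(ep, small_design, "hand")
        nt = ~ep.trials["is_target"].to_numpy()
        mean_left = ep.data[nt & (labels == "left")][:, :, tpk].mean(axis=0)
        mean_right = ep.data[nt & (labels == "right")][:, :, tpk].mean(axis=0)
        from touchdecode.simulate import effect_patterns
        pats = effect_patterns(eff, ep.channel_names, ["left", "right"])
        expected = 3.0 * env[tpk] * (pats["left"] - pats["right"])
        np.testing.assert_allclose(mean_left - mean_right, expected, atol=1e-12)

    def test_no_effect_contribution_before_onset(self, small_design, small_plan):
        eff = sim.EffectSpec("hand", onset=0.2, duration=0.1, amplitude=5.0)
        ep = sim.simulate_subject(
            small_design, small_plan, effects=[eff],
            noise=sim.NoiseSpec(0.0, 0.0), seed=0,
            sampling_rate=256.0, n_channels=8,
        )
        pre = ep.time < 0.2
        assert not ep.data[:, :, pre].any()

    def test_unknown_feature_raises(self, small_design, small_plan):
        with pytest.raises(ValueError, match="unknown design feature"):
            sim.simulate_subject(
                small_design, small_plan,
                effects=[sim.EffectSpec("not_a_column")],
                seed=0, sampling_rate=256.0, n_channels=8,
            )

    def test_empty_channel_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sim.EffectSpec("hand", channels=())


class TestCohort:
    def test_subjects_are_distinct_but_reproducible(self, small_design):
        kwargs = dict(
            plan_kwargs=dict(
                n_sequences=4, repetitions=1, targets_range=(1, 2), min_gap=2
            ),
            sampling_rate=256.0, n_channels=8,
        )
        c1 = sim.simulate_cohort(small_design, 3, seed=21, **kwargs)
        c2 = sim.simulate_cohort(small_design, 3, seed=21, **kwargs)
        assert len(c1) == 3
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(c1[0].data, c1[1].data)
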