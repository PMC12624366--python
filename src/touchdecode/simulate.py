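"""Synthetic cohorts: sequence plans, confound matrices, and EEG epoch simulation.

The generator emulates the rapid-serial design of the study it models:
32 presentation sequences per subject, each containing every base video
exactly once (one of its four orientations), so that over all sequences
each of the 360 oriented stimuli is seen exactly 8 times (2880 non-target
trials).  Target trials (touch to a white object, counted by the subject
and excluded from analysis) are interleaved with 1-9 per sequence and at
least 12 non-targets between consecutive targets.

Epochs span -100..800 ms around stimulus onset at 2048 Hz.  Simulated data
are a sum of declaratively specified effects (class-specific spatial
patterns with a raised-cosine temporal envelope, rating-proportional
amplitude coding, or band-limited carriers) plus 1/f-shaped and white
noise.  With an empty effect list the cohort is an exact null: epochs carry
no stimulus information and every decoder must average to its chance level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONTINUOUS_COLUMNS, FACTOR_COLUMNS
from .epochs import EpochArray
from .searchlight import load_montage

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "generate_sequence_plan",
    "validate_plan",
    "simulate_confounds",
    "simulate_subject",
    "simulate_cohort",
    "raised_cosine_envelope",
    "pink_noise",
]


@dataclass(frozen=True)
class EffectSpec:
    """Declarative description of one injected effect.

    kind:
      - ``categorical-pattern``: each level of ``feature`` gets its own
        unit-norm spatial pattern, added as amplitude * pattern * envelope(t).
      - ``continuous-amplitude``: a single pattern whose amplitude scales
        with the standardized rating of the presented stimulus.
      - ``band-limited``: like categorical-pattern but the envelope is
        multiplied by a sinusoid at ``carrier_hz``.
    """

    feature: str
    kind: str = "categorical-pattern"
    onset: float = 0.10  # s
    duration: float = 0.15  # s
    amplitude: float = 1.0  # microvolts at envelope peak
    channels: tuple[str, ...] | None = None  # None = all channels
    carrier_hz: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError("effect onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("effect duration must be > 0")
        if self.amplitude < 0:
            raise ValueError("effect amplitude must be >= 0")
        if self.kind not in (
            "categorical-pattern", "continuous-amplitude", "band-limited"
        ):
            raise ValueError(f"unknown effect kind: {self.kind!r}")
        if self.kind == "band-limited" and not self.carrier_hz:
            raise ValueError("band-limited effect needs carrier_hz")
        if self.channels is not None and len(self.channels) == 0:
            raise ValueError("effect channel subset is empty")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: white Gaussian + spectrally shaped 1/f background."""

    white_sd: float = 1.0  # microvolts
    pink_scale: float = 1.0  # microvolts (RMS of the shaped component)
    pink_exponent: float = 1.0  # power ~ 1/f**exponent
    subject_gain_sd: float = 0.0  # relative per-subject gain spread

    def __post_init__(self):
        for name in ("white_sd", "pink_scale", "pink_exponent", "subject_gain_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# sequence plans
# ---------------------------------------------------------------------------

def generate_sequence_plan(
    design: pd.DataFrame,
    n_sequences: int = 32,
    repetitions: int = 8,
    targets_range: tuple[int, int] = (1, 9),
    min_gap: int = 12,
    seed: int | None = None,
) -> pd.DataFrame:
    """Build a counterbalanced trial plan.

    Every sequence presents each base video exactly once, choosing one of
    its four orientations such that over all sequences each oriented
    stimulus appears exactly ``repetitions`` times.  This requires
    ``n_sequences == 4 * repetitions``.  Target trials are interleaved with
    a per-sequence count drawn from ``targets_range`` (clipped to what the
    gap constraint allows) and at least ``min_gap`` non-targets between
    consecutive targets.

    Returns a frame with columns ``sequence_index``, ``position``,
    ``stimulus_id``, ``is_target``.
    """
    rng = np.random.default_rng(seed)
    base_ids = np.sort(design["base_video_id"].unique())
    n_base = len(base_ids)
    n_stimuli = len(design)
    if n_sequences * n_base != repetitions * n_stimuli:
        raise ValueError(
            "infeasible sequence plan: n_sequences * base_videos "
            f"({n_sequences} * {n_base}) != repetitions * stimuli "
            f"({repetitions} * {n_stimuli})"
        )
    if n_sequences % 4 != 0:
        raise ValueError(
            "infeasible sequence plan: n_sequences must be a multiple of 4 "
            "to counterbalance the four orientations"
        )
    t_min, t_max = targets_range
    if t_min < 0 or t_max < t_min:
        raise ValueError("invalid targets_range")
    # With g targets, (g-1) inter-target gaps of >= min_gap non-targets must
    # fit among the n_base non-targets.
    feasible_max = n_base // min_gap + 1 if min_gap > 0 else t_max
    t_max_eff = min(t_max, feasible_max)
    if t_min > t_max_eff:
        raise ValueError(
            f"infeasible sequence plan: minimum {t_min} targets cannot "
            f"respect a gap of {min_gap} among {n_base} non-targets"
        )

    # Orientation assignment: per base video a shuffled length-n_sequences
    # vector holding each of its 4 oriented stimulus ids `repetitions` times.
    per_base_rows = {
        b: design.loc[design["base_video_id"] == b, "stimulus_id"].tolist()
        for b in base_ids
    }
    assign = {}
    for b in base_ids:
        pool = np.repeat(np.arange(4), repetitions)
        assign[b] = rng.permutation(pool)

    rows = []
    for s in range(n_sequences):
        stim_ids = [per_base_rows[b][assign[b][s]] for b in base_ids]
        order = rng.permutation(n_base)
        stim_ids = [stim_ids[i] for i in order]
        n_targets = int(rng.integers(t_min, t_max_eff + 1))
        # Gap layout: g0 non-targets, target, (min_gap + e1) non-targets,
        # target, ..., tail.  Distribute the slack uniformly at random.
        slack = n_base - max(0, n_targets - 1) * min_gap
        cuts = np.sort(rng.integers(0, slack + 1, size=n_targets))
        positions_before = [  # number of non-targets before each target
            int(cuts[i]) + i * min_gap for i in range(n_targets)
        ]
        seq = []
        prev = 0
        for k, nbefore in enumerate(positions_before):
            seq.extend(stim_ids[prev:nbefore])
            seq.append(f"target{k:02d}")
            prev = nbefore
        seq.extend(stim_ids[prev:])
        for pos, sid in enumerate(seq):
            rows.append(
                {
                    "sequence_index": s,
                    "position": pos,
                    "stimulus_id": sid,
                    "is_target": sid.startswith("target"),
                }
            )
    plan = pd.DataFrame(rows)
    validate_plan(plan, design, repetitions=repetitions,
                  targets_range=(t_min, t_max), min_gap=min_gap)
    return plan


def validate_plan(
    plan: pd.DataFrame,
    design: pd.DataFrame,
    repetitions: int,
    targets_range: tuple[int, int] = (1, 9),
    min_gap: int = 12,
) -> None:
    """Assert the structural invariants of a sequence plan."""
    nt = plan[~plan["is_target"]]
    n_base = design["base_video_id"].nunique()
    per_seq = nt.groupby("sequence_index").size()
    if not (per_seq == n_base).all():
        raise ValueError("a sequence does not hold one trial per base video")
    counts = nt["stimulus_id"].value_counts()
    if set(counts.index) != set(design["stimulus_id"]):
        raise ValueError("plan stimuli do not match the design")
    if not (counts == repetitions).all():
        raise ValueError("a stimulus does not appear exactly `repetitions` times")
    base_of = design.set_index("stimulus_id")["base_video_id"]
    per_seq_base = nt.assign(base=nt["stimulus_id"].map(base_of)).groupby(
        "sequence_index"
    )["base"].nunique()
    if not (per_seq_base == n_base).all():
        raise ValueError("a base video repeats within a sequence")
    for s, grp in plan.groupby("sequence_index"):
        flags = grp.sort_values("position")["is_target"].to_numpy()
        n_targets = int(flags.sum())
        if not (targets_range[0] <= n_targets <= targets_range[1]):
            raise ValueError(f"sequence {s} has {n_targets} targets")
        tpos = np.flatnonzero(flags)
        if len(tpos) > 1:
            gaps = np.diff(tpos) - 1  # non-targets strictly between
            if gaps.min() < min_gap:
                raise ValueError(
                    f"sequence {s} violates the >= {min_gap} non-target gap"
                )


# ---------------------------------------------------------------------------
# confounds
# ---------------------------------------------------------------------------

_CONFOUND_DEFS = {
    # name -> (location, scale) used to put draws on plausible units
    "entropy": (6.5, 0.7),  # bits
    "mean_luminance": (120.0, 30.0),  # 8-bit brightness units
    "deep_pc1": (0.0, 1.0),  # arbitrary units
}


def _numeric_feature(design: pd.DataFrame, feature: str) -> np.ndarray:
    if feature in CONTINUOUS_COLUMNS:
        return design[feature].to_numpy(float)
    if feature in FACTOR_COLUMNS:
        return pd.Categorical(design[feature]).codes.astype(float)
    raise ValueError(f"unknown design feature: {feature!r}")


def simulate_confounds(
    design: pd.DataFrame,
    correlation_spec: dict[str, tuple[str, float]] | None = None,
    seed: int | None = None,
    max_retries: int = 50,
    tolerance: float = 0.1,
) -> pd.DataFrame:
    """Draw a per-stimulus visual-confound matrix (entropy, luminance, deep_pc1).

    ``correlation_spec`` maps a confound column to ``(design_feature, rho)``;
    the realized sample correlation is checked to lie within ``tolerance``
    of the request and redrawn (bounded retries) otherwise.  Unspecified
    confounds are drawn independently and checked to be near-orthogonal to
    every design column.  Deterministic under a fixed seed.
    """
    spec = dict(correlation_spec or {})
    for name, (feat, rho) in spec.items():
        if name not in _CONFOUND_DEFS:
            raise ValueError(f"unknown confound: {name!r}")
        if not -1 < rho < 1:
            raise ValueError("requested correlations must lie in (-1, 1)")
        _numeric_feature(design, feat)  # validates the feature name
    rng = np.random.default_rng(seed)
    n = len(design)
    check_cols = [
        c for c in CONTINUOUS_COLUMNS + FACTOR_COLUMNS if c in design.columns
    ]
    out = {}
    for name, (loc, scale) in _CONFOUND_DEFS.items():
        target = spec.get(name)
        if target is None:
            # Unconstrained confound: take the most orthogonal of a few
            # independent draws (a hard bound is only meaningful for
            # requested correlations).
            best, best_dev = None, np.inf
            for _ in range(max_retries):
                z = rng.standard_normal(n)
                dev = max(
                    (
                        abs(np.corrcoef(z, _numeric_feature(design, c))[0, 1])
                        for c in check_cols
                        if np.ptp(_numeric_feature(design, c)) > 0
                    ),
                    default=0.0,
                )
                if dev < best_dev:
                    best, best_dev = z, dev
                if dev < tolerance:
                    break
            z = best
        else:
            feat, rho = target
            fv = _numeric_feature(design, feat)
            if np.ptp(fv) == 0:
                raise ValueError(
                    f"cannot correlate {name} with constant feature {feat}"
                )
            fz = (fv - fv.mean()) / fv.std()
            for _ in range(max_retries):
                z = rho * fz + math.sqrt(1 - rho**2) * rng.standard_normal(n)
                if abs(np.corrcoef(z, fv)[0, 1] - rho) <= tolerance:
                    break
            else:
                raise ValueError(
                    f"could not realize the requested correlation for {name!r} "
                    f"within {max_retries} draws (feature too coarse?)"
                )
        out[name] = loc + scale * z
    conf = pd.DataFrame(out)
    conf.insert(0, "stimulus_id", design["stimulus_id"].to_numpy())
    return conf


# ---------------------------------------------------------------------------
# epoch simulation
# ---------------------------------------------------------------------------

def raised_cosine_envelope(time: np.ndarray, onset: float, duration: float) -> np.ndarray:
    """Half-cosine (raised-cosine) bump: 0 outside [onset, onset+duration),
    rising to 1 at the midpoint.  Strictly causal: zero before onset."""
    time = np.asarray(time, float)
    env = np.zeros_like(time)
    inside = (time >= onset) & (time < onset + duration)
    phase = (time[inside] - onset) / duration
    env[inside] = 0.5 * (1.0 - np.cos(2 * np.pi * phase))
    return env


def pink_noise(
    rng: np.random.Generator, shape: tuple[int, ...], fs: float, exponent: float = 1.0
) -> np.ndarray:
    """1/f**exponent-power noise via FFT-shaped white noise, unit RMS.

    The last axis is time.  DC is zeroed; the amplitude spectrum is scaled
    by f**(-exponent/2).
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * gain, n=n, axis=-1)
    rms = shaped.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return shaped / rms


def _unit_pattern(rng: np.random.Generator, n_channels: int, idx: np.ndarray) -> np.ndarray:
    p = np.zeros(n_channels)
    v = rng.standard_normal(len(idx))
    p[idx] = v / np.linalg.norm(v)
    return p


def effect_patterns(
    effect: EffectSpec, channel_names: list[str], levels: list | None
) -> dict | np.ndarray:
    """Deterministic unit-norm spatial pattern(s) for an effect.

    Categorical kinds get one pattern per level (keyed dict); the
    continuous kind gets a single pattern.  Patterns depend only on the
    effect's own seed, so they are identical across subjects.
    """
    if effect.channels is None:
        idx = np.arange(len(channel_names))
    else:
        missing = [c for c in effect.channels if c not in channel_names]
        if missing:
            raise ValueError(f"effect channels not in montage: {missing}")
        idx = np.array([channel_names.index(c) for c in effect.channels])
    rng = np.random.default_rng(effect.seed)
    if effect.kind == "continuous-amplitude":
        return _unit_pattern(rng, len(channel_names), idx)
    return {
        lev: _unit_pattern(rng, len(channel_names), idx) for lev in levels
    }


def simulate_subject(
    design: pd.DataFrame,
    plan: pd.DataFrame,
    effects: list[EffectSpec] = (),
    noise: NoiseSpec = NoiseSpec(),
    montage: pd.DataFrame | None = None,
    seed: int | None = None,
    sampling_rate: float = 2048.0,
    tmin: float = -0.1,
    tmax: float = 0.8,
    n_channels: int | None = None,
) -> EpochArray:
    """Simulate one subject's epoched EEG for a sequence plan.

    data = sum(effects) + 1/f noise + white noise, per trial.  Target
    trials receive noise only (they are excluded downstream anyway).  The
    epoch window is half-open [tmin, tmax) so the sample count is integral
    at both 2048 Hz and 200 Hz.
    """
    rng = np.random.default_rng(seed)
    if montage is None:
        montage = load_montage()
    names = list(montage["name"])
    if n_channels is not None:
        if n_channels > len(names):
            raise ValueError("montage has fewer channels than requested")
        names = names[:n_channels]
    n_ch = len(names)
    n_samples = int(round((tmax - tmin) * sampling_rate))
    time = tmin + np.arange(n_samples) / sampling_rate

    stim_info = design.set_index("stimulus_id")
    for eff in effects:
        if eff.feature not in design.columns:
            raise ValueError(f"unknown design feature: {eff.feature!r}")

    trials = plan[["sequence_index", "position", "stimulus_id", "is_target"]].copy()
    n_trials = len(trials)
    data = np.zeros((n_trials, n_ch, n_samples))

    nontarget = ~trials["is_target"].to_numpy(bool)
    stim_ids = trials["stimulus_id"].to_numpy()

    for eff in effects:
        env = eff.amplitude * raised_cosine_envelope(time, eff.onset, eff.duration)
        if eff.kind == "band-limited":
            carrier = np.sin(2 * np.pi * eff.carrier_hz * (time - eff.onset))
            env = env * carrier
        if eff.kind == "continuous-amplitude":
            pattern = effect_patterns(eff, names, None)
            vals = stim_info[eff.feature].astype(float)
            mu, sd = vals.mean(), vals.std()
            if sd == 0:
                raise ValueError(f"feature {eff.feature!r} has zero variance")
            for i in np.flatnonzero(nontarget):
                z = (float(stim_info.loc[stim_ids[i], eff.feature]) - mu) / sd
                data[i] += z * pattern[:, None] * env[None, :]
        else:
            levels = sorted(stim_info[eff.feature].unique())
            patterns = effect_patterns(eff, names, levels)
            for i in np.flatnonzero(nontarget):
                lev = stim_info.loc[stim_ids[i], eff.feature]
                data[i] += patterns[lev][:, None] * env[None, :]

    if noise.pink_scale > 0:
        data += noise.pink_scale * pink_noise(
            rng, (n_trials, n_ch, n_samples), sampling_rate, noise.pink_exponent
        )
    if noise.white_sd > 0:
        data += noise.white_sd * rng.standard_normal((n_trials, n_ch, n_samples))
    if noise.subject_gain_sd > 0:
        data *= 1.0 + noise.subject_gain_sd * rng.standard_normal()

    return EpochArray(
        data=data,
        sampling_rate=sampling_rate,
        time=time,
        channel_names=names,
        trials=trials.drop(columns="position"),
        seed=seed,
        meta={"n_effects": len(effects)},
    )


def simulate_cohort(
    design: pd.DataFrame,
    n_subjects: int,
    effects: list[EffectSpec] = (),
    noise: NoiseSpec = NoiseSpec(),
    seed: int | None = None,
    plan_kwargs: dict | None = None,
    **subject_kwargs,
) -> list[EpochArray]:
    """Simulate an independent-subject cohort.

    Per-subject seeds are spawned from the master seed; each subject gets a
    freshly generated sequence plan.  An empty effect list yields a null
    cohort (chance-level decoding by construction).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    subject_seeds = cohort_seeds(seed, n_subjects)
    plan_kwargs = dict(plan_kwargs or {})
    out = []
    for s_seed in subject_seeds:
        plan = generate_sequence_plan(design, seed=s_seed, **plan_kwargs)
        out.append(
            simulate_subject(
                design, plan, effects=effects, noise=noise,
                seed=s_seed, **subject_kwargs,
            )
        )
    return out


def cohort_seeds(master_seed: int | None, n_subjects: int) -> list[int]:
    """Deterministic per-subject seeds derived from a master seed (< 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n_subjects)]
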