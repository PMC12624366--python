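"""Composable preprocessing transforms for epoched EEG.

The standard chain, in order: common-average reference, 0.1-100 Hz
zero-phase band-pass, resampling to 200 Hz, baseline correction over
[-100, 0) ms, and a 10-sample (50 ms) centered moving average.  Each step
is an independent, individually testable function over :class:`EpochArray`;
:func:`preprocess` composes them and every step can be switched off.

Filters are zero-phase forward-backward Butterworth (4th order before the
double pass), so effect onsets are not delayed.  The moving average uses
shrunken windows at the edges rather than padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage, signal

from .epochs import EpochArray

__all__ = [
    "PreprocessingConfig",
    "common_average_reference",
    "bandpass_filter",
    "downsample",
    "baseline_correct",
    "moving_average",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessingConfig:
    """Chain configuration; any ``None`` (or 0 for smoothing) skips the step."""

    car: bool = True
    hp_hz: float | None = 0.1
    lp_hz: float | None = 100.0
    resample_hz: float | None = 200.0
    baseline: tuple[float, float] | None = (-0.1, 0.0)
    smooth_samples: int | None = 10

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessingConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown preprocessing keys: {sorted(bad)}")
        cfg = dict(d)
        if cfg.get("baseline") is not None:
            cfg["baseline"] = tuple(cfg["baseline"])
        return cls(**cfg)


def common_average_reference(epochs: EpochArray) -> EpochArray:
    """Subtract the instantaneous mean over channels (zero-sum montage)."""
    if epochs.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy(data=data)


def bandpass_filter(
    epochs: EpochArray, low: float = 0.1, high: float = 100.0
) -> EpochArray:
    """Zero-phase Butterworth band-pass between ``low`` and ``high`` Hz."""
    nyq = epochs.sampling_rate / 2.0
    if high >= nyq:
        raise ValueError(
            f"low-pass corner {high} Hz must be below Nyquist ({nyq} Hz)"
        )
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    sos = signal.butter(
        4, [low, high], btype="bandpass", fs=epochs.sampling_rate, output="sos"
    )
    data = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return epochs.copy(data=np.ascontiguousarray(data))


def downsample(epochs: EpochArray, target_rate: float = 200.0) -> EpochArray:
    """Anti-aliased polyphase resampling to ``target_rate`` Hz.

    The output sample count is the epoch duration times the target rate,
    rounded (180 for the standard 900 ms window); the time axis is rescaled
    with the same origin.
    """
    fs = epochs.sampling_rate
    if target_rate > fs:
        raise ValueError("target_rate exceeds the current sampling rate")
    if target_rate == fs:
        return epochs.copy()
    frac = Fraction(target_rate / fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(epochs.data, up, down, axis=-1, padtype="line")
    n_out = int(round(epochs.n_samples * target_rate / fs))
    if abs(data.shape[-1] - n_out) > 1:
        raise ValueError("resampling produced an unexpected sample count")
    data = data[..., :n_out]
    time = epochs.time[0] + np.arange(n_out) / target_rate
    return epochs.copy(
        data=np.ascontiguousarray(data), time=time, sampling_rate=target_rate
    )


def baseline_correct(
    epochs: EpochArray, window: tuple[float, float] = (-0.1, 0.0)
) -> EpochArray:
    """Subtract the per-trial, per-channel mean over the half-open window."""
    t0, t1 = window
    mask = (epochs.time >= t0) & (epochs.time < t1)
    if not mask.any():
        raise ValueError(f"baseline window {window} contains no samples")
    base = epochs.data[..., mask].mean(axis=-1, keepdims=True)
    return epochs.copy(data=epochs.data - base)


def moving_average(epochs: EpochArray, n_samples: int = 10) -> EpochArray:
    """Centered uniform moving average; edge windows shrink to the available
    samples instead of padding."""
    n = int(n_samples)
    if n < 1:
        raise ValueError("n_samples must be >= 1")
    if n > epochs.n_samples:
        raise ValueError("smoothing window longer than the epoch")
    if n == 1:
        return epochs.copy()
    kernel = np.ones(n)
    # direct (non-FFT) convolution keeps exact zeros exact
    counts = ndimage.convolve1d(
        np.ones(epochs.n_samples), kernel, axis=-1, mode="constant"
    )
    sums = ndimage.convolve1d(epochs.data, kernel, axis=-1, mode="constant")
    return epochs.copy(data=sums / counts)


def preprocess(
    epochs: EpochArray, config: PreprocessingConfig | dict | None = None
) -> EpochArray:
    """Apply the full chain (reference, filter, resample, baseline, smooth)."""
    if config is None:
        config = PreprocessingConfig()
    elif isinstance(config, dict):
        config = PreprocessingConfig.from_dict(config)
    out = epochs
    if config.car:
        out = common_average_reference(out)
    if config.hp_hz is not None and config.lp_hz is not None:
        out = bandpass_filter(out, config.hp_hz, config.lp_hz)
    if config.resample_hz is not None:
        out = downsample(out, config.resample_hz)
    if config.baseline is not None:
        out = baseline_correct(out, config.baseline)
    if config.smooth_samples:
        out = moving_average(out, config.smooth_samples)
    return out
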