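"""End-to-end orchestration: simulate -> preprocess -> decode -> infer.

A single YAML config (one master seed) drives a fully reproducible run:
per-subject seeds are spawned deterministically from the master seed, each
subject's cohort data are simulated, preprocessed and decoded for every
requested design feature, and group-level Bayes-factor evidence curves are
written alongside tidy CSV results and a manifest (config hash, seeds,
version).  Optional stages add channel-searchlight maps and frequency-
domain decoding.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decoding import (
    AnalysisConfig, DecodingResult, decode_time_categorical,
    decode_time_continuous, trial_labels,
)
from .design import CONTINUOUS_COLUMNS, FACTOR_COLUMNS, build_design, write_design
from .epochs import read_epochs, write_epochs  # re-exported pipeline I/O
from .inference import EvidenceCurve, InferenceConfig, evidence_curve
from .preprocessing import PreprocessingConfig, preprocess
from .searchlight import DEFAULT_SEARCHLIGHT_TIMES, searchlight_decode
from .simulate import (
    EffectSpec, NoiseSpec, cohort_seeds, generate_sequence_plan,
    simulate_confounds, simulate_subject,
)
from .spectral import decode_frequency, power_spectrum

__all__ = ["run", "load_config", "read_epochs", "write_epochs", "DEFAULTS"]

logger = logging.getLogger(__name__)

DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "touchdecode_out",
    "design": {"n_base": 90, "category_spec": None},
    "simulate": {
        "n_subjects": 2,
        "n_sequences": 32,
        "repetitions": 8,
        "targets_range": [1, 9],
        "min_gap": 12,
        "sampling_rate": 2048.0,
        "n_channels": None,
        "noise": {
            "white_sd": 1.0,
            "pink_scale": 1.0,
            "pink_exponent": 1.0,
            "subject_gain_sd": 0.0,
        },
        "effects": [],
    },
    "preprocess": {
        "car": True,
        "hp_hz": 0.1,
        "lp_hz": 100.0,
        "resample_hz": 200.0,
        "baseline": [-0.1, 0.0],
        "smooth_samples": 10,
    },
    "decode": {
        "features": ["orientation"],
        "ridge_alpha": 0.5,
        "confounds": {"enabled": False, "mode": "joint"},
    },
    "searchlight": {"enabled": False, "k": 4, "times": None, "features": None},
    "spectral": {"enabled": False, "features": None},
    "inference": {
        "r": 0.707,
        "interval": [0.0, 0.5],
        "min_run": 5,
        "threshold": 6.0,
    },
    "save_epochs": False,
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, val in (override or {}).items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict) and defaults[key] is not None:
            if val is None:
                out[key] = defaults[key]
            elif not isinstance(val, dict):
                raise ValueError(f"config key {here} must be a mapping")
            else:
                out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = val
    return out


def load_config(source) -> dict:
    """Load and validate a config (YAML path or dict), filling defaults."""
    if isinstance(source, (str, Path)):
        with open(source) as f:
            raw = yaml.safe_load(f) or {}
    else:
        raw = dict(source or {})
    return _merge(DEFAULTS, raw)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _feature_task(feature: str) -> str:
    if feature in CONTINUOUS_COLUMNS:
        return "regression"
    if feature in FACTOR_COLUMNS:
        return "classification"
    raise ValueError(f"decode.features: unknown design feature {feature!r}")


def run(config, output_dir=None) -> dict:
    """Execute the configured pipeline; returns the in-memory result bundle.

    Writes to the output directory: ``design.tsv``, per-feature tidy
    decoding CSVs, evidence-curve CSVs with JSON summaries, optional
    searchlight/spectral tables, a stage-timing log, and ``manifest.json``.
    """
    config = load_config(config)
    outdir = Path(output_dir or config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def _log(stage: str, t0: float) -> None:
        line = f"{stage}: {_time.perf_counter() - t0:.2f} s"
        logger.info(line)
        log_lines.append(line)

    master_seed = int(config["seed"])
    sim = config["simulate"]
    n_subjects = int(sim["n_subjects"])
    subject_seeds = cohort_seeds(master_seed, n_subjects)

    t0 = _time.perf_counter()
    design = build_design(
        config["design"]["n_base"],
        category_spec=config["design"]["category_spec"],
        seed=master_seed,
    )
    write_design(design, outdir / "design.tsv")
    _log("design", t0)

    conf_cfg = config["decode"]["confounds"]
    confounds = None
    if conf_cfg["enabled"]:
        confounds = simulate_confounds(design, seed=master_seed)
        confounds.to_csv(outdir / "confounds.csv", index=False)

    features = list(config["decode"]["features"])
    for f in features:
        _feature_task(f)
    analysis = AnalysisConfig(
        ridge_alpha=float(config["decode"]["ridge_alpha"]),
        confound_mode=conf_cfg["mode"],
    )
    effects = [EffectSpec(**e) for e in sim["effects"]]
    noise = NoiseSpec(**sim["noise"])
    sl_cfg = config["searchlight"]
    sp_cfg = config["spectral"]

    results: dict[str, list[DecodingResult]] = {f: [] for f in features}
    sl_maps: dict[str, list] = {}
    sp_results: dict[str, list[DecodingResult]] = {}

    for si, s_seed in enumerate(subject_seeds):
        t0 = _time.perf_counter()
        plan = generate_sequence_plan(
            design,
            n_sequences=int(sim["n_sequences"]),
            repetitions=int(sim["repetitions"]),
            targets_range=tuple(sim["targets_range"]),
            min_gap=int(sim["min_gap"]),
            seed=s_seed,
        )
        raw = simulate_subject(
            design, plan, effects=effects, noise=noise, seed=s_seed,
            sampling_rate=float(sim["sampling_rate"]),
            n_channels=sim["n_channels"],
        )
        if config["save_epochs"]:
            write_epochs(raw, outdir / f"sub-{si:02d}_epochs.h5")
        _log(f"simulate sub-{si:02d}", t0)

        if sp_cfg["enabled"]:
            t0 = _time.perf_counter()
            spectra = power_spectrum(raw)
            for f in sp_cfg["features"] or features:
                task = _feature_task(f)
                res = decode_frequency(
                    spectra, trial_labels(raw, design, f),
                    config=analysis, confounds=confounds,
                    task=task, subject_id=si,
                )
                sp_results.setdefault(f, []).append(res)
            _log(f"spectral sub-{si:02d}", t0)

        t0 = _time.perf_counter()
        ep = preprocess(raw, PreprocessingConfig.from_dict(
            {**config["preprocess"],
             "baseline": config["preprocess"]["baseline"]}
        ))
        del raw
        _log(f"preprocess sub-{si:02d}", t0)

        t0 = _time.perf_counter()
        for f in features:
            labels = trial_labels(ep, design, f)
            if _feature_task(f) == "classification":
                res = decode_time_categorical(
                    ep, labels, config=analysis, confounds=confounds,
                    subject_id=si,
                )
            else:
                res = decode_time_continuous(
                    ep, labels, config=analysis, confounds=confounds,
                    subject_id=si,
                )
            results[f].append(res)
        _log(f"decode sub-{si:02d}", t0)

        if sl_cfg["enabled"]:
            t0 = _time.perf_counter()
            times = sl_cfg["times"] or DEFAULT_SEARCHLIGHT_TIMES
            for f in sl_cfg["features"] or features:
                task = _feature_task(f)
                m = searchlight_decode(
                    ep, trial_labels(ep, design, f), times=times,
                    config=analysis, confounds=confounds, task=task,
                    k=int(sl_cfg["k"]), subject_id=si,
                )
                sl_maps.setdefault(f, []).append(m)
            _log(f"searchlight sub-{si:02d}", t0)

    inf_cfg = config["inference"]
    interval = inf_cfg["interval"]
    inference = InferenceConfig(
        r=float(inf_cfg["r"]),
        excluded_interval=tuple(interval) if interval else None,
        bf_threshold=float(inf_cfg["threshold"]),
        min_run=int(inf_cfg["min_run"]),
    )
    curves: dict[str, EvidenceCurve] = {}
    sp_curves: dict[str, EvidenceCurve] = {}
    t0 = _time.perf_counter()
    for f in features:
        pd.concat([r.to_frame() for r in results[f]]).to_csv(
            outdir / f"decoding_{f}.csv", index=False
        )
        if n_subjects >= 2:
            curves[f] = evidence_curve(results[f], config=inference)
            _write_curve(curves[f], outdir / f"evidence_{f}")
    for f, reslist in sp_results.items():
        pd.concat([r.to_frame() for r in reslist]).to_csv(
            outdir / f"spectral_{f}.csv", index=False
        )
        if n_subjects >= 2:
            sp_curves[f] = evidence_curve(reslist, config=inference)
            _write_curve(sp_curves[f], outdir / f"evidence_spectral_{f}")
    for f, maps in sl_maps.items():
        pd.concat([m.to_frame() for m in maps]).to_csv(
            outdir / f"searchlight_{f}.csv", index=False
        )
    _log("inference", t0)

    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "master_seed": master_seed,
        "subject_seeds": subject_seeds,
        "version": __version__,
        "features": features,
        "onsets": {
            f: {"onset_s": c.onset, "peak_s": c.peak}
            for f, c in curves.items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    return {
        "design": design,
        "results": results,
        "curves": curves,
        "spectral": sp_results,
        "spectral_curves": sp_curves,
        "searchlight": sl_maps,
        "manifest": manifest,
    }


def _write_curve(curve: EvidenceCurve, stem: Path) -> None:
    pd.DataFrame(
        {
            "axis": curve.axis,
            "bf": curve.bf,
            "mean_metric": curve.mean_metric,
        }
    ).to_csv(str(stem) + ".csv", index=False)
    with open(str(stem) + ".json", "w") as fh:
        json.dump(
            {
                "onset_s": curve.onset,
                "peak_s": curve.peak,
                "chance": curve.chance,
                "n_subjects": curve.n_subjects,
                "axis_kind": curve.axis_kind,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
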