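"""Channel-space searchlight decoding.

Decoding is repeated within small clusters of neighboring electrodes (a
center channel plus its k nearest neighbors in the 2-D projected montage)
at a handful of time points; the score is stored at the cluster's center,
yielding a time-by-channel scalp map.  The default time grid is the nine
points from -50 ms to 750 ms in 100 ms steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .epochs import EpochArray

__all__ = [
    "DEFAULT_SEARCHLIGHT_TIMES",
    "load_montage",
    "electrode_neighborhoods",
    "searchlight_decode",
    "SearchlightMap",
]

logger = logging.getLogger(__name__)

#: Nine topography time points: -50 ms to 750 ms, 100 ms apart.
DEFAULT_SEARCHLIGHT_TIMES: tuple[float, ...] = tuple(
    np.round(np.arange(-0.05, 0.7501, 0.10), 3)
)


def load_montage(path=None) -> pd.DataFrame:
    """Load a montage table (columns: name, x, y).

    Without a path, the packaged 64-channel layout (standard 10/20-style
    BioSemi arrangement projected to 2-D head coordinates) is returned.
    """
    if path is None:
        ref = resources.files("touchdecode").joinpath("data/biosemi64_2d.tsv")
        with resources.as_file(ref) as p:
            montage = pd.read_csv(p, sep="\t")
    else:
        montage = pd.read_csv(path, sep="\t")
    if montage["name"].duplicated().any():
        raise ValueError("montage channel names are not unique")
    if not np.isfinite(montage[["x", "y"]].to_numpy(float)).all():
        raise ValueError("montage coordinates must be finite")
    return montage


def electrode_neighborhoods(
    montage: pd.DataFrame, k: int = 4
) -> dict[str, list[str]]:
    """Map each channel to [center] + its k nearest neighbors (Euclidean).

    Distance ties are broken by channel-name order (logged when hit), so
    the clusters are deterministic even for degenerate layouts.
    """
    names = list(montage["name"])
    if k >= len(names):
        raise ValueError("k must be smaller than the channel count")
    xy = montage[["x", "y"]].to_numpy(float)
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    clusters = {}
    for i, center in enumerate(names):
        others = [(d[i, j], names[j]) for j in range(len(names)) if j != i]
        others.sort(key=lambda t: (t[0], t[1]))
        if len(others) > k and others[k - 1][0] == others[k][0]:
            logger.warning(
                "distance tie at cluster %s broken by channel-name order", center
            )
        clusters[center] = [center] + [nm for _, nm in others[:k]]
    return clusters


@dataclass
class SearchlightMap:
    """Channels x time-points metric map (value stored at cluster centers)."""

    values: pd.DataFrame  # index: channel names; columns: time points (s)
    metric: str
    chance: float
    subject_id: str | int | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        long = self.values.reset_index(names="channel").melt(
            id_vars="channel", var_name="time_s", value_name="value"
        )
        long["metric"] = self.metric
        long["chance"] = self.chance
        long["subject"] = self.subject_id
        return long


def searchlight_decode(
    epochs: EpochArray,
    target,
    clusters: dict[str, list[str]] | None = None,
    times=DEFAULT_SEARCHLIGHT_TIMES,
    config=None,
    confounds=None,
    task: str = "classification",
    montage: pd.DataFrame | None = None,
    k: int = 4,
    subject_id=None,
) -> SearchlightMap:
    """Run cluster-restricted decoding at selected time points.

    For each (cluster, time point), the estimator stack of the decoding
    module (standardize -> optional residualize -> shrinkage LDA or ridge)
    is applied to the cluster's channels at that single time point and the
    fold-averaged score is stored at the center channel.
    """
    from .decoding import AnalysisConfig, _setup, decode_matrix

    config = config or AnalysisConfig()
    if clusters is None:
        if montage is None:
            montage = load_montage()
        montage = montage[montage["name"].isin(epochs.channel_names)]
        clusters = electrode_neighborhoods(montage, k=k)
    for center, members in clusters.items():
        missing = [m for m in members if m not in epochs.channel_names]
        if missing:
            raise ValueError(f"cluster {center} references unknown channels {missing}")

    ep, y, folds, C = _setup(epochs, target, None, confounds)
    ch_index = {name: i for i, name in enumerate(ep.channel_names)}
    t_indices = [ep.time_index(t) for t in times]

    values = pd.DataFrame(
        index=pd.Index(clusters.keys(), name="channel"),
        columns=list(times),
        dtype=float,
    )
    for center, members in clusters.items():
        ch = [ch_index[m] for m in members]
        for t, ti in zip(times, t_indices):
            X = ep.data[:, ch, ti]
            per_fold = decode_matrix(X, y, folds, config, C, task=task)
            with np.errstate(invalid="ignore"):
                values.loc[center, t] = np.nanmean(per_fold)
    if task == "classification":
        metric, chance = "balanced_accuracy", 1.0 / len(np.unique(y))
    else:
        metric, chance = "pearson_r", 0.0
    return SearchlightMap(
        values=values, metric=metric, chance=chance, subject_id=subject_id,
        meta={"k": len(next(iter(clusters.values()))) - 1, "times": list(times)},
    )
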