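"""Stimulus design table, valence scoring, and feature dissimilarity matrices.

The experimental design crosses 90 base touch videos with 4 viewing
orientations (left/right hand x self/other perspective), giving 360 unique
stimuli.  Each base video carries categorical sensory annotations (object
type, material, touch type, contact agent, approach) and continuous
affective ratings on a 1-10 scale (arousal, threat, pain).  Valence is not
rated directly: it is the first principal component of the per-video
percentages of raters who called the video pleasant or unpleasant.

Feature models are compared through representational dissimilarity matrices
(RDMs): stimulus x stimulus matrices of pairwise dissimilarity under one
feature, rank-correlated over their lower triangles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_CATEGORY_SPEC",
    "DEFAULT_LABELS",
    "build_design",
    "validate_design",
    "random_ratings",
    "valence_score",
    "feature_rdm",
    "rdm_spearman",
    "read_design",
    "write_design",
]

HANDS = ("left", "right")
PERSPECTIVES = ("self", "other")
ORIENTATIONS = tuple(f"{h}-{p}" for h in HANDS for p in PERSPECTIVES)
APPROACHES = ("approaching", "touching-from-start")

#: Default categorical cardinalities: 28 object types, 8 materials,
#: 12 touch types, 2 contact agents (uniform chance 1/28, 1/8, 1/12, 1/2).
DEFAULT_CATEGORY_SPEC: dict[str, int] = {
    "object_type": 28,
    "material": 8,
    "touch_type": 12,
    "contact_agent": 2,
}

DEFAULT_LABELS: dict[str, list[str]] = {
    "object_type": [
        "hand", "brush", "hammer", "knife", "feather", "scissors", "spoon",
        "fork", "pen", "pencil", "sponge", "towel", "cloth", "rope", "stick",
        "stone", "ice-cube", "flower", "leaf", "comb", "toothbrush", "needle",
        "lighter", "card", "eraser", "ruler", "tweezers", "spatula",
    ],
    "material": [
        "skin", "metal", "wood", "plastic", "fabric", "rubber", "stone",
        "bristle",
    ],
    "touch_type": [
        "touch", "stroke", "press", "tap", "slap", "pinch", "scratch",
        "poke", "rub", "grab", "stab", "cut",
    ],
    "contact_agent": ["hand", "object"],
}

RATING_COLUMNS = ("arousal", "threat", "pain")
PCT_COLUMNS = ("pct_pleasant", "pct_unpleasant")

FACTOR_COLUMNS = (
    "orientation", "hand", "perspective", "approach",
    "object_type", "material", "touch_type", "contact_agent",
)
CONTINUOUS_COLUMNS = ("valence", "arousal", "threat", "pain")


def _labels_for(column: str, n_levels: int) -> list[str]:
    base = DEFAULT_LABELS.get(column, [])
    if n_levels <= len(base):
        return list(base[:n_levels])
    extra = [f"{column}_{i}" for i in range(len(base), n_levels)]
    return list(base) + extra


def random_ratings(n_base: int, seed: int | None = None) -> pd.DataFrame:
    """Draw a plausible per-video rating table.

    Returns a frame indexed by ``base_video_id`` (1..n_base) with arousal,
    threat and pain on the 1-10 rating scale and pleasant/unpleasant
    categorisation percentages summing to at most 100.
    """
    rng = np.random.default_rng(seed)
    idx = pd.RangeIndex(1, n_base + 1, name="base_video_id")
    # Ratings skew low with a long tail, as affective ratings typically do.
    arousal = np.clip(rng.gamma(2.5, 1.4, n_base) + 1, 1, 10)
    threat = np.clip(rng.gamma(1.8, 1.5, n_base) + 1, 1, 10)
    pain = np.clip(0.6 * threat + rng.gamma(1.5, 1.2, n_base), 1, 10)
    # Pleasant / unpleasant / neither percentages from a Dirichlet draw.
    pcts = rng.dirichlet((1.2, 1.2, 0.8), n_base) * 100
    return pd.DataFrame(
        {
            "arousal": arousal,
            "threat": threat,
            "pain": pain,
            "pct_pleasant": pcts[:, 0],
            "pct_unpleasant": pcts[:, 1],
        },
        index=idx,
    )


def build_design(
    base_video_count: int,
    category_spec: dict[str, int] | None = None,
    ratings: pd.DataFrame | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Expand base videos into the full oriented stimulus table.

    Each base video yields 4 rows, one per orientation (hand x perspective);
    categorical annotations are constant within a base video, only the
    orientation columns differ.  ``ratings`` must contain one row per base
    video with arousal/threat/pain in [1, 10] and the two categorisation
    percentage columns; when omitted a seeded random table is drawn.

    Raises ``ValueError`` naming the video when a rating row is missing and
    when a categorical cardinality cannot be realized.
    """
    if base_video_count < 1:
        raise ValueError("base_video_count must be >= 1")
    spec = dict(DEFAULT_CATEGORY_SPEC)
    if category_spec:
        spec.update(category_spec)
    if spec["contact_agent"] != 2:
        raise ValueError("contact_agent is binary (hand vs object)")
    for col in ("object_type", "material", "touch_type"):
        if spec[col] < 1:
            raise ValueError(f"cardinality for {col} must be >= 1")
        if spec[col] > base_video_count:
            raise ValueError(
                f"cardinality mismatch: {col} requests {spec[col]} levels "
                f"but only {base_video_count} base videos exist"
            )

    if ratings is None:
        ratings = random_ratings(base_video_count, seed=seed)
    missing = [
        v for v in range(1, base_video_count + 1) if v not in ratings.index
    ]
    if missing:
        raise ValueError(f"missing rating row for base video {missing[0]}")
    for col in RATING_COLUMNS:
        vals = ratings.loc[1:base_video_count, col].to_numpy(float)
        if np.any(vals < 1) or np.any(vals > 10):
            raise ValueError(f"{col} ratings must lie in [1, 10]")

    if base_video_count == 1:
        # A one-video design has no categorisation variance to project.
        valence = np.zeros(1)
    else:
        valence = valence_score(
            ratings.loc[1:base_video_count, list(PCT_COLUMNS)]
        )

    obj_labels = _labels_for("object_type", spec["object_type"])
    mat_labels = _labels_for("material", spec["material"])
    touch_labels = _labels_for("touch_type", spec["touch_type"])
    # "hand" contact implies skin material; keep object->material assignment
    # cyclic over the remaining labels so every level is realized.
    non_skin = [m for m in mat_labels if m != "skin"] or mat_labels

    rows = []
    for base in range(1, base_video_count + 1):
        obj = obj_labels[(base - 1) % len(obj_labels)]
        agent = "hand" if obj == "hand" else "object"
        if agent == "hand" and "skin" in mat_labels:
            material = "skin"
        else:
            material = non_skin[(base - 1) % len(non_skin)]
        touch = touch_labels[(base - 1) % len(touch_labels)]
        approach = APPROACHES[(base - 1) % 2]
        rr = ratings.loc[base]
        for hand in HANDS:
            for persp in PERSPECTIVES:
                rows.append(
                    {
                        "stimulus_id": f"vid{base:03d}_{hand}_{persp}",
                        "base_video_id": base,
                        "orientation": f"{hand}-{persp}",
                        "hand": hand,
                        "perspective": persp,
                        "approach": approach,
                        "object_type": obj,
                        "material": material,
                        "touch_type": touch,
                        "contact_agent": agent,
                        "valence": valence[base - 1],
                        "arousal": float(rr["arousal"]),
                        "threat": float(rr["threat"]),
                        "pain": float(rr["pain"]),
                    }
                )
    design = pd.DataFrame(rows)
    # With a single object-type level the contact agent cannot vary.
    realized_agents = 2 if len(set(obj_labels)) > 1 and "hand" in obj_labels else 1
    validate_design(design, {**spec, "contact_agent": realized_agents})
    return design


def validate_design(design: pd.DataFrame, category_spec: dict[str, int] | None = None) -> None:
    """Check the structural invariants of a design table; raise on violation."""
    spec = dict(DEFAULT_CATEGORY_SPEC)
    if category_spec:
        spec.update(category_spec)
    counts = design.groupby("base_video_id").size()
    if not (counts == 4).all():
        bad = counts[counts != 4].index[0]
        raise ValueError(f"base video {bad} does not have exactly 4 rows")
    expected = design["hand"].str.cat(design["perspective"], sep="-")
    if not (design["orientation"] == expected).all():
        raise ValueError("orientation is not the cross of hand x perspective")
    per_base = design.groupby("base_video_id")["orientation"].nunique()
    if not (per_base == 4).all():
        raise ValueError("orientations are not unique within a base video")
    for col in ("object_type", "material", "touch_type", "contact_agent"):
        n = design[col].nunique()
        if n != spec[col]:
            raise ValueError(
                f"cardinality mismatch: {col} has {n} levels, spec says {spec[col]}"
            )
    for col in RATING_COLUMNS:
        vals = design[col].to_numpy(float)
        if np.any(vals < 1) or np.any(vals > 10):
            raise ValueError(f"{col} outside [1, 10]")


def valence_score(pcts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """First-principal-component valence score from categorisation percentages.

    ``pcts`` holds one row per video with the percentage of raters who
    called it pleasant and unpleasant.  The two columns are centered and
    projected on the leading eigenvector of their covariance; the sign is
    oriented so that more-pleasant videos score more positively.
    """
    x = np.asarray(
        pcts[list(PCT_COLUMNS)] if isinstance(pcts, pd.DataFrame) else pcts,
        dtype=float,
    )
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("expected a 2-column (pleasant, unpleasant) matrix")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 videos")
    if np.any(x[:, 0] + x[:, 1] > 100 + 1e-9):
        raise ValueError("pct_pleasant + pct_unpleasant exceeds 100")
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 1e-12 * max(1.0, abs(x).max()) ** 2:
        raise ValueError("degenerate ratings: zero variance in percentages")
    pc1 = evecs[:, -1]
    scores = xc @ pc1
    # pleasant-positive orientation
    if pc1[0] - pc1[1] < 0:
        scores = -scores
    return scores


def feature_rdm(values, kind: str) -> np.ndarray:
    """Pairwise dissimilarity matrix for one per-stimulus feature column.

    ``kind="categorical"``: 0 for identical labels, 1 otherwise.
    ``kind="continuous"``: absolute difference of values.
    """
    v = np.asarray(values)
    if v.shape[0] < 2:
        raise ValueError("need at least 2 stimuli")
    if kind == "categorical":
        rdm = (v[:, None] != v[None, :]).astype(float)
    elif kind == "continuous":
        v = v.astype(float)
        rdm = np.abs(v[:, None] - v[None, :])
    else:
        raise ValueError(f"unknown kind: {kind!r}")
    np.fill_diagonal(rdm, 0.0)
    return rdm


def rdm_spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation of two RDMs over the strict lower triangle.

    Returns NaN when either triangle has zero variance (the correlation is
    undefined there).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("RDMs must be square and of equal size")
    i, j = np.tril_indices(a.shape[0], k=-1)
    ta, tb = a[i, j], b[i, j]
    if np.ptp(ta) == 0 or np.ptp(tb) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(ta, tb)
    return float(rho)


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    # structural validation against the realized cardinalities
    realized = {
        col: design[col].nunique()
        for col in ("object_type", "material", "touch_type", "contact_agent")
    }
    validate_design(design, realized)
    return design
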