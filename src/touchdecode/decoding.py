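"""Time-resolved decoding with leave-one-sequence-out cross-validation.

A separate estimator is trained and tested at every time point (sliding
estimator).  Categorical stimulus features are classified with
shrinkage-regularized linear discriminant analysis and scored with
balanced accuracy (chance 1/K); continuous affective ratings are predicted
with ridge regression (alpha = 0.5) and scored by the Pearson correlation
between cross-validated predictions and the true ratings, computed within
each test fold and averaged (chance 0).

Within every fold, features are standardized with train-set statistics,
and (optionally) visual-confound variance is removed by ordinary least
squares per channel and time point, applying train-fit coefficients to the
test data so no information leaks across the fold boundary.  Trials
flagged as targets are always excluded before folds are built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import Ridge

from .epochs import EpochArray

__all__ = [
    "AnalysisConfig",
    "FoldSpec",
    "DecodingResult",
    "loso_folds",
    "standardize",
    "residualize_confounds",
    "fit_lda",
    "balanced_accuracy",
    "decode_time_categorical",
    "decode_time_continuous",
    "trial_labels",
    "trial_confounds",
]

logger = logging.getLogger(__name__)

CONFOUND_COLUMNS = ("entropy", "mean_luminance", "deep_pc1")


@dataclass(frozen=True)
class AnalysisConfig:
    ridge_alpha: float = 0.5
    shrinkage: str | float = "auto"  # Ledoit-Wolf analytic shrinkage
    standardize: bool = True
    confound_mode: str = "joint"  # "joint" | "separate"
    fold_score_mode: str = "fold-averaged"  # "fold-averaged" | "pooled"

    def __post_init__(self):
        if self.ridge_alpha <= 0:
            raise ValueError("ridge_alpha must be > 0")
        if self.confound_mode not in ("joint", "separate"):
            raise ValueError("confound_mode must be 'joint' or 'separate'")
        if self.fold_score_mode not in ("fold-averaged", "pooled"):
            raise ValueError("fold_score_mode must be 'fold-averaged' or 'pooled'")


@dataclass
class FoldSpec:
    """Leave-one-sequence-out folds: one (train, test) pair per sequence."""

    folds: list[tuple[np.ndarray, np.ndarray]]
    sequences: list[int]

    def __len__(self):
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)


@dataclass
class DecodingResult:
    """Per-subject decoding metric along one axis (time, frequency, channel)."""

    axis: np.ndarray
    axis_kind: str  # "time_s" | "frequency_hz" | "channel"
    per_fold: np.ndarray  # (n_folds, n_axis); NaN marks skipped folds
    metric: str  # "balanced_accuracy" | "pearson_r"
    chance: float
    subject_id: str | int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def fold_mean(self) -> np.ndarray:
        """Metric averaged over folds (NaN-skipping) at each axis point."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.per_fold, axis=0)

    def to_frame(self) -> pd.DataFrame:
        n_folds, n_axis = self.per_fold.shape
        return pd.DataFrame(
            {
                "subject": np.repeat(self.subject_id, n_folds * n_axis),
                "axis_kind": self.axis_kind,
                "axis": np.tile(self.axis, n_folds),
                "fold": np.repeat(np.arange(n_folds), n_axis),
                "metric": self.metric,
                "value": self.per_fold.ravel(),
                "chance": self.chance,
            }
        )


def loso_folds(sequence_indices) -> FoldSpec:
    """One fold per distinct sequence; its trials form the test set."""
    seq = np.asarray(sequence_indices)
    uniq = np.unique(seq)
    if len(uniq) < 2:
        raise ValueError("leave-one-sequence-out needs >= 2 sequences")
    folds = []
    for s in uniq:
        test = np.flatnonzero(seq == s)
        train = np.flatnonzero(seq != s)
        folds.append((train, test))
    return FoldSpec(folds=folds, sequences=[int(s) for s in uniq])


def standardize(train: np.ndarray, test: np.ndarray):
    """Z-score with train statistics; zero-variance features map to zeros."""
    train = np.asarray(train, float)
    test = np.asarray(test, float)
    if train.shape[0] < 2:
        raise ValueError("standardize needs >= 2 training rows")
    mu = train.mean(axis=0, keepdims=True)
    sd = train.std(axis=0, keepdims=True)
    nonzero = sd > 0
    safe = np.where(nonzero, sd, 1.0)
    return (
        (train - mu) / safe * nonzero,
        (test - mu) / safe * nonzero,
    )


def _confound_design(conf: np.ndarray) -> np.ndarray:
    n = conf.shape[0]
    return np.column_stack([np.ones(n), conf])


def _drop_collinear(C: np.ndarray) -> np.ndarray:
    """Greedily drop columns (never the intercept) until full rank."""
    keep = list(range(C.shape[1]))
    while len(keep) > 1 and np.linalg.matrix_rank(C[:, keep]) < len(keep):
        dropped = keep.pop()  # last-added confound first
        logger.warning("dropping collinear confound column %d", dropped - 1)
    return np.array(keep)


def residualize_confounds(
    train: np.ndarray,
    test: np.ndarray,
    conf_train: np.ndarray,
    conf_test: np.ndarray,
    mode: str = "joint",
):
    """OLS-residualize features on [intercept, confounds], train-fit only.

    ``train``/``test`` may have any trailing feature shape; the regression
    is fit per feature on the training trials and the same coefficients are
    applied to the test trials.  ``mode="separate"`` removes each confound
    sequentially (each in its own single-regressor model) instead of one
    joint design matrix.
    """
    train = np.asarray(train, float)
    test = np.asarray(test, float)
    conf_train = np.atleast_2d(np.asarray(conf_train, float))
    conf_test = np.atleast_2d(np.asarray(conf_test, float))
    if conf_train.shape[0] != train.shape[0]:
        raise ValueError("confound rows must align with training trials")
    if conf_test.shape[0] != test.shape[0]:
        raise ValueError("confound rows must align with test trials")

    if mode == "separate":
        for j in range(conf_train.shape[1]):
            train, test = residualize_confounds(
                train, test, conf_train[:, [j]], conf_test[:, [j]], mode="joint"
            )
        return train, test

    shape_tr, shape_te = train.shape, test.shape
    Xtr = train.reshape(shape_tr[0], -1)
    Xte = test.reshape(shape_te[0], -1)
    Ctr = _confound_design(conf_train)
    Cte = _confound_design(conf_test)
    keep = _drop_collinear(Ctr)
    beta, *_ = np.linalg.lstsq(Ctr[:, keep], Xtr, rcond=None)
    res_tr = Xtr - Ctr[:, keep] @ beta
    res_te = Xte - Cte[:, keep] @ beta
    return res_tr.reshape(shape_tr), res_te.reshape(shape_te)


def fit_lda(X: np.ndarray, y, shrinkage: str | float = "auto") -> LinearDiscriminantAnalysis:
    """Shrinkage-regularized LDA (covariance shrunk toward scaled identity)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("LDA needs >= 2 classes in the training data")
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    clf.fit(np.asarray(X, float), y)
    return clf


def predict(classifier, X: np.ndarray):
    return classifier.predict(np.asarray(X, float))


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean per-class recall over the classes present in ``y_true``.

    Predicted labels that never occur in ``y_true`` simply contribute
    misclassifications; they add no term of their own to the mean.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("y_true is empty")
    recalls = []
    for cls in np.unique(y_true):
        mask = y_true == cls
        recalls.append(np.mean(y_pred[mask] == cls))
    return float(np.mean(recalls))


def trial_labels(epochs: EpochArray, design: pd.DataFrame, column: str) -> np.ndarray:
    """Per-trial values of a design column (targets get NaN/None)."""
    lookup = design.set_index("stimulus_id")[column]
    return epochs.trials["stimulus_id"].map(lookup).to_numpy()


def trial_confounds(trials, confounds: pd.DataFrame) -> np.ndarray:
    """Broadcast a per-stimulus confound matrix to trial rows.

    ``trials`` is an EpochArray or a trial-annotation frame with a
    ``stimulus_id`` column.
    """
    if isinstance(trials, EpochArray):
        trials = trials.trials
    cols = [c for c in CONFOUND_COLUMNS if c in confounds.columns]
    lookup = confounds.set_index("stimulus_id")[cols]
    rows = lookup.reindex(trials["stimulus_id"])
    if rows.isna().any().any():
        missing = trials.loc[
            rows.isna().any(axis=1).to_numpy(), "stimulus_id"
        ].iloc[0]
        raise ValueError(f"no confound row for stimulus {missing!r}")
    return rows.to_numpy(float)


def _setup(epochs: EpochArray, labels, folds, confounds):
    """Drop targets, align labels/confounds, build default LOSO folds."""
    mask = ~epochs.trials["is_target"].to_numpy(bool)
    labels = np.asarray(labels)
    if len(labels) == epochs.n_trials:
        labels = labels[mask]
    ep = epochs.select_trials(mask)
    if len(labels) != ep.n_trials:
        raise ValueError("labels do not align with the non-target trials")
    if pd.isna(pd.Series(labels)).any():
        raise ValueError("labels undefined for some non-target trials")
    if folds is None:
        folds = loso_folds(ep.trials["sequence_index"].to_numpy())
    C = None
    if confounds is not None:
        if isinstance(confounds, pd.DataFrame) and "stimulus_id" in confounds:
            C = trial_confounds(ep, confounds)
        else:
            C = np.asarray(confounds, float)
            if len(C) == epochs.n_trials:
                C = C[mask]
            if len(C) != ep.n_trials:
                raise ValueError("confounds do not align with trials")
    return ep, labels, folds, C


def _fold_features(X, C, train, test, config):
    """Standardize (and residualize) one fold's features, all time points."""
    Xtr, Xte = X[train], X[test]
    if config.standardize:
        Xtr, Xte = standardize(Xtr, Xte)
    if C is not None:
        Xtr, Xte = residualize_confounds(
            Xtr, Xte, C[train], C[test], mode=config.confound_mode
        )
    return Xtr, Xte


def decode_time_categorical(
    epochs: EpochArray,
    labels,
    folds: FoldSpec | None = None,
    config: AnalysisConfig | None = None,
    confounds: pd.DataFrame | np.ndarray | None = None,
    subject_id=None,
) -> DecodingResult:
    """Sliding-estimator classification of a categorical feature over time."""
    config = config or AnalysisConfig()
    ep, y, folds, C = _setup(epochs, labels, folds, confounds)
    classes = np.unique(y)
    chance = 1.0 / len(classes)
    T = ep.n_samples
    per_fold = np.full((len(folds), T), np.nan)
    for fi, (train, test) in enumerate(folds):
        if len(np.unique(y[train])) < len(classes):
            logger.warning("fold %d skipped: training split lacks a class", fi)
            continue
        Xtr, Xte = _fold_features(ep.data, C, train, test, config)
        for t in range(T):
            clf = fit_lda(Xtr[:, :, t], y[train], shrinkage=config.shrinkage)
            per_fold[fi, t] = balanced_accuracy(y[test], clf.predict(Xte[:, :, t]))
    return DecodingResult(
        axis=ep.time.copy(),
        axis_kind="time_s",
        per_fold=per_fold,
        metric="balanced_accuracy",
        chance=chance,
        subject_id=subject_id,
        meta={"n_classes": len(classes)},
    )


def decode_time_continuous(
    epochs: EpochArray,
    ratings,
    folds: FoldSpec | None = None,
    config: AnalysisConfig | None = None,
    confounds: pd.DataFrame | np.ndarray | None = None,
    subject_id=None,
) -> DecodingResult:
    """Sliding-estimator ridge regression of a continuous rating over time.

    The metric is the Pearson correlation between the cross-validated
    predictions and the true ratings, computed within each held-out fold
    and averaged across folds (``config.fold_score_mode="pooled"`` instead
    pools predictions over folds before correlating).
    """
    config = config or AnalysisConfig()
    ep, y, folds, C = _setup(epochs, ratings, folds, confounds)
    y = y.astype(float)
    T = ep.n_samples
    per_fold = np.full((len(folds), T), np.nan)
    pooled_pred = np.full((ep.n_trials, T), np.nan)
    for fi, (train, test) in enumerate(folds):
        Xtr, Xte = _fold_features(ep.data, C, train, test, config)
        for t in range(T):
            model = Ridge(alpha=config.ridge_alpha)
            model.fit(Xtr[:, :, t], y[train])
            pred = model.predict(Xte[:, :, t])
            pooled_pred[test, t] = pred
            if np.std(pred) == 0 or np.std(y[test]) == 0:
                logger.warning(
                    "fold %d, t=%d: zero-variance predictions", fi, t
                )
                continue
            per_fold[fi, t] = np.corrcoef(pred, y[test])[0, 1]
    meta = {}
    if config.fold_score_mode == "pooled":
        pooled = np.array(
            [
                np.corrcoef(pooled_pred[:, t], y)[0, 1]
                if np.std(pooled_pred[:, t]) > 0
                else np.nan
                for t in range(T)
            ]
        )
        meta["pooled_r"] = pooled
    return DecodingResult(
        axis=ep.time.copy(),
        axis_kind="time_s",
        per_fold=per_fold,
        metric="pearson_r",
        chance=0.0,
        subject_id=subject_id,
        meta=meta,
    )


def decode_matrix(
    X: np.ndarray,
    y: np.ndarray,
    folds: FoldSpec,
    config: AnalysisConfig | None = None,
    confounds: np.ndarray | None = None,
    task: str = "classification",
) -> np.ndarray:
    """Cross-validated decoding of a single feature matrix (trials x features).

    Shared core for the searchlight and spectral paths; returns the
    per-fold metric vector (NaN where a fold was skipped).
    """
    config = config or AnalysisConfig()
    y = np.asarray(y)
    out = np.full(len(folds), np.nan)
    classes = np.unique(y) if task == "classification" else None
    for fi, (train, test) in enumerate(folds):
        if task == "classification" and len(np.unique(y[train])) < len(classes):
            logger.warning("fold %d skipped: training split lacks a class", fi)
            continue
        Xtr, Xte = X[train], X[test]
        if config.standardize:
            Xtr, Xte = standardize(Xtr, Xte)
        if confounds is not None:
            Xtr, Xte = residualize_confounds(
                Xtr, Xte, confounds[train], confounds[test],
                mode=config.confound_mode,
            )
        if task == "classification":
            clf = fit_lda(Xtr, y[train], shrinkage=config.shrinkage)
            out[fi] = balanced_accuracy(y[test], clf.predict(Xte))
        else:
            model = Ridge(alpha=config.ridge_alpha)
            model.fit(Xtr, y[train].astype(float))
            pred = model.predict(Xte)
            if np.std(pred) > 0 and np.std(y[test].astype(float)) > 0:
                out[fi] = np.corrcoef(pred, y[test].astype(float))[0, 1]
    return out
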