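"""Group-level Bayes-factor evidence curves and onset/peak detection.

At every axis point (time, frequency bin, or channel) the subjects'
fold-averaged decoding metrics, expressed as effects above chance, enter a
one-sample JZS Bayes factor: the alternative places a half-Cauchy prior
(width r = 0.707) on the standardized effect size d, restricted to
directional above-chance effects, against the point null d = 0.  For
time-resolved curves, effect sizes d in [0, 0.5] are excluded from the
prior (prior mass renormalized on d > 0.5) so that effects too small to be
meaningful cannot support the alternative; topography and frequency
analyses use no excluded interval.  Evidence thresholds follow the 6 /
1/6 convention (>= 3 for topography displays).

Onset is the earliest post-stimulus point where the Bayes factor exceeds
threshold for a sustained run; the peak is the point of maximal group-mean
decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

__all__ = [
    "InferenceConfig",
    "EvidenceCurve",
    "bf_directional",
    "evidence_curve",
    "detect_onset_peak",
]


@dataclass(frozen=True)
class InferenceConfig:
    r: float = 0.707  # half-Cauchy prior width
    excluded_interval: tuple[float, float] | None = (0.0, 0.5)  # in d units
    bf_threshold: float = 6.0
    bf_null_threshold: float = 1.0 / 6.0
    topo_threshold: float = 3.0
    min_run: int = 5  # consecutive samples for a "sustained" onset
    interval_mode: str = "truncate"  # "truncate" | "interval-null"

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("prior width r must be > 0")
        if self.excluded_interval is not None:
            lo, hi = self.excluded_interval
            if lo < 0 or hi < lo:
                raise ValueError("excluded interval must be [0, hi] with hi >= 0")
            if lo != 0:
                raise ValueError("excluded interval must start at d = 0")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.interval_mode not in ("truncate", "interval-null"):
            raise ValueError("interval_mode must be 'truncate' or 'interval-null'")


@dataclass
class EvidenceCurve:
    axis: np.ndarray
    bf: np.ndarray  # Bayes factor per axis point (> 0)
    mean_metric: np.ndarray  # group-mean metric per axis point
    chance: float
    axis_kind: str = "time_s"
    onset: float | None = None
    peak: float | None = None
    n_subjects: int | None = None
    meta: dict = field(default_factory=dict)


def _half_cauchy_pdf(d: np.ndarray, r: float) -> np.ndarray:
    """Density of |Cauchy(0, r)| on d >= 0."""
    return 2.0 / (np.pi * r * (1.0 + (d / r) ** 2))


def _half_cauchy_sf(d0: float, r: float) -> float:
    """P(d > d0) under the half-Cauchy prior."""
    return 1.0 - 2.0 / np.pi * np.arctan(d0 / r)


def _marginal_h1(t: float, n: int, r: float, lower: float) -> float:
    """Marginal likelihood of t under d ~ half-Cauchy(r) truncated to d > lower."""
    df = n - 1
    sqrt_n = np.sqrt(n)
    mass = _half_cauchy_sf(lower, r)

    def integrand(d):
        return stats.nct.pdf(t, df, d * sqrt_n) * _half_cauchy_pdf(d, r)

    val, _ = integrate.quad(
        integrand, lower, np.inf, epsrel=1e-9, epsabs=0, limit=200,
        points=None,
    )
    return val / mass


def bf_directional(
    effects,
    r: float = 0.707,
    excluded_interval: tuple[float, float] | None = None,
    mode: str = "truncate",
) -> float:
    """Directional one-sample JZS Bayes factor for above-chance effects.

    ``effects`` are the per-subject metric-minus-chance values.  The
    alternative is d ~ half-Cauchy(r) restricted to d above the excluded
    interval's upper bound (d > 0 when no interval is given); the null is
    d = 0.  Computed by adaptive quadrature over the prior.

    ``mode="interval-null"`` instead contrasts d above the interval against
    d inside it (an interval-vs-interval Bayes factor under the full
    half-Cauchy prior).
    """
    x = np.asarray(effects, float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need >= 2 subject-level effects")
    if not np.isfinite(x).all():
        raise ValueError("effects must be finite")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance across subjects")
    n = len(x)
    t = x.mean() / (sd / np.sqrt(n))
    df = n - 1
    lower = 0.0 if excluded_interval is None else float(excluded_interval[1])

    if mode == "interval-null" and lower > 0:
        # H1: d > lower vs H0: 0 <= d <= lower, both under the full prior.
        m_above = _marginal_h1(t, n, r, lower) * _half_cauchy_sf(lower, r)
        m_inside = _marginal_interval(t, n, r, 0.0, lower)
        prior_odds = _half_cauchy_sf(lower, r) / (1.0 - _half_cauchy_sf(lower, r))
        return float((m_above / m_inside) / prior_odds)

    m1 = _marginal_h1(t, n, r, lower)
    m0 = stats.t.pdf(t, df)
    return float(m1 / m0)


def _marginal_interval(t: float, n: int, r: float, lo: float, hi: float) -> float:
    df = n - 1
    sqrt_n = np.sqrt(n)
    mass = _half_cauchy_sf(lo, r) - _half_cauchy_sf(hi, r)

    def integrand(d):
        return stats.nct.pdf(t, df, d * sqrt_n) * _half_cauchy_pdf(d, r)

    val, _ = integrate.quad(integrand, lo, hi, epsrel=1e-9, epsabs=0, limit=200)
    return val / mass


def evidence_curve(
    results,
    chance: float | None = None,
    config: InferenceConfig | None = None,
    use_interval: bool | None = None,
) -> EvidenceCurve:
    """Group Bayes-factor curve over the shared axis of per-subject results.

    ``results`` is a list of :class:`~touchdecode.decoding.DecodingResult`
    (one per subject); the subject-level input at each axis point is the
    fold-averaged metric.  The excluded interval is applied for time-
    resolved curves and switched off for frequency/channel axes unless
    ``use_interval`` overrides this.
    """
    config = config or InferenceConfig()
    if len(results) < 2:
        raise ValueError("need >= 2 subjects")
    axis = np.asarray(results[0].axis, float)
    axis_kind = results[0].axis_kind
    for res in results[1:]:
        if res.axis_kind != axis_kind or not np.allclose(res.axis, axis):
            raise ValueError("subjects have mismatched axes")
    if chance is None:
        chance = results[0].chance
    if use_interval is None:
        use_interval = axis_kind == "time_s"
    interval = config.excluded_interval if use_interval else None

    metrics = np.vstack([res.fold_mean for res in results])  # subjects x axis
    effects = metrics - chance

    def _bf(col: np.ndarray) -> float:
        if col.std(ddof=1) == 0:
            # Saturated decoders (e.g. every subject at ceiling): the t
            # statistic degenerates; return the limiting Bayes factor.
            m = col.mean()
            return np.inf if m > 0 else (np.finfo(float).tiny if m < 0 else 1.0)
        return bf_directional(
            col, r=config.r, excluded_interval=interval,
            mode=config.interval_mode,
        )

    bf = np.array([_bf(effects[:, i]) for i in range(effects.shape[1])])
    mean_metric = metrics.mean(axis=0)
    curve = EvidenceCurve(
        axis=axis,
        bf=bf,
        mean_metric=mean_metric,
        chance=chance,
        axis_kind=axis_kind,
        n_subjects=len(results),
        meta={"interval": interval, "r": config.r},
    )
    if axis_kind == "time_s":
        curve.onset, curve.peak = detect_onset_peak(
            curve, threshold=config.bf_threshold, min_run=config.min_run
        )
    return curve


def detect_onset_peak(
    curve: EvidenceCurve, threshold: float = 6.0, min_run: int = 5
):
    """Sustained-evidence onset and group-metric peak on a time axis.

    Onset: earliest post-stimulus point where BF > threshold holds for at
    least ``min_run`` consecutive points.  Peak: post-onset point (post-
    stimulus when no onset exists) of maximal group-mean metric.  Either is
    ``None`` when undefined.
    """
    if curve.axis_kind != "time_s":
        raise ValueError("onset/peak detection needs a time axis")
    post = curve.axis >= 0
    idx = np.flatnonzero(post)
    above = curve.bf[idx] > threshold
    onset = None
    run = 0
    for j, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run >= min_run:
            onset = float(curve.axis[idx[j - min_run + 1]])
            break
    if onset is not None:
        peak_pool = idx[curve.axis[idx] >= onset]
    else:
        peak_pool = idx
    peak = None
    if len(peak_pool) and onset is not None:
        peak = float(curve.axis[peak_pool[np.argmax(curve.mean_metric[peak_pool])]])
    elif len(peak_pool) and onset is None:
        peak = None  # no sustained evidence: report no peak either
    return onset, peak
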