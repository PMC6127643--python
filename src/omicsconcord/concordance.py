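"""Intraclass correlation estimators with subject-level bootstrap CIs.

Two estimators are provided:

* ``icc_oneway`` — the one-way random-effects ANOVA ICC for paired scalar
  measurements (gold standard + one alternate method, k = 2 replicates
  per subject).
* ``distance_icc`` — a distance-based analogue for beta-diversity,
  contrasting within-subject squared distances (gold vs. method sample of
  the same subject) with between-subject squared distances.

Confidence intervals are nonparametric percentile bootstrap intervals
resampling whole subjects (pairs kept intact).  Negative estimates are
reported unmodified so that concordance failures remain visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .diversity import DistanceMatrix
from .io_model import PairedMeasurements, SampleDesign, ValidationError

__all__ = [
    "ICCEstimate",
    "icc_oneway",
    "bootstrap_ci",
    "icc_oneway_with_ci",
    "distance_icc",
    "bootstrap_distance_icc",
]

logger = logging.getLogger(__name__)

_MAX_REDRAW_ROUNDS = 100


@dataclass
class ICCEstimate:
    """Point estimate with optional percentile-bootstrap CI.

    When a bootstrap was run (``n_bootstrap > 0``) the interval is widened,
    if necessary, to contain the point estimate, so that
    ``ci_low <= estimate <= ci_high`` always holds.
    """

    estimate: float
    ci_low: float | None
    ci_high: float | None
    n_subjects: int
    k_replicates: int
    estimator: str
    n_bootstrap: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.estimate > 1.0 + 1e-12:
            raise ValidationError("ICC estimate cannot exceed 1")
        if self.n_bootstrap > 0:
            if self.ci_low is None or self.ci_high is None:
                raise ValidationError("bootstrap run but CI missing")

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_subjects": self.n_subjects,
            "k_replicates": self.k_replicates,
            "estimator": self.estimator,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
        }


def _icc_from_arrays(gold: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Vectorized one-way ICC over the last axis; NaN where undefined."""
    n = gold.shape[-1]
    means = 0.5 * (gold + alt)
    grand = means.mean(axis=-1, keepdims=True)
    msb = 2.0 * ((means - grand) ** 2).sum(axis=-1) / (n - 1)
    msw = ((gold - alt) ** 2).sum(axis=-1) / (2.0 * n)
    denom = msb + msw
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, (msb - msw) / denom, np.nan)
    return icc


def icc_oneway(pairs: PairedMeasurements) -> ICCEstimate:
    """One-way random-effects ICC(1) for k = 2 replicates per subject.

    ICC = (MSB - MSW) / (MSB + MSW) where MSB/MSW are the between- and
    within-subject mean squares.  Identical values everywhere leave the
    ICC undefined and raise an error.
    """
    if pairs.n_subjects < 3:
        raise ValidationError("icc_oneway requires at least 3 subjects")
    icc = float(_icc_from_arrays(pairs.gold, pairs.alternate))
    if np.isnan(icc):
        raise ValidationError("ICC undefined: zero total variance")
    return ICCEstimate(
        estimate=icc,
        ci_low=None,
        ci_high=None,
        n_subjects=pairs.n_subjects,
        k_replicates=2,
        estimator="anova_oneway",
    )


def bootstrap_ci(
    pairs: PairedMeasurements,
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the one-way ICC, resampling subjects.

    Resamples whose ICC is undefined (all values identical) are redrawn;
    the number of redraws is logged.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if seed is None:
        raise ValidationError("seed is required")
    n = pairs.n_subjects
    if n < 3:
        raise ValidationError("too few subjects to resample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    est = _icc_from_arrays(pairs.gold[idx], pairs.alternate[idx])
    redraws = 0
    for _ in range(_MAX_REDRAW_ROUNDS):
        bad = np.isnan(est)
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        redraws += n_bad
        idx_bad = rng.integers(0, n, size=(n_bad, n))
        est[bad] = _icc_from_arrays(pairs.gold[idx_bad], pairs.alternate[idx_bad])
    else:
        raise ValidationError("bootstrap resamples persistently degenerate")
    if redraws:
        logger.info("bootstrap_ci: redrew %d degenerate resamples", redraws)
    alpha = 1.0 - level
    lo, hi = np.quantile(est, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def icc_oneway_with_ci(
    pairs: PairedMeasurements,
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> ICCEstimate:
    """Convenience wrapper: point estimate plus percentile bootstrap CI."""
    point = icc_oneway(pairs)
    lo, hi = bootstrap_ci(pairs, B=B, seed=seed, level=level)
    return ICCEstimate(
        estimate=point.estimate,
        ci_low=min(lo, point.estimate),
        ci_high=max(hi, point.estimate),
        n_subjects=pairs.n_subjects,
        k_replicates=2,
        estimator="anova_oneway",
        n_bootstrap=B,
        seed=seed,
    )


def _paired_indices(
    dm: DistanceMatrix, design: SampleDesign, method: str
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Subjects having both gold and method samples in the matrix."""
    if method == design.gold_method:
        raise ValidationError("method must differ from the gold standard")
    present = set(dm.sample_ids)
    subjects, gidx, midx = [], [], []
    for subject in design.subjects:
        g = design.sample_for(subject, design.gold_method)
        m = design.sample_for(subject, method)
        if g in present and m in present:
            subjects.append(subject)
            gidx.append(dm.index_of(g))
            midx.append(dm.index_of(m))
    if len(subjects) < 3:
        raise ValidationError(
            f"fewer than 3 subjects with complete gold/{method} pairs"
        )
    return subjects, np.array(gidx), np.array(midx)


def _distance_icc_components(
    d2: np.ndarray, gidx: np.ndarray, midx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Within-pair squared distances and the 4-way cross-sum matrix.

    ``cross[i, j]`` is the sum of the four squared distances between
    subject i's (gold, method) samples and subject j's.
    """
    within = d2[gidx, midx]
    cross = (
        d2[np.ix_(gidx, gidx)]
        + d2[np.ix_(gidx, midx)]
        + d2[np.ix_(midx, gidx)]
        + d2[np.ix_(midx, midx)]
    )
    return within, cross


def distance_icc(
    dm: DistanceMatrix, design: SampleDesign, method: str
) -> ICCEstimate:
    """Distance-based ICC of ``method`` against the gold standard.

    With n subjects, sigma_w^2 = mean over subjects of d(gold_i, method_i)^2 / 2
    and sigma_t^2 = mean over all between-subject sample pairs of d^2 / 2;
    ICC = (sigma_t^2 - sigma_w^2) / sigma_t^2.  Bounded above by 1, may be
    negative.
    """
    subjects, gidx, midx = _paired_indices(dm, design, method)
    d2 = dm.values**2
    within, cross = _distance_icc_components(d2, gidx, midx)
    n = len(subjects)
    sw2 = within.mean() / 2.0
    # cross is symmetric with meaningless diagonal; each unordered subject
    # pair contributes 4 squared distances.
    cross_sum = cross.sum() - np.diag(cross).sum()
    st2 = cross_sum / (4.0 * n * (n - 1)) / 2.0
    if st2 <= 0:
        raise ValidationError("distance ICC undefined: zero total variance")
    return ICCEstimate(
        estimate=float((st2 - sw2) / st2),
        ci_low=None,
        ci_high=None,
        n_subjects=n,
        k_replicates=2,
        estimator="distance_based",
    )


def bootstrap_distance_icc(
    dm: DistanceMatrix,
    design: SampleDesign,
    method: str,
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> ICCEstimate:
    """Distance-based ICC with a subject-resampling percentile bootstrap CI.

    Subjects are drawn with replacement; duplicated subjects enter the
    resampled statistic as distinct index copies, so the distance between
    two copies of the same physical sample is 0, while a draw's own
    gold/method pair only ever contributes to the within-subject term.
    """
    if seed is None:
        raise ValidationError("seed is required")
    if B < 1:
        raise ValidationError("B must be >= 1")
    point = distance_icc(dm, design, method)
    subjects, gidx, midx = _paired_indices(dm, design, method)
    n = len(subjects)
    d2 = dm.values**2
    within, cross = _distance_icc_components(d2, gidx, midx)
    rng = np.random.default_rng(seed)

    def _resample_batch(draws: np.ndarray) -> np.ndarray:
        sw2 = within[draws].mean(axis=1) / 2.0
        sub = cross[draws[:, :, None], draws[:, None, :]]  # B × n × n
        diag = cross[draws, draws].sum(axis=1)
        cross_sum = sub.sum(axis=(1, 2)) - diag
        st2 = cross_sum / (4.0 * n * (n - 1)) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(st2 > 0, (st2 - sw2) / st2, np.nan)

    est = _resample_batch(rng.integers(0, n, size=(B, n)))
    redraws = 0
    for _ in range(_MAX_REDRAW_ROUNDS):
        bad = np.isnan(est)
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        redraws += n_bad
        est[bad] = _resample_batch(rng.integers(0, n, size=(n_bad, n)))
    else:
        raise ValidationError("bootstrap resamples persistently degenerate")
    if redraws:
        logger.info("bootstrap_distance_icc: redrew %d degenerate resamples", redraws)
    alpha = 1.0 - level
    lo, hi = np.quantile(est, [alpha / 2.0, 1.0 - alpha / 2.0])
    return ICCEstimate(
        estimate=point.estimate,
        ci_low=min(float(lo), point.estimate),
        ci_high=max(float(hi), point.estimate),
        n_subjects=n,
        k_replicates=2,
        estimator="distance_based",
        n_bootstrap=B,
        seed=seed,
    )
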