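"""Metabolite detectability accounting and preprocessing.

Detectability is always computed on raw (pre-imputation) intensities:
a feature counts as detected in a participant when its value for that
participant's sample is non-missing.  Preprocessing for concordance runs
per collection method in the order: half-minimum imputation, quantile
normalization, log10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import ceil
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .concordance import ICCEstimate, icc_oneway
from .io_model import FeatureTable, SampleDesign, ValidationError, pair_by_subject

__all__ = [
    "DetectabilitySummary",
    "ICCDistributionSummary",
    "detectability",
    "min_detected_count",
    "filter_by_detectability",
    "overlap_with_gold",
    "half_min_impute",
    "quantile_normalize",
    "log10_transform",
    "metabolite_icc_profile",
    "detectability_table",
]

logger = logging.getLogger(__name__)


@dataclass
class DetectabilitySummary:
    """Per-method feature counts and shared-with-gold overlap at one level."""

    method: str
    level: float  # 0.0 means "detected in at least one participant"
    n_features: int
    n_shared: int | None  # None for the gold method itself
    pct_shared: float | None
    n_known: int
    n_known_shared: int | None
    pct_known_shared: float | None


@dataclass
class ICCDistributionSummary:
    method: str
    n_features: int
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValidationError("quartiles out of order")


def detectability(
    table: FeatureTable, design: SampleDesign, method: str
) -> pd.Series:
    """Fraction of participants in which each feature is detected for ``method``.

    The denominator is the number of participants having a sample for the
    method; detected means non-missing.
    """
    samples = [s for s in design.samples_for_method(method) if s in table.data.columns]
    if not samples:
        raise ValidationError(f"no samples for method {method!r} in table")
    sub = table.data[samples]
    return (sub.notna().sum(axis=1) / len(samples)).rename(method)


def min_detected_count(level: float, n_participants: int) -> int:
    """Smallest integer c with c / n >= level, i.e. ceil(level * n)."""
    if not (0 < level <= 1):
        raise ValidationError("level must be in (0, 1]")
    if n_participants < 1:
        raise ValidationError("n_participants must be >= 1")
    return ceil(level * n_participants - 1e-12)


def filter_by_detectability(
    table: FeatureTable, design: SampleDesign, method: str, level: float
) -> FeatureTable:
    """Keep features with detected fraction >= ``level`` for ``method``.

    An empty result is allowed (a count of 0 at a level is meaningful).
    """
    frac = detectability(table, design, method)
    keep = frac.index[frac >= level - 1e-12]
    return FeatureTable(table.data.loc[keep].copy(), table.kind)


def _pct_one_decimal(numerator: int, denominator: int) -> float:
    """100*num/den, rounded half-away-from-zero to one decimal."""
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def overlap_with_gold(
    gold_features: Iterable[str], method_features: Iterable[str]
) -> tuple[int, float]:
    """Shared feature count and its percentage of the gold set (one decimal)."""
    gold = set(gold_features)
    if not gold:
        raise ValidationError("gold feature set is empty")
    shared = len(gold & set(method_features))
    return shared, _pct_one_decimal(shared, len(gold))


def half_min_impute(
    table: FeatureTable, design: SampleDesign, method: str
) -> FeatureTable:
    """Impute missing cells within one method's samples.

    Each missing cell becomes half the minimum detected value of that
    feature within the method.  Cells outside the method's samples and
    detected cells are untouched.
    """
    if table.kind != "intensity":
        raise ValidationError("imputation applies to intensity tables")
    samples = [s for s in design.samples_for_method(method) if s in table.data.columns]
    if not samples:
        raise ValidationError(f"no samples for method {method!r} in table")
    data = table.data.copy()
    sub = data[samples]
    needs = sub.isna().any(axis=1)
    for fid in sub.index[needs]:
        row = sub.loc[fid]
        detected = row.dropna()
        if detected.empty:
            raise ValidationError(
                f"feature {fid!r} has no detected value within method {method!r}"
            )
        fill = detected.min() / 2.0
        data.loc[fid, row.index[row.isna()]] = fill
    return FeatureTable(data, "intensity")


def quantile_normalize(table: FeatureTable) -> FeatureTable:
    """Quantile normalization across the table's samples.

    Each sample's order statistics are replaced by the across-sample mean of
    order statistics; tied values within a sample receive the mean of the
    reference values their positions span.  After normalization every
    sample holds the same multiset of values.
    """
    X = table.data.to_numpy()
    if np.isnan(X).any():
        raise ValidationError("quantile normalization requires complete data (impute first)")
    n_features, n_samples = X.shape
    if n_samples == 1:
        logger.warning("quantile_normalize: single sample, normalization is identity")
        return FeatureTable(table.data.copy(), table.kind)
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n_features)
        assigned[order] = reference
        # average assigned reference values within tie groups
        s = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = s.to_numpy()
    return FeatureTable(
        pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
        table.kind,
    )


def log10_transform(table: FeatureTable) -> FeatureTable:
    """Elementwise log10; every value must be strictly positive."""
    X = table.data.to_numpy()
    if np.isnan(X).any() or np.any(X <= 0):
        raise ValidationError("log10 requires strictly positive, complete values")
    return FeatureTable(
        pd.DataFrame(np.log10(X), index=table.data.index, columns=table.data.columns),
        "transformed",
    )


def preprocess_method(
    table: FeatureTable, design: SampleDesign, method: str
) -> FeatureTable:
    """Impute -> quantile normalize -> log10 for one method's samples."""
    samples = [s for s in design.samples_for_method(method) if s in table.data.columns]
    sub = FeatureTable(
        half_min_impute(table, design, method).data[samples], "intensity"
    )
    return log10_transform(quantile_normalize(sub))


def metabolite_icc_profile(
    gold_table: FeatureTable,
    method_table: FeatureTable,
    design: SampleDesign,
    method: str,
    features: Sequence[str] | None = None,
) -> tuple[ICCDistributionSummary, dict[str, ICCEstimate]]:
    """Per-feature one-way ICC between preprocessed gold and method tables.

    ``gold_table`` and ``method_table`` hold the (already preprocessed)
    samples of the gold standard and of ``method``.  ``features`` restricts
    the profile to the shared feature set at a detectability level; when
    omitted, the intersection of both tables' features is used.  Returns
    the median/IQR summary plus the individual estimates.  Features whose
    ICC is undefined (zero variance) are skipped and logged.
    """
    if features is None:
        features = [f for f in gold_table.feature_ids if f in set(method_table.feature_ids)]
    if not features:
        raise ValidationError("no shared features to profile")
    merged = pd.concat(
        [gold_table.data.loc[list(features)], method_table.data.loc[list(features)]],
        axis=1,
    )
    estimates: dict[str, ICCEstimate] = {}
    skipped = 0
    for fid in features:
        values = merged.loc[fid]
        try:
            pairs = pair_by_subject(values, design, method, variable=fid)
            estimates[fid] = icc_oneway(pairs)
        except ValidationError:
            skipped += 1
    if skipped:
        logger.info("metabolite_icc_profile: skipped %d degenerate features", skipped)
    if not estimates:
        raise ValidationError("no feature produced a defined ICC")
    vals = np.array([e.estimate for e in estimates.values()])
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    summary = ICCDistributionSummary(
        method=method, n_features=len(estimates),
        median=float(med), q1=float(q1), q3=float(q3),
    )
    return summary, estimates


def detectability_table(
    table: FeatureTable,
    design: SampleDesign,
    known_features: Iterable[str] | None = None,
    levels: Sequence[float] = (0.0, 0.5, 0.75, 1.0),
) -> list[DetectabilitySummary]:
    """Overlap-with-gold accounting per method and detectability level.

    Level 0.0 means "detected in at least one participant".  Methods with
    no samples in the table (e.g. assay-incompatible preservatives) are
    simply absent from the output.
    """
    known = set(known_features) if known_features is not None else set()
    methods = [
        m for m in design.methods
        if any(s in table.data.columns for s in design.samples_for_method(m))
    ]
    if design.gold_method not in methods:
        raise ValidationError("gold method has no samples in the intensity table")
    fracs = {m: detectability(table, design, m) for m in methods}
    out: list[DetectabilitySummary] = []
    for level in levels:
        threshold = max(level, np.nextafter(0, 1)) if level == 0.0 else level
        sets = {
            m: set(f.index[f >= threshold - 1e-12]) for m, f in fracs.items()
        }
        gold_set = sets[design.gold_method]
        gold_known = gold_set & known
        for m in methods:
            feats = sets[m]
            feats_known = feats & known
            if m == design.gold_method:
                out.append(DetectabilitySummary(
                    m, level, len(feats), None, None, len(feats_known), None, None,
                ))
            else:
                if gold_set:
                    n_shared, pct = overlap_with_gold(gold_set, feats)
                else:
                    n_shared, pct = 0, None
                if gold_known:
                    nk, pk = overlap_with_gold(gold_known, feats_known)
                else:
                    nk, pk = 0, None
                out.append(DetectabilitySummary(
                    m, level, len(feats), n_shared, pct, len(feats_known), nk, pk,
                ))
    return out
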