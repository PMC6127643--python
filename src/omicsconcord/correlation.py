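"""Spearman correlation screen between taxa and metabolites, per method.

For small samples (n <= 9) the two-sided p-value is computed by exact
enumeration of all rank permutations; above that, the usual
t-approximation with n - 2 degrees of freedom is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
import scipy.stats

from .io_model import FeatureTable, SampleDesign, ValidationError

__all__ = [
    "CorrelationResult",
    "spearman",
    "bonferroni_threshold",
    "correlation_screen",
]

_EXACT_MAX_N = 9
_perm_cache: dict[int, np.ndarray] = {}


@dataclass
class CorrelationResult:
    taxon: str
    metabolite: str
    method: str
    rho: float
    p_value: float
    n: int
    significant_nominal: bool
    significant_bonferroni: bool

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _perm_matrix(n: int) -> np.ndarray:
    if n not in _perm_cache:
        _perm_cache[n] = np.array(list(permutations(range(n))), dtype=np.intp)
    return _perm_cache[n]


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValidationError("constant input: Spearman rho undefined")
    return float((rx * ry).sum() / denom)


def spearman(x, y, method: str = "auto") -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with a two-sided p-value.

    Missing pairs are dropped listwise; at least 4 complete pairs are
    required.  ``method`` selects the p-value convention: "exact"
    enumerates all rank permutations, "approx" uses the t-approximation
    with n - 2 df, and "auto" (default) picks exact for n <= 9.
    """
    if method not in ("auto", "exact", "approx"):
        raise ValidationError(f"unknown p-value method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be aligned 1-D vectors")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValidationError(f"need at least 4 complete pairs, got {n}")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho = _rho_of_ranks(rx, ry)
    exact = method == "exact" or (method == "auto" and n <= _EXACT_MAX_N)
    if exact and n > 10:
        raise ValidationError("exact enumeration infeasible beyond n = 10")
    if exact:
        perms = _perm_matrix(n)
        ry_perm = ry[perms]  # n! × n
        rxc = rx - rx.mean()
        ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
        rho_perm = (ryc @ rxc) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 2.0 / factorial(n)  # degenerate perfect ranking
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Critical p-value alpha / m for m tests."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    return alpha / m


def correlation_screen(
    taxa: FeatureTable,
    metabolites: FeatureTable,
    design: SampleDesign,
    method: str,
    alpha: float = 0.05,
    m_tests: int | None = None,
) -> list[CorrelationResult]:
    """Test every taxon × metabolite pair within one method's samples.

    Both tables are aligned by participant: for each subject with a sample
    of ``method`` in both tables, the taxon value and metabolite value are
    paired.  Results are sorted by p-value; the Bonferroni denominator
    defaults to the number of tests actually performed, with ``m_tests``
    as an override.  Pairs involving a constant vector (rho undefined) are
    skipped and do not count toward m.
    """
    taxa_cols = {
        design.subject_of(s): s
        for s in design.samples_for_method(method)
        if s in taxa.data.columns
    }
    met_cols = {
        design.subject_of(s): s
        for s in design.samples_for_method(method)
        if s in metabolites.data.columns
    }
    subjects = [s for s in design.subjects if s in taxa_cols and s in met_cols]
    if not subjects:
        raise ValidationError(f"no overlapping participants for method {method!r}")
    T = taxa.data[[taxa_cols[s] for s in subjects]].to_numpy()
    M = metabolites.data[[met_cols[s] for s in subjects]].to_numpy()
    raw: list[tuple[str, str, float, float, int]] = []
    for i, taxon in enumerate(taxa.feature_ids):
        for j, met in enumerate(metabolites.feature_ids):
            try:
                rho, p = spearman(T[i], M[j])
            except ValidationError:
                continue
            keep = ~(np.isnan(T[i]) | np.isnan(M[j]))
            raw.append((taxon, met, rho, p, int(keep.sum())))
    m = m_tests if m_tests is not None else len(raw)
    crit = bonferroni_threshold(alpha, m) if m else alpha
    results = [
        CorrelationResult(
            taxon=t, metabolite=met, method=method, rho=rho, p_value=p, n=n,
            significant_nominal=p < alpha,
            significant_bonferroni=p < crit,
        )
        for t, met, rho, p, n in raw
    ]
    results.sort(key=lambda r: (r.p_value, r.metabolite, r.taxon))
    return results


def screen_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
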