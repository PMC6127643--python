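"""Kruskal-Wallis across groups and PERMANOVA on distance matrices."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

from .diversity import DistanceMatrix
from .io_model import ValidationError

__all__ = ["GroupTestResult", "kruskal_wallis", "permanova"]


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    n_groups: int
    n_samples: int
    n_permutations: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_groups": self.n_groups,
            "n_samples": self.n_samples,
        }
        if self.n_permutations is not None:
            d["n_permutations"] = self.n_permutations
            d["seed"] = self.seed
        return d


def _split_groups(values: Sequence[float], groups: Sequence) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValidationError("values and group labels must align")
    labels = []
    for g in groups:  # preserve first-appearance order
        if g not in labels:
            labels.append(g)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    return [values[groups == g] for g in labels]


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H test with chi-square p-value.

    All-identical inputs (no rank variation) return H = 0, p = 1 rather
    than an error.
    """
    parts = _split_groups(values, groups)
    if any(len(p) < 1 for p in parts):
        raise ValidationError("each group needs at least one observation")
    flat = np.concatenate(parts)
    if np.all(flat == flat[0]):
        return GroupTestResult(0.0, 1.0, len(parts), len(flat))
    stat, p = scipy.stats.kruskal(*parts)
    return GroupTestResult(float(stat), float(p), len(parts), len(flat))


def _pseudo_f(d2: np.ndarray, groups: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from squared distances (one-way partition)."""
    n = d2.shape[0]
    a = len(labels)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in labels:
        idx = np.flatnonzero(groups == g)
        ng = len(idx)
        if ng > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    dm: DistanceMatrix,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int | None = None,
) -> GroupTestResult:
    """One-way PERMANOVA with free permutation of sample labels.

    p = (1 + #{permuted F >= observed F}) / (n_permutations + 1), so the
    smallest attainable p-value is 1/(n_permutations + 1).
    """
    if seed is None:
        raise ValidationError("seed is required for reproducible permutation tests")
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    groups = np.asarray(groups)
    n = dm.n_samples
    if len(groups) != n:
        raise ValidationError("group labels must align with distance matrix samples")
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    d2 = dm.values**2
    f_obs = _pseudo_f(d2, groups, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if _pseudo_f(d2, groups[perm], labels) >= f_obs:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return GroupTestResult(
        float(f_obs), float(p), len(labels), n, n_permutations, seed
    )
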