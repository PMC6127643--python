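"""Alpha diversity, Bray-Curtis distances, and principal coordinates analysis.

Shannon entropy uses the natural logarithm; Simpson is reported as the
Gini-Simpson probability 1 - sum(p^2); Chao1 uses the bias-corrected form
so that the estimate is defined when no doubletons are observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import FeatureTable, ValidationError

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "relative_abundance",
    "sqrt_transform",
    "shannon",
    "simpson",
    "chao1",
    "bray_curtis",
    "distance_matrix",
    "alpha_diversity",
    "pcoa",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative samples × samples matrix with zero diagonal."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape must match sample ids")
        if np.any(self.values < 0):
            raise ValidationError("distances must be nonnegative")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def index_of(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def between(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), [str(s) for s in df.columns])


@dataclass
class OrdinationResult:
    """Classical-scaling embedding: coordinates, eigenvalues, explained shares."""

    coordinates: pd.DataFrame  # samples × axes
    eigenvalues: np.ndarray  # all axes, non-increasing (negatives retained)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Divide each sample column by its total; returns a proportion table."""
    if table.kind != "counts":
        raise ValidationError("relative abundance requires a counts table")
    totals = table.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(f"zero-total samples: {list(zero.index)}")
    return FeatureTable(table.data / totals, "proportion")


def sqrt_transform(table: FeatureTable) -> FeatureTable:
    """Elementwise square root of a proportion table."""
    if table.kind != "proportion":
        raise ValidationError("sqrt transform expects a proportion table")
    return FeatureTable(np.sqrt(table.data), "transformed")


def _clean_vector(x, allow_float: bool = True) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("expected a 1-D vector")
    if np.any(x < 0) or np.isnan(x).any():
        raise ValidationError("vector must be nonnegative and complete")
    if not np.any(x > 0):
        raise ValidationError("vector must have at least one positive entry")
    return x


def shannon(x) -> float:
    """Shannon entropy H = -sum(p ln p) in nats over positive proportions."""
    x = _clean_vector(x)
    p = x / x.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson(x) -> float:
    """Gini-Simpson index 1 - sum(p^2)."""
    x = _clean_vector(x)
    p = x / x.sum()
    return float(1.0 - (p**2).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1))."""
    counts = _clean_vector(counts)
    if not np.allclose(counts, np.round(counts), atol=1e-8):
        raise ValidationError("chao1 requires integer counts")
    counts = np.round(counts).astype(int)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Per-sample Shannon, Simpson and Chao1 (Chao1 only for count tables)."""
    records = {}
    for sid in table.sample_ids:
        col = table.data[sid].to_numpy()
        rec = {"shannon": shannon(col), "simpson": simpson(col)}
        if table.kind == "counts":
            rec["chao1"] = chao1(col)
        records[sid] = rec
    return pd.DataFrame(records).T.rename_axis("sample_id")


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must be aligned")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("vectors must be nonnegative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValidationError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


def distance_matrix(table: FeatureTable, metric: str = "braycurtis") -> DistanceMatrix:
    """Pairwise distances over sample columns.

    ``metric`` is "braycurtis" or "euclidean".
    """
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    X = table.data.to_numpy().T  # samples × features
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "braycurtis":
                try:
                    d = bray_curtis(X[i], X[j])
                except ValidationError as exc:
                    raise ValidationError(
                        f"metric failed for pair "
                        f"({table.sample_ids[i]!r}, {table.sample_ids[j]!r}): {exc}"
                    ) from exc
            elif metric == "euclidean":
                d = float(np.sqrt(((X[i] - X[j]) ** 2).sum()))
            else:
                raise ValidationError(f"unknown metric {metric!r}")
            D[i, j] = D[j, i] = d
    return DistanceMatrix(D, list(table.sample_ids))


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Classical (Torgerson) scaling of a distance matrix.

    The squared distances are double-centered and eigendecomposed; negative
    eigenvalues are reported unaltered, and axes with non-positive
    eigenvalues get zero coordinates.  Proportions explained are computed
    over the positive eigenvalues only.
    """
    n = dm.n_samples
    if n_axes < 1:
        raise ValidationError("n_axes must be >= 1")
    if n_axes > n - 1:
        raise ValidationError(f"n_axes={n_axes} exceeds sample count - 1 = {n - 1}")
    d2 = dm.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > 1e-12
    coords = np.zeros((n, n_axes))
    for k in range(n_axes):
        if pos[k]:
            coords[:, k] = eigvecs[:, k] * np.sqrt(eigvals[k])
    total_pos = eigvals[pos].sum()
    prop = np.where(pos, eigvals / total_pos if total_pos > 0 else 0.0, 0.0)
    axes = [f"PC{k + 1}" for k in range(n_axes)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dm.sample_ids, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )
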