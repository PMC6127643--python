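"""Data model for feature tables, taxonomy, sample design, and paired values.

Feature tables are features-in-rows / samples-in-columns, read from
delimited text (TSV/CSV) or BIOM v1 (JSON) files.  Count tables must be
integer-valued and complete; intensity tables may contain missing values
(represented as NaN).  The sample design maps each sample to a
(subject, collection-method) pair and designates one method as the gold
standard against which all concordance statistics are computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "FeatureTable",
    "TaxonomyMap",
    "SampleDesign",
    "PairedMeasurements",
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
    "read_design",
    "filter_low_depth",
    "aggregate_by_rank",
    "pair_by_subject",
]

#: Supported taxonomic ranks, ordered from coarsest to finest.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

_KINDS = ("counts", "intensity", "proportion", "transformed")

_PROPORTION_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when a table or design violates its invariants."""


@dataclass
class FeatureTable:
    """A validated features × samples matrix.

    Parameters
    ----------
    data:
        DataFrame with feature identifiers as the index and sample
        identifiers as the columns.  Values are floats; NaN marks a
        missing (undetected) cell and is only legal for intensity tables.
    kind:
        One of ``counts``, ``intensity``, ``proportion`` or
        ``transformed`` (the output of a monotone transform of a
        proportion table, e.g. square root, which no longer sums to 1).
    """

    data: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown table kind {self.kind!r}")
        self.data = self.data.astype(float)
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        self.data.index.name = "feature_id"
        self.data.columns.name = None
        values = self.data.to_numpy()
        # transformed tables (e.g. log10 intensities) may be negative
        if self.kind != "transformed" and np.any(values < 0):
            raise ValidationError("negative entries are not allowed")
        has_nan = bool(np.isnan(values).any())
        if has_nan and self.kind != "intensity":
            raise ValidationError(
                f"missing values are only allowed in intensity tables, not {self.kind}"
            )
        if self.kind == "counts":
            if not np.allclose(values, np.round(values), atol=1e-8):
                raise ValidationError("count tables must be integer-valued")
        elif self.kind == "proportion":
            colsums = values.sum(axis=0)
            if np.any(np.abs(colsums - 1.0) > _PROPORTION_TOL):
                raise ValidationError("proportion columns must each sum to 1")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        """Return a new table restricted (and reordered) to ``sample_ids``."""
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return FeatureTable(self.data.loc[:, list(sample_ids)].copy(), self.kind)

    def select_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return FeatureTable(self.data.loc[list(feature_ids)].copy(), self.kind)


@dataclass
class TaxonomyMap:
    """feature_id → ranked lineage (kingdom..genus), ranks optionally absent.

    Lineages are stored as ``{rank: name}`` dicts; absent ranks are simply
    not present in the dict (an empty string in the input file also counts
    as absent).
    """

    lineages: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for fid, lineage in self.lineages.items():
            for rank in lineage:
                if rank not in RANKS:
                    raise ValidationError(f"unknown rank {rank!r} for feature {fid!r}")

    def lineage_up_to(self, feature_id: str, rank: str) -> tuple[str, ...]:
        """Names of ranks from kingdom down to ``rank``, skipping absent ones."""
        stop = RANKS.index(rank)
        lineage = self.lineages.get(feature_id, {})
        return tuple(
            lineage[r] for r in RANKS[: stop + 1] if r in lineage and lineage[r]
        )

    def name_at(self, feature_id: str, rank: str) -> str | None:
        name = self.lineages.get(feature_id, {}).get(rank, "")
        return name or None


@dataclass
class SampleDesign:
    """sample_id → (subject, method) mapping with a gold-standard method."""

    assignments: dict[str, tuple[str, str]]
    gold_method: str

    def __post_init__(self) -> None:
        methods = {m for _, m in self.assignments.values()}
        if self.gold_method not in methods:
            raise ValidationError(
                f"gold method {self.gold_method!r} not present among methods {sorted(methods)}"
            )
        seen: dict[tuple[str, str], str] = {}
        for sid, key in self.assignments.items():
            if key in seen:
                raise ValidationError(
                    f"subject/method pair {key} maps to both {seen[key]!r} and {sid!r}"
                )
            seen[key] = sid
        self._by_pair = {key: sid for key, sid in seen.items()}

    @property
    def methods(self) -> list[str]:
        """Methods in first-appearance order, gold first."""
        ordered: list[str] = [self.gold_method]
        for _, m in self.assignments.values():
            if m not in ordered:
                ordered.append(m)
        return ordered

    @property
    def subjects(self) -> list[str]:
        ordered: list[str] = []
        for s, _ in self.assignments.values():
            if s not in ordered:
                ordered.append(s)
        return ordered

    def subject_of(self, sample_id: str) -> str:
        return self.assignments[sample_id][0]

    def method_of(self, sample_id: str) -> str:
        return self.assignments[sample_id][1]

    def sample_for(self, subject: str, method: str) -> str | None:
        return self._by_pair.get((subject, method))

    def samples_for_method(self, method: str) -> list[str]:
        return [sid for sid, (_, m) in self.assignments.items() if m == method]

    def subjects_for_method(self, method: str) -> list[str]:
        return [s for sid, (s, m) in self.assignments.items() if m == method]

    def restrict_to(self, sample_ids: Iterable[str]) -> "SampleDesign":
        """Design restricted to samples actually present in a table."""
        keep = {sid: v for sid, v in self.assignments.items() if sid in set(sample_ids)}
        return SampleDesign(keep, self.gold_method)


@dataclass
class PairedMeasurements:
    """Aligned (gold, alternate) values per subject for one scalar variable."""

    subject_ids: list[str]
    gold: np.ndarray
    alternate: np.ndarray
    variable: str
    method: str

    def __post_init__(self) -> None:
        self.gold = np.asarray(self.gold, dtype=float)
        self.alternate = np.asarray(self.alternate, dtype=float)
        if len(self.subject_ids) != len(self.gold) or len(self.gold) != len(self.alternate):
            raise ValidationError("subject ids, gold and alternate must align")
        if np.isnan(self.gold).any() or np.isnan(self.alternate).any():
            raise ValidationError("paired measurements may not contain missing values")
        if len(self.subject_ids) < 2:
            raise ValidationError("need at least 2 complete subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_biom_v1(path: Path) -> pd.DataFrame:
    """Minimal BIOM v1 (JSON) reader: rows × columns dense or sparse."""
    with open(path) as fh:
        doc = json.load(fh)
    rows = [r["id"] for r in doc["rows"]]
    cols = [c["id"] for c in doc["columns"]]
    values = np.zeros((len(rows), len(cols)), dtype=float)
    if doc.get("matrix_type", "sparse") == "dense":
        values[:] = np.asarray(doc["data"], dtype=float)
    else:
        for i, j, v in doc["data"]:
            values[int(i), int(j)] = v
    return pd.DataFrame(values, index=rows, columns=cols)


def read_feature_table(path: str | Path, kind: str) -> FeatureTable:
    """Read a feature table from TSV/CSV (features × samples) or BIOM v1 JSON.

    Blank or "NA"/"NaN" cells become missing values; missing values are an
    error for count tables.
    """
    path = Path(path)
    if path.suffix == ".biom":
        df = _read_biom_v1(path)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(
            path, sep=sep, index_col=0,
            na_values=["NA", "NaN", "nan", ""], keep_default_na=False,
        )
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    if kind == "counts" and df.isna().any().any():
        raise ValidationError("count tables may not contain missing/blank cells")
    return FeatureTable(df, kind)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a table as TSV; missing values are written as ``NA``."""
    path = Path(path)
    df = table.data
    if table.kind == "counts":
        df = df.astype(int)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")


_GG_PREFIXES = {f"{r[0]}__" for r in RANKS}


def _parse_lineage(text: str) -> dict[str, str]:
    parts = [p.strip() for p in text.split(";")]
    lineage: dict[str, str] = {}
    for rank, part in zip(RANKS, parts):
        if part[:3] in _GG_PREFIXES:  # greengenes-style "g__Blautia"
            part = part[3:]
        if part:
            lineage[rank] = part
    return lineage


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column TSV of feature_id and semicolon-delimited lineage."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    fid_col, lin_col = df.columns[0], df.columns[1]
    return TaxonomyMap(
        {row[fid_col]: _parse_lineage(row[lin_col]) for _, row in df.iterrows()}
    )


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    records = []
    for fid, lineage in taxonomy.lineages.items():
        text = ";".join(lineage.get(r, "") for r in RANKS)
        records.append((fid, text))
    pd.DataFrame(records, columns=["feature_id", "lineage"]).to_csv(
        path, sep="\t", index=False
    )


def read_design(path: str | Path, gold_method: str) -> SampleDesign:
    """Read a metadata TSV with columns sample_id, subject_id, method."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subject_id", "method"}
    if not required.issubset(df.columns):
        raise ValidationError(f"metadata must have columns {sorted(required)}")
    assignments = {
        row["sample_id"]: (row["subject_id"], row["method"]) for _, row in df.iterrows()
    }
    if len(assignments) != len(df):
        raise ValidationError("duplicate sample_id in metadata")
    return SampleDesign(assignments, gold_method)


def write_design(design: SampleDesign, path: str | Path) -> None:
    records = [
        (sid, subj, meth) for sid, (subj, meth) in design.assignments.items()
    ]
    pd.DataFrame(records, columns=["sample_id", "subject_id", "method"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_low_depth(
    table: FeatureTable, min_reads: int = 1000
) -> tuple[FeatureTable, list[str]]:
    """Drop samples whose total read count is below ``min_reads``.

    Returns the filtered table and the list of dropped sample ids.
    Retained columns are never altered.
    """
    if table.kind != "counts":
        raise ValidationError("depth filtering requires a counts table")
    depths = table.data.sum(axis=0)
    dropped = [s for s in table.sample_ids if depths[s] < min_reads]
    kept = [s for s in table.sample_ids if depths[s] >= min_reads]
    if not kept:
        raise ValidationError(
            f"all {table.n_samples} samples fall below min_reads={min_reads}"
        )
    return FeatureTable(table.data.loc[:, kept].copy(), "counts"), dropped


def _unclassified_label(taxonomy: TaxonomyMap, feature_id: str, rank: str) -> str:
    """Placeholder for a feature lacking ``rank``: deepest known name + _UC<r>."""
    prefix = taxonomy.lineage_up_to(feature_id, rank)
    deepest = prefix[-1] if prefix else "unknown"
    return f"{deepest}_UC{rank[0].upper()}"


def aggregate_by_rank(
    table: FeatureTable, taxonomy: TaxonomyMap, rank: str
) -> FeatureTable:
    """Sum features sharing the same lineage prefix up to ``rank``.

    Features without an assignment at ``rank`` are grouped under a labelled
    placeholder carrying the deepest available rank (e.g. ``Rikenellaceae_UCG``
    for an unclassified genus in the family Rikenellaceae).  Column totals
    are conserved.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for fid in table.feature_ids:
        name = taxonomy.name_at(fid, rank)
        if name is None:
            name = _unclassified_label(taxonomy, fid, rank)
        if name not in groups:
            groups[name] = []
            order.append(name)
        groups[name].append(fid)
    rows = {name: table.data.loc[groups[name]].sum(axis=0) for name in order}
    out = pd.DataFrame(rows).T.loc[order]
    out.columns = table.data.columns
    kind = table.kind if table.kind != "transformed" else "transformed"
    return FeatureTable(out, kind)


def pair_by_subject(
    values: Mapping[str, float] | pd.Series,
    design: SampleDesign,
    method: str,
    variable: str = "value",
) -> PairedMeasurements:
    """Align per-sample scalars into (gold, method) pairs by subject.

    Subjects having both a gold sample and a ``method`` sample with
    non-missing values are retained, in design subject order.
    """
    if method == design.gold_method:
        raise ValidationError("method must differ from the gold standard")
    values = dict(values.items()) if isinstance(values, pd.Series) else dict(values)
    subject_ids, gold, alt = [], [], []
    for subject in design.subjects:
        g_sid = design.sample_for(subject, design.gold_method)
        m_sid = design.sample_for(subject, method)
        if g_sid is None or m_sid is None:
            continue
        g, m = values.get(g_sid), values.get(m_sid)
        if g is None or m is None or np.isnan(g) or np.isnan(m):
            continue
        subject_ids.append(subject)
        gold.append(float(g))
        alt.append(float(m))
    if len(subject_ids) < 2:
        raise ValidationError(
            f"fewer than 2 complete subjects for method {method!r}"
        )
    return PairedMeasurements(subject_ids, np.array(gold), np.array(alt), variable, method)
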