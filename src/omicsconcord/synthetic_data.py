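"""Synthetic paired-design datasets with known ground truth.

Every generator follows the same hierarchical variance-components model
the ICC analysis assumes: a subject-level effect with variance
``icc * total_variance`` plus independent replicate noise with variance
``(1 - icc) * total_variance``, so the true ICC is known by construction.
Counts add a multinomial sequencing-depth layer; intensities add
detection-limit censoring.  All generators are bit-reproducible given a
seed, and the returned truth records contain everything needed to compute
the expected estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    FeatureTable,
    PairedMeasurements,
    SampleDesign,
    TaxonomyMap,
    ValidationError,
)

__all__ = [
    "SyntheticTruth",
    "generate_paired_scalars",
    "generate_community",
    "generate_metabolome",
    "generate_taxonomy",
    "DEFAULT_METHODS",
    "DEFAULT_SCFA_PANEL",
]

#: Five collection methods, gold standard first.
DEFAULT_METHODS = ("frozen", "omnigene", "ethanol", "rnalater", "fta")

#: Three predominant short-chain fatty acids plus seven minor ones.
DEFAULT_SCFA_PANEL = (
    "acetic_acid", "propionic_acid", "butyric_acid",
    "isobutyric_acid", "valeric_acid", "isovaleric_acid",
    "2-methylbutyric_acid", "hexanoic_acid", "heptanoic_acid", "caproic_acid",
)


@dataclass
class SyntheticTruth:
    """Ground-truth variance components behind a simulated dataset."""

    true_icc: np.ndarray  # per feature (length 1 for scalar generators)
    sigma_b2: np.ndarray  # between-subject variance per feature
    sigma_w2: np.ndarray  # residual variance per feature
    seed: int
    censor_quantile: float | None = None
    depth_mean: float | None = None
    known_features: list[str] | None = None

    def __post_init__(self) -> None:
        self.true_icc = np.atleast_1d(np.asarray(self.true_icc, dtype=float))
        self.sigma_b2 = np.atleast_1d(np.asarray(self.sigma_b2, dtype=float))
        self.sigma_w2 = np.atleast_1d(np.asarray(self.sigma_w2, dtype=float))
        total = self.sigma_b2 + self.sigma_w2
        ok = total > 0
        implied = np.where(ok, self.sigma_b2 / np.where(ok, total, 1.0), self.true_icc)
        if not np.allclose(self.true_icc, implied, atol=1e-9):
            raise ValidationError("true ICC must equal sigma_b2 / (sigma_b2 + sigma_w2)")
        if np.any(self.true_icc < 0) or np.any(self.true_icc > 1):
            raise ValidationError("true ICC must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "true_icc": self.true_icc.tolist(),
            "sigma_b2": self.sigma_b2.tolist(),
            "sigma_w2": self.sigma_w2.tolist(),
            "seed": self.seed,
            "censor_quantile": self.censor_quantile,
            "depth_mean": self.depth_mean,
            "known_features": self.known_features,
        }


def generate_paired_scalars(
    n_subjects: int,
    true_icc: float,
    total_variance: float = 1.0,
    seed: int | None = None,
    method: str = "synthetic",
) -> tuple[PairedMeasurements, SyntheticTruth]:
    """Paired (gold, alternate) scalars under the one-way variance model."""
    if not (0.0 <= true_icc <= 1.0):
        raise ValidationError("true_icc must be in [0, 1]")
    if total_variance <= 0:
        raise ValidationError("total_variance must be positive")
    if n_subjects < 3:
        raise ValidationError("need at least 3 subjects")
    if seed is None:
        raise ValidationError("seed is required")
    rng = np.random.default_rng(seed)
    sigma_b2 = true_icc * total_variance
    sigma_w2 = (1.0 - true_icc) * total_variance
    subject = rng.normal(0.0, np.sqrt(sigma_b2), size=n_subjects)
    gold = subject + rng.normal(0.0, np.sqrt(sigma_w2), size=n_subjects)
    alt = subject + rng.normal(0.0, np.sqrt(sigma_w2), size=n_subjects)
    subjects = [f"S{i + 1:03d}" for i in range(n_subjects)]
    pairs = PairedMeasurements(subjects, gold, alt, "synthetic", method)
    truth = SyntheticTruth(
        true_icc=np.array([true_icc]),
        sigma_b2=np.array([sigma_b2]),
        sigma_w2=np.array([sigma_w2]),
        seed=seed,
    )
    return pairs, truth


def _design_for(
    subjects: Sequence[str], methods: Sequence[str]
) -> SampleDesign:
    assignments = {
        f"{subj}.{meth}": (subj, meth) for subj in subjects for meth in methods
    }
    return SampleDesign(assignments, methods[0])


def generate_community(
    n_subjects: int = 8,
    methods: Sequence[str] = DEFAULT_METHODS,
    n_taxa: int = 150,
    subject_sd: float = 1.0,
    method_sd: float = 0.3,
    depth_mean: float = 18000.0,
    seed: int | None = None,
    base_sd: float = 1.5,
    subject_presence_prob: float = 1.0,
) -> tuple[FeatureTable, SampleDesign, SyntheticTruth]:
    """Multinomial count table for a subjects × methods paired design.

    Each taxon gets a fixed baseline log-abundance; subjects perturb it
    with sd ``subject_sd`` and each sample adds a method/replicate
    perturbation with sd ``method_sd``.  Counts are multinomial draws at a
    Poisson(depth_mean) depth, so column sums equal the drawn depths
    exactly.  A larger subject_sd / method_sd ratio produces stronger
    subject clustering in Bray-Curtis space.

    ``subject_presence_prob < 1`` additionally gives each subject a random
    taxon support (taxa absent from a subject in every sample), creating
    genuine between-subject richness differences so that richness
    estimators also carry subject signal.
    """
    if not (0.0 < subject_presence_prob <= 1.0):
        raise ValidationError("subject_presence_prob must be in (0, 1]")
    if len(methods) < 2:
        raise ValidationError("need at least 2 methods (gold + one alternate)")
    if depth_mean < 1:
        raise ValidationError("depth_mean must be >= 1")
    if seed is None:
        raise ValidationError("seed is required")
    rng = np.random.default_rng(seed)
    subjects = [f"S{i + 1:03d}" for i in range(n_subjects)]
    design = _design_for(subjects, methods)
    base = rng.normal(0.0, base_sd, size=n_taxa)
    subj_eff = rng.normal(0.0, subject_sd, size=(n_subjects, n_taxa))
    present = np.ones((n_subjects, n_taxa), dtype=bool)
    if subject_presence_prob < 1.0:
        present = rng.random((n_subjects, n_taxa)) < subject_presence_prob
        for i in range(n_subjects):  # keep every subject non-empty
            if not present[i].any():
                present[i, int(rng.integers(n_taxa))] = True
    columns = {}
    for i, subj in enumerate(subjects):
        for meth in methods:
            logit = base + subj_eff[i] + rng.normal(0.0, method_sd, size=n_taxa)
            p = np.where(present[i], np.exp(logit - logit.max()), 0.0)
            p /= p.sum()
            depth = max(1, int(rng.poisson(depth_mean)))
            columns[f"{subj}.{meth}"] = rng.multinomial(depth, p)
    data = pd.DataFrame(
        columns, index=[f"OTU{t + 1:04d}" for t in range(n_taxa)], dtype=float
    )
    table = FeatureTable(data, "counts")
    sb2, sw2 = subject_sd**2, method_sd**2
    icc = sb2 / (sb2 + sw2) if (sb2 + sw2) > 0 else 0.0
    truth = SyntheticTruth(
        true_icc=np.full(n_taxa, icc),
        sigma_b2=np.full(n_taxa, sb2),
        sigma_w2=np.full(n_taxa, sw2),
        seed=seed,
        depth_mean=depth_mean,
    )
    return table, design, truth


_PHYLA = ("Firmicutes", "Bacteroidetes", "Actinobacteria",
          "Proteobacteria", "Verrucomicrobia")
_PHYLUM_WEIGHTS = (0.45, 0.3, 0.12, 0.08, 0.05)


def generate_taxonomy(
    feature_ids: Sequence[str],
    seed: int,
    unclassified_genus_fraction: float = 0.1,
) -> TaxonomyMap:
    """Plausible ranked lineages for synthetic taxa.

    A fraction of features get no genus assignment so that aggregation
    exercises the unclassified-genus placeholder path.
    """
    rng = np.random.default_rng(seed)
    lineages: dict[str, dict[str, str]] = {}
    for fid in feature_ids:
        phylum = rng.choice(_PHYLA, p=_PHYLUM_WEIGHTS)
        fam_idx = int(rng.integers(1, 13))
        lineage = {
            "kingdom": "Bacteria",
            "phylum": str(phylum),
            "class": f"{phylum}_class",
            "order": f"{phylum}_order",
            "family": f"{phylum}_Family{fam_idx:02d}",
        }
        if rng.random() >= unclassified_genus_fraction:
            lineage["genus"] = f"{phylum}_Genus{int(rng.integers(1, 31)):02d}"
        lineages[fid] = lineage
    return TaxonomyMap(lineages)


def generate_metabolome(
    n_subjects: int = 8,
    methods: Sequence[str] = ("frozen", "omnigene", "ethanol", "fta"),
    n_features: int = 300,
    icc_range: tuple[float, float] = (0.2, 0.9),
    censor_quantile: float = 0.25,
    seed: int | None = None,
    method_censor_shift: Mapping[str, float] | None = None,
    known_fraction: float = 0.2,
    baseline_mean: float = 14.0,
    baseline_sd: float = 3.0,
    feature_prefix: str = "MET",
    feature_names: Sequence[str] | None = None,
) -> tuple[FeatureTable, SampleDesign, SyntheticTruth]:
    """Intensity table with per-feature ICCs and detection-limit censoring.

    Latent log-intensities follow the paired variance-components model with
    per-feature true ICC drawn uniformly from ``icc_range`` (unit total
    variance) on top of a wide per-feature baseline; intensities are the
    exponential of the latent values.  Per feature, values below that
    feature's empirical ``censor_quantile`` (plus an optional per-method
    shift, so methods can differ in detectability) are set missing.
    """
    lo, hi = icc_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValidationError("icc_range must satisfy 0 <= lo <= hi <= 1")
    if not (0.0 <= censor_quantile < 1.0):
        raise ValidationError("censor_quantile must be in [0, 1)")
    if seed is None:
        raise ValidationError("seed is required")
    rng = np.random.default_rng(seed)
    subjects = [f"S{i + 1:03d}" for i in range(n_subjects)]
    design = _design_for(subjects, methods)
    n_methods = len(methods)
    if feature_names is not None:
        if len(feature_names) != n_features:
            raise ValidationError("feature_names length must equal n_features")
        feature_ids = list(feature_names)
    else:
        feature_ids = [f"{feature_prefix}{k + 1:04d}" for k in range(n_features)]

    true_icc = rng.uniform(lo, hi, size=n_features)
    sigma_b2 = true_icc  # unit total variance
    sigma_w2 = 1.0 - true_icc
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_features)
    subj_eff = rng.normal(size=(n_features, n_subjects)) * np.sqrt(sigma_b2)[:, None]
    latent = np.empty((n_features, n_subjects * n_methods))
    sample_ids = []
    col = 0
    for j, meth in enumerate(methods):
        for i, subj in enumerate(subjects):
            noise = rng.normal(size=n_features) * np.sqrt(sigma_w2)
            latent[:, col] = baseline + subj_eff[:, i] + noise
            sample_ids.append(f"{subj}.{meth}")
            col += 1

    values = np.exp(latent)
    if censor_quantile > 0.0:
        shifts = dict(method_censor_shift or {})
        for j, meth in enumerate(methods):
            q = float(np.clip(censor_quantile + shifts.get(meth, 0.0), 0.0, 0.999))
            if q <= 0.0:
                continue
            cols = slice(j * n_subjects, (j + 1) * n_subjects)
            thresh = np.quantile(latent, q, axis=1)  # pooled per-feature quantile
            mask = latent[:, cols] < thresh[:, None]
            block = values[:, cols]
            block[mask] = np.nan
            values[:, cols] = block
    data = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    table = FeatureTable(data, "intensity")
    n_known = int(round(known_fraction * n_features))
    known = sorted(
        rng.choice(feature_ids, size=n_known, replace=False).tolist()
    ) if n_known else []
    truth = SyntheticTruth(
        true_icc=true_icc,
        sigma_b2=sigma_b2,
        sigma_w2=sigma_w2,
        seed=seed,
        censor_quantile=censor_quantile,
        known_features=known,
    )
    return table, design, truth
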