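"""End-to-end concordance pipeline: inputs -> report sections -> files.

The report mirrors the structure of a collection-method comparison study:
per-method ICCs for alpha-diversity indices, a distance-based ICC with
bootstrap CI for beta-diversity, per-phylum ICCs on square-root relative
abundances, a detectability/overlap block for metabolites, per-method
metabolite ICC distributions, per-SCFA ICCs, and a taxon-SCFA Spearman
screen.  Every random step draws its seed from a single seed stream, so
identical config + inputs produce identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import bootstrap_distance_icc, icc_oneway_with_ci
from .correlation import correlation_screen, screen_to_frame
from .diversity import (
    alpha_diversity,
    distance_matrix,
    pcoa,
    relative_abundance,
    sqrt_transform,
)
from .group_tests import kruskal_wallis, permanova
from .io_model import (
    FeatureTable,
    SampleDesign,
    TaxonomyMap,
    ValidationError,
    aggregate_by_rank,
    filter_low_depth,
    pair_by_subject,
    read_design,
    read_feature_table,
    read_taxonomy,
)
from .metabolome_prep import (
    detectability,
    detectability_table,
    filter_by_detectability,
    metabolite_icc_profile,
    preprocess_method,
)

logger = logging.getLogger(__name__)

ALPHA_INDICES = ("shannon", "simpson", "chao1")

DEFAULT_CONFIG: dict[str, Any] = {
    "min_reads": 1000,
    "permutations": 999,
    "bootstrap": 1000,
    "seed": 0,
    "detectability_levels": [0.5, 0.75, 1.0],
    "icc_detectability_level": 0.75,
    "n_top_taxa": 3,
    "taxa_for_icc": None,          # explicit phylum list overrides n_top_taxa
    "taxon_rank": "phylum",
    "alpha": 0.05,
    "bonferroni_m": None,
    "scfa_panel": [],
    "scfa_correlate": [],
    "distance_on": "counts",       # or "proportion"
    "pcoa_axes": 2,
    "inputs": {},
}


class _SeedStream:
    """Deterministic stream of child seeds derived from one base seed."""

    def __init__(self, base_seed: int):
        self._state = iter(
            np.random.SeedSequence(base_seed).generate_state(100000).tolist()
        )

    def next(self) -> int:
        return int(next(self._state))


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: Mapping[str, Any]) -> dict[str, Any]:
    cfg = {**DEFAULT_CONFIG, **dict(user)}
    if "gold_method" not in cfg:
        raise ValidationError("config must name gold_method")
    return cfg


def config_hash(cfg: Mapping[str, Any]) -> str:
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# sections
# ---------------------------------------------------------------------------

def run_microbiome_concordance(
    count_table: FeatureTable,
    taxonomy: TaxonomyMap,
    design: SampleDesign,
    config: Mapping[str, Any],
    seeds: _SeedStream | None = None,
) -> dict[str, Any]:
    """Alpha/beta diversity concordance plus per-taxon ICCs."""
    cfg = merge_config(config)
    seeds = seeds or _SeedStream(cfg["seed"])
    B = cfg["bootstrap"]

    table, dropped = filter_low_depth(count_table, cfg["min_reads"])
    design_r = design.restrict_to(table.sample_ids)
    if not design_r.samples_for_method(design.gold_method):
        raise ValidationError("no gold-standard samples survive the depth filter")
    methods = [m for m in design_r.methods if m != design_r.gold_method]

    alpha = alpha_diversity(table)
    group_labels = [design_r.method_of(s) for s in alpha.index]
    kw = {
        idx: kruskal_wallis(alpha[idx].to_numpy(), group_labels).to_dict()
        for idx in ALPHA_INDICES
        if idx in alpha.columns
    }
    alpha_icc: dict[str, dict[str, dict]] = {}
    for method in methods:
        alpha_icc[method] = {}
        for idx in ALPHA_INDICES:
            pairs = pair_by_subject(alpha[idx], design_r, method, variable=idx)
            est = icc_oneway_with_ci(pairs, B=B, seed=seeds.next())
            alpha_icc[method][idx] = est.to_dict()

    dist_input = table if cfg["distance_on"] == "counts" else relative_abundance(table)
    dm = distance_matrix(dist_input, metric="braycurtis")
    perm = permanova(
        dm,
        [design_r.method_of(s) for s in dm.sample_ids],
        n_permutations=cfg["permutations"],
        seed=seeds.next(),
    )
    ordination = pcoa(dm, n_axes=cfg["pcoa_axes"])
    beta_icc = {
        method: bootstrap_distance_icc(
            dm, design_r, method, B=B, seed=seeds.next()
        ).to_dict()
        for method in methods
    }

    proportions = relative_abundance(table)
    by_rank = aggregate_by_rank(proportions, taxonomy, cfg["taxon_rank"])
    if cfg["taxa_for_icc"]:
        taxa = [t for t in cfg["taxa_for_icc"] if t in by_rank.feature_ids]
    else:
        means = by_rank.data.mean(axis=1).sort_values(ascending=False)
        taxa = list(means.index[: cfg["n_top_taxa"]])
    transformed = sqrt_transform(by_rank)
    taxa_icc: dict[str, dict[str, dict]] = {}
    for method in methods:
        taxa_icc[method] = {}
        for taxon in taxa:
            pairs = pair_by_subject(
                transformed.data.loc[taxon], design_r, method, variable=taxon
            )
            est = icc_oneway_with_ci(pairs, B=B, seed=seeds.next())
            taxa_icc[method][taxon] = est.to_dict()

    return {
        "dropped_low_depth_samples": dropped,
        "alpha_diversity": {
            "per_sample": alpha.round(10).to_dict(orient="index"),
            "kruskal_wallis": kw,
            "icc": alpha_icc,
        },
        "beta_diversity": {
            "permanova": perm.to_dict(),
            "pcoa": {
                "eigenvalues": [round(float(v), 10) for v in ordination.eigenvalues],
                "proportion_explained": [
                    round(float(v), 10) for v in ordination.proportion_explained
                ],
            },
            "distance_icc": beta_icc,
        },
        "taxa_icc": {"rank": cfg["taxon_rank"], "taxa": taxa, "icc": taxa_icc},
        "_artifacts": {
            "alpha_table": alpha,
            "distance_matrix": dm,
            "pcoa_coordinates": ordination.coordinates,
        },
    }


def run_metabolome_concordance(
    intensity_table: FeatureTable,
    design: SampleDesign,
    config: Mapping[str, Any],
    known_features: list[str] | None = None,
) -> dict[str, Any]:
    """Detectability/overlap block plus per-method metabolite ICC profiles."""
    cfg = merge_config(config)
    level = cfg["icc_detectability_level"]
    levels = [0.0] + list(cfg["detectability_levels"])
    design_r = design.restrict_to(intensity_table.sample_ids)
    if design_r.gold_method not in design_r.methods:
        raise ValidationError("gold method absent from intensity table")

    block = detectability_table(
        intensity_table, design_r, known_features=known_features, levels=levels
    )
    block_rows = [s.__dict__ for s in block]

    methods = [m for m in design_r.methods if m != design_r.gold_method]
    gold_prep = preprocess_method(
        filter_by_detectability(
            intensity_table, design_r, design_r.gold_method, level
        ),
        design_r,
        design_r.gold_method,
    )
    profiles: dict[str, Any] = {}
    per_feature: dict[str, pd.DataFrame] = {}
    for method in methods:
        method_prep = preprocess_method(
            filter_by_detectability(intensity_table, design_r, method, level),
            design_r,
            method,
        )
        shared = [
            f for f in gold_prep.feature_ids if f in set(method_prep.feature_ids)
        ]
        if not shared:
            profiles[method] = None
            logger.warning("no shared features at level %s for %s", level, method)
            continue
        summary, estimates = metabolite_icc_profile(
            gold_prep, method_prep, design_r, method, features=shared
        )
        entry: dict[str, Any] = {"all": summary.__dict__}
        if known_features:
            shared_known = [f for f in shared if f in set(known_features)]
            if len(shared_known) >= 2:
                k_summary, _ = metabolite_icc_profile(
                    gold_prep, method_prep, design_r, method, features=shared_known
                )
                entry["known"] = k_summary.__dict__
        profiles[method] = entry
        per_feature[method] = pd.DataFrame(
            [
                {"feature_id": fid, "icc": est.estimate, "n_subjects": est.n_subjects}
                for fid, est in estimates.items()
            ]
        )
    return {
        "detectability_levels": levels,
        "icc_detectability_level": level,
        "table1": block_rows,
        "icc_profiles": profiles,
        "_artifacts": {"per_feature_icc": per_feature},
    }


def run_targeted_concordance(
    scfa_table: FeatureTable,
    design: SampleDesign,
    config: Mapping[str, Any],
    seeds: _SeedStream | None = None,
) -> dict[str, Any]:
    """Per-SCFA detectability and ICC + bootstrap CI, per method."""
    cfg = merge_config(config)
    seeds = seeds or _SeedStream(cfg["seed"])
    level = cfg["icc_detectability_level"]
    B = cfg["bootstrap"]
    design_r = design.restrict_to(scfa_table.sample_ids)
    panel = list(cfg["scfa_panel"]) or scfa_table.feature_ids
    present, skipped = [], []
    for name in panel:
        (present if name in scfa_table.data.index else skipped).append(name)
    for name in skipped:
        logger.warning("configured SCFA %r absent from table; skipped", name)

    methods = [m for m in design_r.methods if m != design_r.gold_method]
    detect = {
        m: detectability(scfa_table, design_r, m).loc[present] for m in design_r.methods
    }
    icc: dict[str, dict[str, Any]] = {}
    for method in methods:
        icc[method] = {}
        for name in present:
            if (
                detect[design_r.gold_method][name] < level - 1e-12
                or detect[method][name] < level - 1e-12
            ):
                continue  # below detectability cut: reported only in detect block
            pairs = pair_by_subject(
                scfa_table.data.loc[name], design_r, method, variable=name
            )
            est = icc_oneway_with_ci(pairs, B=B, seed=seeds.next())
            icc[method][name] = est.to_dict()
    return {
        "panel": present,
        "skipped": skipped,
        "detectability": {
            m: {k: round(float(v), 10) for k, v in d.items()} for m, d in detect.items()
        },
        "icc": icc,
    }


def run_correlation_screen(
    count_table: FeatureTable,
    taxonomy: TaxonomyMap,
    scfa_table: FeatureTable,
    design: SampleDesign,
    config: Mapping[str, Any],
) -> dict[str, Any]:
    """Genus-level Spearman screen against configured SCFAs, per method."""
    cfg = merge_config(config)
    table, _ = filter_low_depth(count_table, cfg["min_reads"])
    genera = sqrt_transform(
        aggregate_by_rank(relative_abundance(table), taxonomy, "genus")
    )
    scfa_names = [
        n for n in (cfg["scfa_correlate"] or scfa_table.feature_ids)
        if n in scfa_table.data.index
    ]
    if not scfa_names:
        return {"methods": {}, "n_scfa": 0}
    scfa_sub = FeatureTable(scfa_table.data.loc[scfa_names], scfa_table.kind)
    design_taxa = design.restrict_to(table.sample_ids)
    methods = [
        m for m in design.methods
        if design_taxa.samples_for_method(m)
        and any(s in scfa_table.data.columns for s in design.samples_for_method(m))
    ]
    sections: dict[str, Any] = {}
    for method in methods:
        results = correlation_screen(
            genera, scfa_sub, design, method,
            alpha=cfg["alpha"], m_tests=cfg["bonferroni_m"],
        )
        sections[method] = [r.to_dict() for r in results]
    return {"methods": sections, "n_scfa": len(scfa_names)}


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _strip_artifacts(section: dict[str, Any]) -> dict[str, Any]:
    return {k: v for k, v in section.items() if not k.startswith("_")}


def _read_known_features(path: str | Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    if "known" not in df.columns:
        raise ValidationError("annotation file needs columns feature_id, known")
    truthy = df["known"].astype(str).str.lower().isin(["1", "true", "yes"])
    return df.loc[truthy, "feature_id"].tolist()


def run_all(config: Mapping[str, Any] | str | Path, out_dir: str | Path) -> dict:
    """Run every section for which the config supplies inputs.

    Writes ``report.json`` plus TSV artifacts into ``out_dir`` and returns
    the report dict.  Identical config + inputs yield byte-identical
    outputs.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = cfg.get("inputs", {})
    if "design" not in inputs:
        raise ValidationError("config inputs must include a design table")
    design = read_design(inputs["design"], cfg["gold_method"])
    seeds = _SeedStream(cfg["seed"])

    report: dict[str, Any] = {
        "metadata": {
            "tool": "omicsconcord",
            "version": __version__,
            "seed": cfg["seed"],
            "bootstrap": cfg["bootstrap"],
            "permutations": cfg["permutations"],
            "gold_method": cfg["gold_method"],
            "config_hash": config_hash(cfg),
        }
    }

    taxonomy = None
    count_table = None
    if "counts" in inputs:
        count_table = read_feature_table(inputs["counts"], "counts")
        if "taxonomy" not in inputs:
            raise ValidationError("counts input requires a taxonomy input")
        taxonomy = read_taxonomy(inputs["taxonomy"])
        section = run_microbiome_concordance(
            count_table, taxonomy, design, cfg, seeds=seeds
        )
        art = section["_artifacts"]
        art["alpha_table"].round(10).to_csv(out / "alpha_diversity.tsv", sep="\t")
        art["distance_matrix"].write_tsv(out / "bray_curtis.tsv")
        art["pcoa_coordinates"].round(10).to_csv(
            out / "pcoa_coordinates.tsv", sep="\t", index_label="sample_id"
        )
        report["microbiome"] = _strip_artifacts(section)
        logger.info("microbiome section complete")

    if "metabolites" in inputs:
        intensity = read_feature_table(inputs["metabolites"], "intensity")
        known = (
            _read_known_features(inputs["metabolite_annotations"])
            if "metabolite_annotations" in inputs
            else None
        )
        section = run_metabolome_concordance(intensity, design, cfg, known_features=known)
        for method, df in section["_artifacts"]["per_feature_icc"].items():
            df.round(10).to_csv(
                out / f"metabolite_icc_{method}.tsv", sep="\t", index=False
            )
        pd.DataFrame(section["table1"]).to_csv(
            out / "detectability_table.tsv", sep="\t", index=False
        )
        report["metabolome"] = _strip_artifacts(section)
        logger.info("metabolome section complete")

    if "scfa" in inputs:
        scfa = read_feature_table(inputs["scfa"], "intensity")
        report["targeted"] = run_targeted_concordance(scfa, design, cfg, seeds=seeds)
        logger.info("targeted section complete")
        if count_table is not None and taxonomy is not None:
            section = run_correlation_screen(count_table, taxonomy, scfa, design, cfg)
            rows = [
                row for method_rows in section["methods"].values() for row in method_rows
            ]
            if rows:
                pd.DataFrame(rows).round(10).to_csv(
                    out / "correlation_screen.tsv", sep="\t", index=False
                )
            report["correlations"] = section
            logger.info("correlation section complete")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
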