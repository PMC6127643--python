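# omicsconcord

Concordance evaluation of paired-design omics measurements. Given a study in
which each subject is sampled once per collection method, with one method
designated the gold standard, `omicsconcord` quantifies how well each
alternate method reproduces the gold-standard measurement:

- **io_model** — feature tables (counts / intensities / proportions) from
  TSV/CSV or BIOM v1 JSON, taxonomy maps, sample designs, low-depth sample
  filtering, rank aggregation (with labelled unclassified placeholders), and
  subject-wise pairing of per-sample scalars.
- **diversity** — Shannon (nats), Gini-Simpson, bias-corrected Chao1,
  relative abundance + square-root transform, Bray-Curtis distance matrices,
  and classical-scaling PCoA (negative eigenvalues reported, not corrected).
- **group_tests** — tie-corrected Kruskal-Wallis and seeded one-way
  PERMANOVA with the `(1 + exceedances) / (permutations + 1)` p-value.
- **concordance** — one-way random-effects ICC for paired scalars and a
  distance-based ICC for beta-diversity, both with subject-level percentile
  bootstrap CIs (default B = 1000). Negative estimates are reported, not
  truncated.
- **metabolome_prep** — detectability fractions, detectability-level
  filtering, overlap-with-gold accounting (counts and one-decimal
  percentages, overall and for annotated features), half-minimum imputation,
  Bolstad-style quantile normalization, log10, and per-feature ICC profiles
  summarized as median/IQR.
- **correlation** — Spearman screen between taxa and metabolites per method,
  exact permutation p-values for n ≤ 9 (t-approximation above), Bonferroni
  flags.
- **synthetic_data** — paired-design generators with known variance
  components (true ICC), multinomial sequencing depth, and detection-limit
  censoring, so every stage is testable without any external data.
- **pipeline / cli** — YAML-configured orchestration producing a
  deterministic JSON + TSV report.

## CLI

Generate a synthetic dataset (8 subjects × 5 methods by default) and run the
full pipeline on it:

```bash
omicsconcord simulate --out-dir demo --seed 1
omicsconcord report --config demo/config.yaml --out-dir demo/out
```

`demo/out/report.json` contains every section (alpha/beta diversity ICCs,
PERMANOVA, detectability table, metabolite ICC profiles, per-SCFA ICCs,
correlation screen) plus run metadata (seeds, bootstrap size, config hash);
TSV artifacts (alpha diversity, Bray-Curtis matrix, PCoA coordinates,
per-feature ICCs, detectability table, correlation table) are written
alongside. Reruns with the same config are byte-identical. Individual
sections are available as `diversity`, `concordance`, `metabolome`,
`targeted`, and `correlate` subcommands, all driven by the same config.

To analyse real data, point the config `inputs` at your own tables:
a counts TSV (features × samples), a taxonomy TSV (feature_id, semicolon
lineage), a metadata TSV (sample_id, subject_id, method), and optional
intensity tables for untargeted metabolites and a targeted SCFA panel.

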