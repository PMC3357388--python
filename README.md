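# diurnal

Analysis toolkit for two-condition diurnal transcriptome time courses:
detect per-gene rhythmicity by cosinor/harmonic regression, classify
between-condition rhythm changes into a six-class taxonomy, summarize
acrophase shifts with circular statistics, test gene-set
overrepresentation of change classes, and compute the accompanying
physiology statistics (two-way ANOVA with Bonferroni post-hoc, profile
acrophases, tolerance-test AUC, delta-delta-Ct). A synthetic-data module
generates matched datasets with recorded ground truth so every stage is
testable end to end.

## Concepts

* **Cosinor fit** — OLS of `y(t) = m + a·cos(2πt/T) + b·sin(2πt/T)`
  (period `T` = 24 h by default); amplitude `A = √(a²+b²)`, acrophase
  `φ = (T/2π)·atan2(b, a)` in ZT hours. Rhythmicity is an F-test of the
  harmonic terms with Benjamini–Hochberg correction across genes within
  each condition; expression must be log2 scale.
* **Change classes** — I same-phase rhythmic in both conditions, II
  phase-shifted (|Δφ| ≥ 3 h by default), III rhythmic in condition 1
  only, VI rhythmic in condition 2 only, IV/V baseline up/down among
  genes rhythmic in neither, NC no change. Signed phase differences are
  circular, in (−T/2, T/2]; negative = advance.
* **Circular summary** — mean resultant vector (length R, direction =
  mean shift), Rayleigh uniformity test, and 20°-wedge histograms of
  per-gene shifts.

## CLI

```sh
diurnal simulate   --out-dir data --seed 1 --n-genes 300
diurnal fit-rhythms --matrix data/expression.tsv --samples data/samples.tsv --out rhythms.tsv
diurnal classify   --matrix data/expression.tsv --samples data/samples.tsv --out-dir results
diurnal phase-shift --classes results/classes.tsv --out-dir results
diurnal enrich     --classes results/classes.tsv --gmt data/gene_sets.gmt --out enrichment.tsv
diurnal physiology --profile data/hormones.tsv --tolerance data/tolerance.tsv --out-dir phys
diurnal run-all    --out-dir full_run --seed 1        # simulates when no inputs given
```

Common flags: `--config` (flat YAML mirroring `AnalysisConfig`; CLI
flags override), `--seed`, `--alpha`. `run-all` writes all result
tables plus `manifest.json` with the config, seed and SHA-256 content
hashes; the same config and inputs reproduce every table byte for byte.

## File formats

Tab-separated UTF-8 throughout: expression matrices (first column gene
id, header row sample ids, log2 values), sample tables
(`sample_id  condition  zt  replicate`), long-format physiology
profiles (`condition  zt  replicate  value`), and standard GMT gene
sets.

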