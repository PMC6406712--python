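# csfmet

A CSF metabolomics analysis pipeline that takes a quantified LC-HRMS feature
table (features × injections) all the way to biological results:

1. **Preprocessing** (`csfmet.preprocess`) — blank-based contaminant removal,
   dilution-series correlation filtering (|r| ≥ 0.7), log2 transform, TIC
   outlier removal (< 60% of mean), 75% coverage filtering, QC-anchored LOESS
   drift normalization (span 0.3), QC CV computation on inverse-log2 values,
   technical-replicate averaging, albumin-ratio Spearman filtering and mean
   imputation — in that fixed, provenance-logged order.
2. **Identification** (`csfmet.identification`) — library matching at
   15 ppm / 20 s with MS/MS validation levels (level 1: m/z + RT; level 2:
   fragmentation match via ≥50% coverage or ≥5 shared peaks plus cosine > 0.5).
3. **Age adjustment** (`csfmet.age_adjust`) — linear detrending estimated on
   RRMS + controls and applied to all subjects.
4. **Discrimination** (`csfmet.plsda`) — two-class PLS-DA (single-response
   iterative PLS on autoscaled data), VIP scoring, R²Y/Q², permutation tests,
   and 5-fold × 10-repeat stratified cross-validation yielding averaged VIPs
   with 95% CIs, AUROCs and vertically averaged ROC curves; held-out sample
   projection.
5. **Differential statistics** (`csfmet.diffstats`) — VIP ≥ 1.0 selection,
   log2 fold changes, Welch's t-test, Benjamini–Hochberg FDR, cross-contrast
   name overlap.
6. **Pathway analysis** (`csfmet.pathways`) — hypergeometric
   over-representation with BH FDR across the library and topology impact via
   relative betweenness centrality.
7. **Clinical associations** (`csfmet.associations`) — Spearman correlations
   (exact permutation p for n ≤ 9) of altered metabolites with EDSS, disease
   duration and MRI measures over MS patients, with complete-linkage
   hierarchical clustering of correlation profiles.

Because no patient-level data ship with the package, `csfmet.synthetic`
generates a complete synthetic study — cohort metadata (10 controls /
30 RRMS / 16 SPMS by default), injection sequence with QC + blank pairs every
8th injection and a 0.5–32 µL dilution series, intensity drift, group/age/
albumin effects, contaminants, missingness, an MSP spectral library and a
GMT pathway library — together with the ground truth needed to validate
every stage.

## CLI

```sh
csfmet simulate --seed 1 --outdir study/            # write a synthetic study
csfmet preprocess --features study/features.csv \
    --injections study/injections.csv --samples study/samples.csv \
    --library study/library.msp --outdir clean/
csfmet run-all --seed 1 --outdir run/               # simulate + full analysis
csfmet report --samples study/samples.csv           # demographics table
```

`run-all` writes `cleaned_matrix.csv`, `filter_report.json`, `qc_cv.csv`,
`age_models.csv`, per-contrast `altered_*.csv` / `roc_*.csv` /
`enrichment_*.csv`, `associations.csv` and a `manifest.json` recording
config, seed and per-stage feature/sample counts. A contrast whose model has
Q² < 0 is reported as showing no significant difference and excluded from
downstream tables.

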