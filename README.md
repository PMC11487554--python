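# gutcore

Tools for assessing how completely a culture collection (a strain biobank)
covers a metagenomic community profile, extracting a cohort's core microbiome
with a dual prevalence/abundance threshold, and associating core-taxon
abundances with clinical indices.

The package operates on three plain-text inputs:

- **Abundance tables** (TSV): taxa x samples relative abundances in percent,
  first column `taxon`, optional `#rank=species|genus` pragma.
- **Biobank rosters** (CSV): `strain_id, species, genus, family, phylum,
  novel, deposits`.
- **Clinical tables** (TSV): first column sample ID, numeric index columns
  (e.g. ESR, CRP, anti-CCP, cytokines), optional `cohort` label column;
  empty cells are missing values.

## What it computes

- `abundance`: column closure to 100%, per-taxon mean relative abundance,
  prevalence (FO), abundance strata (low / medium_above >= 0.2% /
  high >= 1%, nested and inclusive), species-to-genus aggregation.
- `roster`: roster summaries per rank, synonym-aware taxon-name matching
  (case folding, underscore/whitespace normalization, "sp." qualifiers
  stripped, extendable synonym CSV), cross-biobank unique species.
- `coverage`: stratified count coverage with one-decimal half-away-from-zero
  percentages computed in exact integer arithmetic, the cultured-but-
  undetected complement, and abundance-mass coverage (a taxon-level
  approximation of sequence-level coverage — not a read-mapping statistic).
- `core`: dominant (mean R.A. >= 0.2%) and common (prevalence >= 80%) gates,
  core = both, ranked by mean abundance; all cuts configurable.
- `association`: Spearman correlation (mid-ranks; exact permutation p for
  n <= 10, t-approximation above) and the two-sided Wilcoxon rank-sum test
  (exact enumeration for small groups, tie/continuity-corrected normal
  approximation otherwise), star annotation (`*` p<0.05 ... `****` p<0.0001),
  optional Benjamini-Hochberg correction.
- `simulate`: seeded zero-inflated log-normal two-cohort generator with
  planted core taxa, planted cohort-differential taxa and planted monotone
  clinical associations, plus recovery checks against the stored truth.

## CLI

```sh
gutcore simulate --seed 7 --out-dir study/          # synthetic study
gutcore profile  --table study/abundance_A.tsv      # mean R.A. / FO / stratum
gutcore core     --table study/abundance_A.tsv --rank genus --k 5
gutcore coverage --table study/abundance_A.tsv --roster study/roster.csv \
                 --stratum medium_above             # JSON coverage report
gutcore undetected --table study/abundance_A.tsv --roster study/roster.csv
gutcore mass-coverage --table study/abundance_A.tsv --roster study/roster.csv
gutcore associate --table study/abundance_A.tsv --clinical study/clinical.tsv \
                  --correction BH                   # long-format TSV
gutcore roster-summary --roster study/roster.csv
```

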