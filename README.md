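# regsnv

An integrative screen for **non-coding somatic single-nucleotide variants
(SNVs) that are recurrently associated with altered expression of nearby
genes — or altered DNA methylation of nearby CpG-island (CGI) probes — in
multi-cancer cohorts**. It is aimed at cancer genomics groups who have
per-sample somatic SNV calls, an expression (and optionally a 450K-style
methylation) matrix, copy-number calls and SV breakpoints, and who want a
tested, reproducible implementation of the regulatory-SNV association
pipeline: region windows, presence matrices, covariate-adjusted linear
models, Storey–Tibshirani FDR, a copy-number-independence filter, and the
downstream annotation of hits (repressor TF-site overlap, SNV density,
hot-mutation-region detection).

## The model

For each gene *g* and each of seven genomic region windows (20 kb / 2 kb /
1 kb upstream of the TSS, introns, 1 kb downstream, 3′ UTR, 5′ UTR — the
upstream windows nest), a binary predictor marks every sample *s* that
carries ≥1 passing SNV in the window. Genes with ≥3 carriers are fit by
ordinary least squares:

```
log2(expr_gs + 1) = β0 + β_snv·SNV_gs + Σ_t β_t·type_ts + β_sex·sex_s
                    + β_b·log2(burden_s) + β_sv·log10(d_gs + 1) + ε
```

where `burden_s` is the sample's total SNV count and `d_gs` the distance
from the gene start to the sample's nearest SV breakend (capped at 1 Mb).
The two-sided t-test p-value for `β_snv` is converted, per region, to a
Storey–Tibshirani q-value (π0 estimated on the λ = 0.05…0.95 grid). Hits at
FDR < 10% are refit with the gene's copy number added; only associations
that stay significant (P < 0.05) count — i.e. that are not explained by a
copy-number alteration. The methylation arm applies the identical engine to
logit-transformed beta values of autosomal CGI probes, joined to genes via
the array manifest.

Downstream, significant upstream genes are annotated in carrier samples
with elevated expression (> 0.4 SD above the cohort median): overlap of
their SNVs with binding sites of 20 repressor/chromatin TFs, SNVs per
patient, and hot mutation regions (≥5 patients, ≥10 SNVs, inter-SNV gaps
≤30 bp).

Because the screens demand cohort-scale controlled-access data, the package
ships a first-class synthetic cohort generator (`regsnv.synthetic_data`)
that plants cis effects of known size, copy-number- and SV-confounded
genes, and null genes, together with a truth ledger, so sensitivity,
realized FDR and confounder rejection are measurable end to end.

## Worked example

```bash
python analysis/01_simulate_cohort.py     # writes scratch/cohort/
python analysis/02_expression_screen.py   # writes results/expression_results.tsv
python analysis/03_methylation_screen.py
python analysis/04_annotate_hits.py
```

The demo cohort has 200 samples × 500 genes (≈300 SNVs per sample), with 5
planted expression effects (+2 log2 units in ≥5% carriers), 4 planted
methylation effects (+1.5 logit units), and 3 copy-number- plus 3
SV-confounded genes. Script 02 prints:

```
significant gene x region results at FDR<10% + CNA filter: 13
         n_significant  n_positive
up1kb                6           6
up2kb                7           5
...
recovered 5/5 planted genes in their planted region; realized FDR 0.231;
CNA-confounded leak rate 0.0
```

All 5 planted genes are recovered in their planted window (and again in the
nesting 2 kb window — the same SNVs are genuinely inside both); the three
copy-number-driven genes are called by the marginal model and then removed
by the copy refit (leak rate 0.0). Script 04 then reports, for the 8 genes
significant 1–2 kb upstream, that 67 upstream SNV events occur in samples
with elevated expression, 10.4% of them inside repressor TF binding sites,
≈1.1 SNVs per elevated patient, and 0 hot mutation regions — a diffuse
mutational background does not produce 10 SNVs within 30 bp chains, which
is exactly why hot regions flag biology when they do appear.

The same functionality is exposed as subcommands
(`regsnv simulate | build-matrix | sv-distance | associate-expression |
associate-methylation | tf-annotate | hotspots | density | methyl-context |
overlap-hits | compare-cohorts | run-all`); `regsnv run-all` executes every
stage from a flat key=value config file and writes hash-tagged tables.

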