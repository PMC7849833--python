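# Methods

## Screen model and assumptions

Both arms of the screen are covariate-adjusted ordinary least squares with
a binary "SNV presence" predictor. For a gene (expression arm) or a
CGI probe joined to its gene (methylation arm), the response is
`log2(x + 1)` expression or `logit(beta)` methylation, and the design is

    [1, snv, cancer-type dummies (reference level dropped), gender,
     log2(total SNV burden), log10(SV breakpoint distance + 1), (copy)]

Assumptions: additive covariate effects, homoscedastic Gaussian residuals
on the transformed scale, and carriers exchangeable within a region window.
The SNV coefficient's two-sided t-test p-value is the screen statistic.
Samples missing the response, a covariate or (in the refit) the copy value
are dropped listwise per fit; constant design columns (e.g. gender in a
single-sex cohort, copy = 2 everywhere) are dropped rather than allowed to
make the design singular. A rank-deficient design skips the gene with
reason "collinear"; an exactly interpolating fit (zero residual variance)
reports p = 1 and is flagged, except in the methylation–expression
correlation where an exact fit means an infinite t-statistic and the
minimum representable p is reported.

Fits use a column-scaled QR factorisation (numpy/scipy); the test suite
verifies equality with an explicit normal-equations oracle and with
statsmodels OLS to 1e-8 in both coefficients and p-values.

## Region windows

All internal coordinates are 0-based half-open; VCF and GTF inputs are
converted on read. "Upstream" is anchored at the transcription start of the
canonical transcript (the longest per gene; ties broken by smallest
transcript id) and is strand-aware; an SNV exactly at the TSS base belongs
to the gene body, not upstream. The intron window is the union of the
canonical transcript's introns; UTR windows come from exon∕CDS geometry and
are empty (not an error) for non-coding genes. Windows are clipped at
chromosome base 0 and are *not* truncated at neighbouring genes — a
single SNV may legitimately sit in several genes' windows, matching the
per-gene independent tests. Window sizes (20000/2000/1000/1000) are
configurable.

## Multiple testing and the copy-number filter

q-values follow Storey–Tibshirani: pi0 is estimated from the p-value
histogram on the grid λ = 0.05, 0.10, …, 0.95 via a natural cubic spline
through π0(λ) evaluated at λ = 0.95, clamped to [0, 1]; with fewer than 100
p-values π0 is pinned to 1, making the procedure exactly
Benjamini–Hochberg (the suite asserts this equivalence, plus q-monotonicity
in p). q-values are computed within each region, not pooled, so each
region's significant-gene count is self-contained.

Hits at q < 0.10 are refit with the gene's numeric copy value appended
(thresholded −2..+2 calls are used as-is). The hit survives only if the SNV
term stays below P < 0.05 — associations carried by copy-number dosage lose
their SNV coefficient once copy enters the design and are discarded.

## SV-distance covariate

Per gene and sample: the distance from the strand-aware gene start to the
sample's nearest breakend on that chromosome, capped at 1 Mb, with 1 Mb
imputed when no breakend exists. The model enters `log10(d + 1)` because
raw distances span six orders of magnitude and their effect on expression
is plausibly multiplicative in scale; the covariate is bounded, monotone in
d, and 0 at a breakend through the gene start.

## Downstream annotation

*Elevated expression*: sample value > 0.4 SD above the cohort **median**,
with SD the usual n−1 standard deviation about the mean. The mixed
centre/scale is deliberate and documented because the annotation is a
robust-centre heuristic, not a z-test; a zero-variance row flags nobody.

*TF-site overlap* considers only a fixed set of 20
repressor/chromatin-remodelling TFs (BAF170 … ZHX1, exact uppercase match);
every (SNV, patient) event counts once and an SNV inside two sites yields
two association rows.

*Hot mutation regions* are maximal single-linkage chains of SNV events on
sorted positions with inter-SNV gaps ≤ 30 bp, kept when they contain ≥10
SNVs from ≥5 patients. Output is order-invariant and emitted regions are
disjoint with >30 bp between them.

*Exon-boundary flag*: an intronic SNV is "boundary-proximal" when its
distance to the nearest exon–intron junction (first intronic base = 1) is
at most a configurable window, default 10 bases — the default is an
assumption, chosen to capture canonical splice-site disruption.

## Synthetic cohorts

`synthetic_data.simulate_cohort` emulates the statistical structure the
screens assume, on a compact synthetic genome (genes of 5 kb with three
exons, tiled every 30 kb on one chromosome, random strands):

- **Background SNVs**: per-sample burden is lognormal (σ = 0.5) around a
  uniform per-base rate of 2×10⁻⁵ — ≈1200 SNVs per sample on the 60 Mb
  default genome, a deliberately compressed genome with realistic
  per-window carrier frequencies (a 1 kb window averages ~6 carriers in
  300 samples). The burden covariate is computed from the realized counts,
  so hypermutated samples genuinely exercise it.
- **Planted effects**: default 20 expression genes (+2 log2 units) and 10
  methylation probes (+1.5 logit units) with carriers (5% of samples,
  minimum 3 — infeasible configs raise) receiving one SNV uniformly in the
  gene's 1 kb-upstream window.
- **Expression**: per-gene baseline N(8, 2) on the log2 scale, per-(gene,
  cancer-type) shifts N(0, 0.5), residual N(0, 1); raw values are
  `2^z − 1` so the pipeline's log2(x+1) recovers z exactly.
- **Methylation**: per-probe baseline N(−1, 1) on the logit scale, residual
  N(0, 0.5), inverse-logit to betas; one probe per gene for the first
  `n_probes` genes, plus decoy probes (chrX or CGI-less) that the filter
  must remove.
- **Confounders**: copy-number-confounded genes have ~25% amplified samples
  (copies 3–5), expression +1 log2 per copy above 2, and carriers drawn
  only from amplified samples — the SNV association is real but entirely
  copy-driven, which the refit must reject. SV-confounded genes shift
  expression linearly in `6 − log10(d+1)` with targeted breakends near the
  gene start and carriers drawn from the rearranged samples, so the SV
  covariate can absorb the confound exactly.

What the generator does **not** emulate: sequence context and mutational
signatures, linkage between nearby genes' expression, coupling between
methylation and expression (they are generated independently, so the
methylation–expression correlation and the expression∕methylation hit
overlap exercise their *null* behaviour on simulated cohorts and their
alternative behaviour only on crafted test fixtures), multi-chromosome
genomes, and read-level noise. Passing recovery tests therefore show the
inference machinery is correct under the model's own assumptions, not that
real cohorts satisfy those assumptions.

## Benchmark problem sizes and results

The benchmark runs (`regsnv.evaluation`, `scripts/acceptance.py`,
`analysis/05_calibration_benchmarks.py`) use 2000 genes × 300 samples:
20 null-calibration seeds, 10 recovery seeds, 10 copy-confounder seeds and
5 methylation seeds, plus a 50-gene × 200-sample × 200-permutation
uniformity check pooled over ~10⁴ p-values. Measured at these sizes:
recovery sensitivity ≈ 0.99 with realized FDR ≈ 0.12 at q < 0.10; the copy
refit rejects ≈ 93% of confounded genes called pre-filter; methylation
sensitivity 1.0; permutation KS distance ≈ 0.008.

One property worth understanding rather than "fixing": an all-null cohort
yields **zero** significant calls in only ~half of seeds (measured 11/20).
This is the expected behaviour of any FDR procedure controlling at
q < 0.10 — under the global null BH rejects ≥1 feature with probability
≈ α per region (it is the Simes test), and seven regions compound it. The
per-test p-values are uniform (the KS check above), i.e. the screen is
calibrated; expecting a ≥95% zero-call rate at α = 0.10 is not a property
a correct implementation can have.

## Numerical choices and degenerate inputs

- Expression pseudocount 1; beta values clipped to [1e-6, 1−1e-6] before
  the logit (round-trips to 1e-9 inside the clip range).
- p-values are floored at the smallest positive double, keeping them in
  (0, 1] for the q-value machinery.
- Collinearity is declared when a column-scaled QR diagonal falls below
  1e-8 of the maximum; zero residual variance below 1e-12 of total
  variance.
- Ties: canonical transcripts by smallest id; dominant cancer type in the
  density table by lexicographic order; q-value ties share the running
  minimum.
- Fisher/hypergeometric overlap tests take an explicit universe (the genes
  tested in both arms for that region); a hit set larger than the universe
  is an error, an empty universe is skipped.

## Known limitations

- One canonical transcript per gene; isoform-specific windows are out of
  scope.
- The SV covariate uses breakend positions only; SV class is ignored.
- The biophysical TF-binding-affinity scoring that would rank hot-region
  mutations is out of scope; only the block detection is implemented.
- No array normalisation or expression-pipeline harmonisation: matrices
  are taken as provided.
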