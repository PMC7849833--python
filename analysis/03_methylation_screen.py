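#!/usr/bin/env python
"""Methylation arm: CGI probes, logit betas, SNV screen, context breakdowns.

Reads the simulated bundle (01) and the expression results (02), filters
probes to autosomal CpG islands, runs the SNV screen on logit-transformed
betas with the same covariates and copy refit, breaks hits down by promoter
association and position class, correlates methylation with expression, and
tests the overlap between methylation-hit and expression-hit genes per
region.  Tables land under results/.
"""

from pathlib import Path

import pandas as pd

from regsnv import assoc, io_formats, methyl, sv_distance
from regsnv.regions import build_all_presence_matrices
from regsnv.synthetic_data import evaluate_recovery

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

snvs = io_formats.read_snvs(COHORT / "snvs.tsv", "table")
genes = io_formats.read_gene_models(COHORT / "genes.gtf")
betas = io_formats.read_matrix(COHORT / "betas.tsv")
manifest = io_formats.read_probe_manifest(COHORT / "probe_manifest.tsv")
expression = io_formats.read_matrix(COHORT / "expression.tsv")
covariates = io_formats.read_covariates(COHORT / "covariates.tsv")
breakends = io_formats.read_breakends(COHORT / "sv.bedpe")
copy_number = io_formats.read_matrix(COHORT / "copy_number.tsv")
truth = pd.read_csv(COHORT / "truth.tsv", sep="\t")
samples = list(covariates.index)

kept = methyl.filter_cgi_probes(manifest)
print(f"probe filter: {len(kept)} autosomal CGI probes kept of {len(manifest)}")

presence = build_all_presence_matrices(snvs, genes, samples)
sv_cov = sv_distance.sv_covariate(
    sv_distance.breakpoint_distance_matrix(breakends, genes, samples)
)
results = methyl.run_methylation_screen(
    presence, betas, kept["gene"], covariates, sv_cov, copy_number
)
results.to_csv(RESULTS / "methylation_results.tsv", sep="\t", index=False)
score = evaluate_recovery(results, truth, 0.10, feature_type="probe")
print(f"significant probe x region results: {int(results['significant'].sum())}; "
      f"recovered {score['n_recovered']}/{score['n_planted']} planted probes")

sig = results[results["significant"]]
context = methyl.context_breakdown(
    {"+": sig[sig["direction"] == "+"]["feature_id"].unique(),
     "-": sig[sig["direction"] == "-"]["feature_id"].unique()},
    results["feature_id"].unique(), kept,
)
context.to_csv(RESULTS / "methylation_context.tsv", sep="\t", index=False)
print(context[["direction", "n_hits", "promoter_fraction",
               "background_promoter_fraction", "promoter_chi2_p"]])

corr = methyl.methylation_expression_correlation(
    betas, assoc.log_transform(expression), kept["gene"], covariates, copy_number
)
corr.to_csv(RESULTS / "methylation_expression_correlation.tsv", sep="\t",
            index=False)
n_inv = int(((corr["coef"] < 0) & corr["significant"]).sum())
print(f"methylation-expression correlation: {int(corr['significant'].sum())} "
      f"significant pairs at FDR<5% ({n_inv} inverse)")

expr_results = pd.read_csv(RESULTS / "expression_results.tsv", sep="\t")
rows = []
for region in sorted(set(results["region"]) & set(expr_results["region"])):
    er = expr_results[expr_results["region"] == region]
    mr = results[results["region"] == region]
    universe = sorted(set(er["gene_id"]) & set(mr["gene_id"]))
    if not universe:
        continue
    ov = methyl.overlap_expression_methylation_hits(
        er[er["significant"]]["gene_id"].unique(),
        mr[mr["significant"]]["gene_id"].unique(), universe,
    )
    ov.pop("overlap_genes")
    rows.append({"region": region, **ov})
overlap = pd.DataFrame(rows)
overlap.to_csv(RESULTS / "hit_overlap.tsv", sep="\t", index=False)
print(overlap)
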