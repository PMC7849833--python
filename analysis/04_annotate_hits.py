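#!/usr/bin/env python
"""Annotate significant genes: elevation, TF-site overlap, density, hotspots.

For genes significant in the 1-2 kb upstream screens (02): flag the carrier
samples with elevated expression (>0.4 SD above the cohort median), overlap
their upstream SNVs with repressor TF binding sites, tabulate SNVs per
patient, and chain SNVs into hot mutation regions (>=5 patients, >=10 SNVs,
gaps <=30 bp).  Also counts how many intronic SNV events touch exon-intron
boundaries.
"""

from pathlib import Path

import pandas as pd

from regsnv import annotate, assoc, io_formats
from regsnv.regions import RegionKind, region_snv_events

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

snvs = io_formats.read_snvs(COHORT / "snvs.tsv", "table")
genes = io_formats.read_gene_models(COHORT / "genes.gtf")
expression = assoc.log_transform(io_formats.read_matrix(COHORT / "expression.tsv"))
covariates = io_formats.read_covariates(COHORT / "covariates.tsv")
tf_sites = io_formats.read_tf_sites(COHORT / "tf_sites.bed")
results = pd.read_csv(RESULTS / "expression_results.tsv", sep="\t")

upstream = results[
    results["region"].isin(["up1kb", "up2kb"]) & results["significant"]
]
sig_genes = sorted(upstream["gene_id"].unique())
print(f"{len(sig_genes)} genes significant for the 1-2 kb upstream region")

elevated = {g: annotate.elevated_samples(expression.loc[g]) for g in sig_genes}
events = region_snv_events(
    snvs, [g for g in genes if g.gene_id in set(sig_genes)], RegionKind.UP2KB
)
elev_events = events[
    events.apply(lambda r: r.sample_id in set(elevated[r.gene_id]), axis=1)
] if not events.empty else events
print(f"{len(elev_events)} upstream SNV events in samples with elevated expression")

assoc_tbl, per_tf, summary = annotate.tf_overlap(elev_events, tf_sites)
assoc_tbl.to_csv(RESULTS / "tf_associations.tsv", sep="\t", index=False)
per_tf.to_csv(RESULTS / "tf_counts.tsv", sep="\t", index=False)
print(f"{summary.iloc[0]['n_in_sites']} of {summary.iloc[0]['n_events']} events "
      f"({summary.iloc[0]['fraction_in_sites']:.1%}) fall in repressor TF sites")
if not per_tf.empty:
    top = per_tf.sort_values('n_events', ascending=False).iloc[0]
    print(f"most-hit TF: {top['tf_name']} ({top['n_events']} events)")

density = annotate.snv_density(sig_genes, events, elevated,
                               covariates["cancer_type"])
density.to_csv(RESULTS / "snv_density.tsv", sep="\t", index=False)
print("SNVs per elevated patient (upstream):")
print(density.sort_values("snvs_per_patient", ascending=False).head())

hot_rows = []
for gene_id, ev in (elev_events.groupby("gene_id") if not elev_events.empty else ()):
    for hr in annotate.find_hot_regions(ev):
        hot_rows.append({"gene_id": gene_id, "chrom": hr.chrom, "start": hr.start,
                         "end": hr.end, "snv_count": hr.snv_count,
                         "patient_count": hr.patient_count})
hot = pd.DataFrame(hot_rows, columns=["gene_id", "chrom", "start", "end",
                                      "snv_count", "patient_count"])
hot.to_csv(RESULTS / "hot_regions.tsv", sep="\t", index=False)
print(f"{len(hot)} hot mutation regions "
      "(a diffuse background rarely clusters 10 SNVs within 30 bp gaps)")

gene_by_id = {g.gene_id: g for g in genes}
intron_events = region_snv_events(snvs, genes, RegionKind.INTRON)
n_boundary = sum(
    annotate.exon_boundary_flag(r.pos, gene_by_id[r.gene_id], boundary_window=10)
    for r in intron_events.itertuples(index=False)
)
print(f"{n_boundary} of {len(intron_events)} intronic SNV events lie within "
      "10 bases of an exon-intron boundary")
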