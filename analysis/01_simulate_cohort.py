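#!/usr/bin/env python
"""Simulate a multi-cancer cohort with planted cis effects and write the bundle.

Writes the full input bundle (SNV table, GTF gene models, expression /
methylation / copy-number matrices, SV BEDPE, TF-site BED, covariates,
truth ledger) under scratch/cohort/, in the same external formats a real
cohort would arrive in.  Downstream analysis scripts read from there.

The demo cohort is deliberately compact (500 genes, 200 samples, 5 planted
expression effects, 4 planted methylation effects, 3 copy-number- and 3
SV-confounded genes) so the whole walkthrough runs in seconds; the
benchmark script (05) uses the full study conditions.
"""

from pathlib import Path

from regsnv.synthetic_data import SimConfig, simulate_cohort, write_bundle

OUTDIR = Path(__file__).resolve().parent.parent / "scratch" / "cohort"

config = SimConfig(
    n_samples=200, n_genes=500, n_probes=250,
    n_effect_genes_expr=5, n_effect_genes_meth=4,
    n_cna_confounded=3, n_sv_confounded=3,
    seed=2024,
)

bundle = simulate_cohort(config)
paths = write_bundle(bundle, OUTDIR, vcf=False)

n_snvs = len(bundle.snvs)
print(f"cohort: {config.n_samples} samples x {config.n_genes} genes, "
      f"{n_snvs} somatic SNVs ({n_snvs / config.n_samples:.0f} per sample)")
print(f"planted: {config.n_effect_genes_expr} expression effects "
      f"(+{config.effect_size_expr} log2), {config.n_effect_genes_meth} "
      f"methylation effects (+{config.effect_size_meth} logit), "
      f"{config.n_cna_confounded} CNA-confounded, "
      f"{config.n_sv_confounded} SV-confounded genes")
for name, p in paths.items():
    print(f"  {name:12s} -> {p}")
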