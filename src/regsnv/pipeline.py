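"""End-to-end orchestration: inputs -> presence matrices -> screens -> annotation.

``run_all`` executes the stages in dependency order and writes every result
table (tagged with a hash of the configuration) to the output directory.
The expression arm is mandatory; the methylation arm runs only when beta
and manifest paths are configured.  Reruns with identical inputs and config
are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
import numpy as np
import pandas as pd

from . import annotate, assoc, io_formats, methyl, sv_distance
from .assoc import ScreenLog
from .regions import (
    ALL_REGIONS,
    RegionKind,
    build_all_presence_matrices,
    region_snv_events,
)


@dataclass
class PipelineConfig:
    """Paths plus every tunable threshold (defaults follow the screen design)."""

    snvs: str = ""
    snv_format: str = "vcf"           # vcf | table
    genes: str = ""
    gene_format: str = "gtf"          # gtf | bed12
    expression: str = ""
    covariates: str = ""
    sv_bedpe: str = ""
    copy_number: str = ""
    betas: str = ""                   # optional: methylation arm
    probe_manifest: str = ""
    tf_sites: str = ""                # optional: TF annotation
    outdir: str = "results"
    window_up20kb: int = 20000
    window_up2kb: int = 2000
    window_up1kb: int = 1000
    window_down1kb: int = 1000
    min_carriers: int = 3
    fdr_threshold: float = 0.10
    relaxed_fdr: float = 0.25
    cna_alpha: float = 0.05
    z_cut: float = 0.4
    hot_min_patients: int = 5
    hot_min_snvs: int = 10
    hot_max_gap: int = 30
    meth_corr_fdr: float = 0.05
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "relaxed_fdr", "cna_alpha", "meth_corr_fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("window_up20kb", "window_up2kb", "window_up1kb",
                     "window_down1kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def window_sizes(self) -> dict[str, int]:
        return {
            "up20kb": self.window_up20kb, "up2kb": self.window_up2kb,
            "up1kb": self.window_up1kb, "down1kb": self.window_down1kb,
        }

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # output location does not affect the computation
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat key = value config text; '#' starts a comment."""
        kwargs: dict = {}
        fields = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key = value")
            key, val = (x.strip() for x in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
            typ = fields[key]
            if typ == "int":
                kwargs[key] = int(val)
            elif typ == "float":
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_table(df: pd.DataFrame, path: Path, config_hash: str, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(f"# regsnv config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def run_all(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the in-memory tables and log."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    tables: dict[str, pd.DataFrame] = {}
    log: dict = {"config_hash": chash, "stages": [], "skips": {}}

    def stage(name):
        log["stages"].append(name)

    try:
        stage("read_inputs")
        snvs = io_formats.read_snvs(config.snvs, config.snv_format)
        genes = io_formats.read_gene_models(config.genes, config.gene_format)
        raw_expr = io_formats.read_matrix(config.expression)
        covariates = io_formats.read_covariates(config.covariates)
        breakends = io_formats.read_breakends(config.sv_bedpe)
        copy_matrix = (
            io_formats.read_matrix(config.copy_number) if config.copy_number else None
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("read_inputs", exc) from exc

    samples = [s for s in covariates.index if s in raw_expr.columns]
    if not samples:
        raise StageError("read_inputs", ValueError("no samples shared between "
                                                   "covariates and expression"))

    try:
        stage("presence_matrices")
        presence = build_all_presence_matrices(
            snvs, genes, samples, config.window_sizes
        )
        for kind, pm in presence.items():
            _write_table(pm.values, outdir / f"presence_{kind.value}.tsv", chash, True)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("presence_matrices", exc) from exc

    try:
        stage("sv_distance")
        dist = sv_distance.breakpoint_distance_matrix(breakends, genes, samples)
        sv_cov = sv_distance.sv_covariate(dist)
        _write_table(dist, outdir / "sv_breakpoint_distance.tsv", chash, True)
    except Exception as exc:  # noqa: BLE001
        raise StageError("sv_distance", exc) from exc

    try:
        stage("expression_screen")
        expr_log2 = assoc.log_transform(raw_expr, config.pseudocount)
        elog = ScreenLog()
        expr_results = assoc.run_expression_screen(
            presence, expr_log2, covariates, sv_cov, copy_matrix,
            min_carriers=config.min_carriers, fdr_threshold=config.fdr_threshold,
            cna_alpha=config.cna_alpha, log=elog,
        )
        tables["expression_results"] = expr_results
        _write_table(expr_results, outdir / "expression_results.tsv", chash, False)
        log["skips"]["expression"] = elog.skipped
        log["tested"] = {"expression": elog.tested}
    except Exception as exc:  # noqa: BLE001
        raise StageError("expression_screen", exc) from exc

    if config.betas and config.probe_manifest:
        try:
            stage("methylation_screen")
            betas = io_formats.read_matrix(config.betas)
            manifest = io_formats.read_probe_manifest(config.probe_manifest)
            kept = methyl.filter_cgi_probes(manifest)
            probe_gene = kept["gene"]
            mlog = ScreenLog()
            meth_results = methyl.run_methylation_screen(
                presence, betas.loc[betas.index.intersection(kept.index)],
                probe_gene, covariates, sv_cov, copy_matrix,
                min_carriers=config.min_carriers,
                fdr_threshold=config.fdr_threshold,
                cna_alpha=config.cna_alpha, log=mlog,
            )
            tables["methylation_results"] = meth_results
            _write_table(meth_results, outdir / "methylation_results.tsv", chash, False)
            log["skips"]["methylation"] = mlog.skipped

            sig = meth_results[meth_results["significant"]]
            context = methyl.context_breakdown(
                {
                    "+": sig[sig["direction"] == "+"]["feature_id"].unique(),
                    "-": sig[sig["direction"] == "-"]["feature_id"].unique(),
                },
                meth_results["feature_id"].unique(), kept,
            )
            tables["methylation_context"] = context
            _write_table(context, outdir / "methylation_context.tsv", chash, False)

            corr = methyl.methylation_expression_correlation(
                betas, expr_log2, probe_gene, covariates, copy_matrix,
                fdr_threshold=config.meth_corr_fdr,
            )
            tables["methylation_expression_correlation"] = corr
            _write_table(corr, outdir / "methylation_expression_correlation.tsv",
                         chash, False)

            overlap_rows = []
            for kind in ALL_REGIONS:
                region = kind.value
                er = expr_results[expr_results["region"] == region]
                mr = meth_results[meth_results["region"] == region]
                universe = sorted(
                    set(er["gene_id"]) & set(mr["gene_id"])
                )
                if not universe:
                    continue
                res = methyl.overlap_expression_methylation_hits(
                    er[er["significant"]]["gene_id"].unique(),
                    mr[mr["significant"]]["gene_id"].unique(),
                    universe,
                )
                res.pop("overlap_genes")
                overlap_rows.append({"region": region, **res})
            tables["hit_overlap"] = pd.DataFrame(overlap_rows)
            _write_table(tables["hit_overlap"], outdir / "hit_overlap.tsv", chash,
                         False)
        except Exception as exc:  # noqa: BLE001
            raise StageError("methylation_screen", exc) from exc
    else:
        log["skips"]["methylation"] = "not configured; arm skipped"

    try:
        stage("annotation")
        tables.update(
            _annotation_stage(config, snvs, genes, expr_log2, tables,
                              covariates, outdir, chash)
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("annotation", exc) from exc

    (outdir / "run.log").write_text(json.dumps(log, indent=2, default=str) + "\n")
    return {"tables": tables, "log": log, "outdir": str(outdir)}


def _annotation_stage(config, snvs, genes, expr_log2, tables, covariates,
                      outdir, chash) -> dict:
    expr_results = tables["expression_results"]
    out: dict[str, pd.DataFrame] = {}
    upstream = expr_results[
        expr_results["region"].isin([RegionKind.UP1KB.value, RegionKind.UP2KB.value])
        & expr_results["significant"]
    ]
    sig_genes = sorted(upstream["gene_id"].unique())
    elevated = {
        g: annotate.elevated_samples(expr_log2.loc[g], config.z_cut)
        for g in sig_genes if g in expr_log2.index
    }
    events = region_snv_events(
        snvs, [g for g in genes if g.gene_id in set(sig_genes)],
        RegionKind.UP2KB, config.window_sizes,
    )
    elev_events = (
        events[events.apply(
            lambda r: r.sample_id in set(elevated.get(r.gene_id, ())), axis=1)]
        if not events.empty else events
    )
    if config.tf_sites:
        sites = io_formats.read_tf_sites(config.tf_sites)
        assoc_tbl, per_tf, summary = annotate.tf_overlap(elev_events, sites)
        out["tf_associations"] = assoc_tbl
        out["tf_counts"] = per_tf
        out["tf_summary"] = summary
        _write_table(assoc_tbl, outdir / "tf_associations.tsv", chash, False)
        _write_table(per_tf, outdir / "tf_counts.tsv", chash, False)
        _write_table(summary, outdir / "tf_summary.tsv", chash, False)

    density_rows = []
    for kind in (RegionKind.UP2KB, RegionKind.INTRON, RegionKind.UTR3):
        region = kind.value
        if kind is RegionKind.UP2KB:
            region_sig = sig_genes
        else:
            region_sig = sorted(
                expr_results[(expr_results["region"] == region)
                             & expr_results["significant"]]["gene_id"].unique()
            )
        if not region_sig:
            continue
        ev = region_snv_events(
            snvs, [g for g in genes if g.gene_id in set(region_sig)], kind,
            config.window_sizes,
        )
        elev = {
            g: annotate.elevated_samples(expr_log2.loc[g], config.z_cut)
            for g in region_sig if g in expr_log2.index
        }
        dens = annotate.snv_density(region_sig, ev, elev, covariates["cancer_type"])
        dens.insert(0, "region", region)
        density_rows.append(dens)
    out["snv_density"] = (
        pd.concat(density_rows, ignore_index=True) if density_rows
        else pd.DataFrame(columns=["region", "gene_id", "n_patients_elevated",
                                   "snvs_per_patient", "dominant_cancer_type"])
    )
    _write_table(out["snv_density"], outdir / "snv_density.tsv", chash, False)

    hot_rows = []
    for gene_id, ev in (elev_events.groupby("gene_id") if not elev_events.empty else ()):
        for hr in annotate.find_hot_regions(
            ev, config.hot_min_patients, config.hot_min_snvs, config.hot_max_gap
        ):
            hot_rows.append({
                "gene_id": gene_id, "chrom": hr.chrom, "start": hr.start,
                "end": hr.end, "snv_count": hr.snv_count,
                "patient_count": hr.patient_count,
            })
    out["hot_regions"] = pd.DataFrame(
        hot_rows, columns=["gene_id", "chrom", "start", "end", "snv_count",
                           "patient_count"],
    )
    _write_table(out["hot_regions"], outdir / "hot_regions.tsv", chash, False)
    return out


def cross_cohort_compare(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    relaxed_fdr: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes positively SNV-correlated in the same region in both cohorts.

    A gene is a relaxed hit in a cohort when q < ``relaxed_fdr`` with
    direction '+'.  Returns (shared-gene table, per-region summary with a
    one-sided Fisher/hypergeometric enrichment p over the shared tested
    universe).
    """
    from scipy import stats

    regions = sorted(set(results_a["region"]) & set(results_b["region"]))
    universe_any = False
    shared_rows, summary_rows = [], []
    for region in regions:
        ra = results_a[results_a["region"] == region]
        rb = results_b[results_b["region"] == region]
        universe = set(ra["feature_id"]) & set(rb["feature_id"])
        if not universe:
            continue
        universe_any = True
        hits_a = set(ra[(ra["q_snv"] < relaxed_fdr)
                        & (ra["direction"] == "+")]["feature_id"]) & universe
        hits_b = set(rb[(rb["q_snv"] < relaxed_fdr)
                        & (rb["direction"] == "+")]["feature_id"]) & universe
        shared = sorted(hits_a & hits_b)
        for g in shared:
            shared_rows.append({"region": region, "feature_id": g})
        p = float(stats.hypergeom.sf(len(shared) - 1, len(universe),
                                     len(hits_a), len(hits_b)))
        summary_rows.append({
            "region": region, "n_universe": len(universe),
            "n_hits_a": len(hits_a), "n_hits_b": len(hits_b),
            "n_shared": len(shared),
            "expected_shared": len(hits_a) * len(hits_b) / len(universe),
            "fisher_p_one_sided": p,
        })
    if not universe_any:
        raise ValueError("no shared tested universe between the two cohorts")
    return (
        pd.DataFrame(shared_rows, columns=["region", "feature_id"]),
        pd.DataFrame(summary_rows),
    )
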