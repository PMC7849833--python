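"""Synthetic multi-cancer cohorts with planted cis effects and a truth ledger.

The generator emulates the statistical structure the screens assume: a
multi-cancer-type cohort with lognormal per-sample mutation burden, uniform
background SNVs over a compact synthetic genome, planted SNV->expression
effects (a mean shift on the log2 scale in carriers), planted
SNV->methylation effects (a shift on the logit scale), copy-number- and
SV-driven confounder genes whose SNV association should be explained away
by the covariates, and null genes for calibration.  Every planted feature
is recorded in a truth table so recovery, realized FDR and confounder
leakage are measurable.  All randomness flows from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from . import io_formats, sv_distance
from .io_formats import GeneModel, SNVRecord, SVBreakend
from .regions import RegionKind, build_region_window

BASES = np.array(list("ACGT"))

# relative exon geometry of every synthetic gene (0-based, within the gene)
_EXONS_REL = [(0, 600), (2200, 2800), (4400, 5000)]
_CDS_REL = (300, 4700)
_GENE_LEN = 5000

POSITION_CLASS_CHOICES = ["TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 300
    n_genes: int = 2000
    n_cancer_types: int = 3
    gene_spacing: int = 30_000       # bases between successive gene starts
    genome_margin: int = 25_000      # padding before the first gene
    snv_rate: float = 2e-5           # background SNVs per base per sample
    burden_sigma: float = 0.5        # lognormal sd of per-sample burden factor
    n_effect_genes_expr: int = 20
    n_effect_genes_meth: int = 10
    n_cna_confounded: int = 10
    n_sv_confounded: int = 10
    effect_size_expr: float = 2.0    # log2 units added in carriers
    effect_size_meth: float = 1.5    # logit units added in carriers
    carrier_fraction: float = 0.05
    effect_region: RegionKind = RegionKind.UP1KB
    expr_noise_sd: float = 1.0       # log2-scale residual sd
    meth_noise_sd: float = 0.5       # logit-scale residual sd
    type_effect_sd: float = 0.5      # per-(gene, cancer type) baseline shifts
    copy_effect: float = 1.0         # log2 expression per copy above 2
    sv_effect: float = 0.5           # log2 expression per unit of 6 - log10(d+1)
    amplified_fraction: float = 0.25
    n_probes: int = 1000
    n_decoy_probes: int = 20         # chrX / CGI-less probes, removed by the filter
    sv_background_mean: float = 30.0  # breakends per sample
    n_tf_site_genes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_cancer_types) <= 0:
            raise ValueError("counts must be positive")
        n_special = (self.n_effect_genes_expr + self.n_effect_genes_meth
                     + self.n_cna_confounded + self.n_sv_confounded)
        if n_special > self.n_genes:
            raise ValueError("more planted/confounded genes than genes")
        if not 0.0 < self.carrier_fraction < 1.0:
            raise ValueError("carrier_fraction must lie in (0, 1)")
        if self.n_probes > self.n_genes:
            raise ValueError("n_probes must not exceed n_genes (one probe per gene)")
        if n_special and int(round(self.carrier_fraction * self.n_samples)) < 3:
            raise ValueError(
                "carrier_fraction * n_samples < 3: planted genes would be untestable"
            )
        if self.n_effect_genes_meth > self.n_probes:
            raise ValueError("more methylation effect genes than probes")

    @property
    def n_carriers(self) -> int:
        n = int(round(self.carrier_fraction * self.n_samples))
        if n < 3:
            raise ValueError(
                "carrier_fraction * n_samples < 3: planted genes would be untestable"
            )
        return n

    @property
    def genome_length(self) -> int:
        return 2 * self.genome_margin + self.n_genes * self.gene_spacing


@dataclass
class SimBundle:
    """Everything the pipeline consumes, plus the truth ledger."""

    config: SimConfig
    samples: list[str]
    snvs: list[SNVRecord]
    genes: list[GeneModel]
    expression: pd.DataFrame       # raw scale, genes x samples
    betas: pd.DataFrame            # probes x samples in [0, 1]
    manifest: pd.DataFrame
    breakends: list[SVBreakend]
    copy_number: pd.DataFrame
    covariates: pd.DataFrame
    tf_sites: pd.DataFrame
    truth: pd.DataFrame


def _make_gene_models(config: SimConfig, strands: np.ndarray) -> list[GeneModel]:
    genes = []
    for i in range(config.n_genes):
        start = config.genome_margin + i * config.gene_spacing
        exons = [(start + s, start + e) for s, e in _EXONS_REL]
        genes.append(
            GeneModel(
                gene_id=f"G{i:04d}", symbol=f"SYM{i:04d}", chrom="chr1",
                strand="+" if strands[i] else "-",
                tx_start=start, tx_end=start + _GENE_LEN, exons=exons,
                cds_start=start + _CDS_REL[0], cds_end=start + _CDS_REL[1],
            )
        )
    return genes


def simulate_cohort(config: SimConfig) -> SimBundle:
    """Generate one full cohort bundle, deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_genes
    samples = [f"S{i:03d}" for i in range(n)]

    strands = rng.random(m) < 0.5
    genes = _make_gene_models(config, strands)
    gene_ids = [g.gene_id for g in genes]

    # --- assign gene roles -------------------------------------------------
    special = rng.choice(
        m,
        size=(config.n_effect_genes_expr + config.n_effect_genes_meth
              + config.n_cna_confounded + config.n_sv_confounded),
        replace=False,
    )
    cut1 = config.n_effect_genes_expr
    cut2 = cut1 + config.n_effect_genes_meth
    cut3 = cut2 + config.n_cna_confounded
    expr_idx = np.sort(special[:cut1])
    meth_idx = np.sort(special[cut1:cut2])
    cna_idx = np.sort(special[cut2:cut3])
    sv_idx = np.sort(special[cut3:])
    # methylation-effect genes must carry a probe (probes map to the first
    # n_probes genes), so draw them from that range up front
    if config.n_effect_genes_meth and (meth_idx >= config.n_probes).any():
        pool = np.setdiff1d(np.arange(config.n_probes),
                            np.concatenate([expr_idx, cna_idx, sv_idx]))
        meth_idx = np.sort(rng.choice(pool, config.n_effect_genes_meth, replace=False))

    # --- background SNVs ---------------------------------------------------
    burden_factor = np.exp(
        rng.normal(0.0, config.burden_sigma, n) - config.burden_sigma**2 / 2
    )
    lam = config.snv_rate * config.genome_length * burden_factor
    counts = rng.poisson(np.maximum(lam, 1.0))
    counts = np.maximum(counts, 1)  # log2 burden needs >=1 SNV per sample
    snv_rows: list[tuple[str, int]] = []
    for si in range(n):
        for pos in rng.integers(0, config.genome_length, counts[si]):
            snv_rows.append((samples[si], int(pos)))

    # --- planted carriers and their SNVs ----------------------------------
    nc = config.n_carriers
    carrier_sets: dict[int, np.ndarray] = {}
    copy_mat = np.full((m, n), 2.0)
    amp_sets: dict[int, np.ndarray] = {}
    for gi in cna_idx:
        amp = rng.choice(n, max(nc, int(round(config.amplified_fraction * n))),
                         replace=False)
        amp_sets[gi] = amp
        copy_mat[gi, amp] = rng.choice([3.0, 4.0, 5.0], amp.size)
        carrier_sets[gi] = rng.choice(amp, nc, replace=False)
    for gi in np.concatenate([expr_idx, meth_idx, sv_idx]).astype(int):
        carrier_sets[gi] = rng.choice(n, nc, replace=False)

    # --- SV breakends ------------------------------------------------------
    breakends: list[SVBreakend] = []
    sv_counts = rng.poisson(config.sv_background_mean, n)
    for si in range(n):
        for pos in rng.integers(0, config.genome_length, sv_counts[si]):
            breakends.append(SVBreakend(samples[si], "chr1", int(pos)))
    for gi in sv_idx:
        start = sv_distance.gene_start(genes[gi])
        for si in carrier_sets[gi]:
            offset = int(rng.integers(50, 5000))
            breakends.append(SVBreakend(samples[si], "chr1", max(0, start - offset)))

    # planted SNVs go into the designated region window of each special gene
    for gi, carriers in carrier_sets.items():
        window = build_region_window(genes[gi], config.effect_region)
        if window.empty:
            raise ValueError(
                f"planted region {config.effect_region} empty for {gene_ids[gi]}"
            )
        chrom, ws, we = window.intervals[0]
        for si in carriers:
            snv_rows.append((samples[si], int(rng.integers(ws, we))))

    snvs = _to_snv_records(snv_rows, rng)

    # --- covariates --------------------------------------------------------
    total_counts = pd.Series(0, index=samples, dtype=int)
    vc = pd.Series([s for s, _ in snv_rows]).value_counts()
    total_counts.loc[vc.index] = vc
    cancer_type = pd.Series(
        [f"type{rng.integers(config.n_cancer_types)}" for _ in samples], index=samples
    )
    gender = pd.Series(np.where(rng.random(n) < 0.5, "F", "M"), index=samples)
    covariates = pd.DataFrame(
        {
            "cancer_type": cancer_type,
            "gender": gender,
            "log2_burden": np.log2(total_counts.astype(float)),
        }
    )
    covariates.index.name = "sample_id"

    # --- expression --------------------------------------------------------
    baseline = rng.normal(8.0, 2.0, m)
    type_codes = cancer_type.str.removeprefix("type").astype(int).to_numpy()
    type_shift = rng.normal(0.0, config.type_effect_sd, (m, config.n_cancer_types))
    z = (
        baseline[:, None]
        + type_shift[:, type_codes]
        + rng.normal(0.0, config.expr_noise_sd, (m, n))
    )
    for gi in expr_idx:
        z[gi, carrier_sets[gi]] += config.effect_size_expr
    z += config.copy_effect * (copy_mat - 2.0)
    if len(sv_idx):
        dist = sv_distance.breakpoint_distance_matrix(
            breakends, [genes[gi] for gi in sv_idx], samples
        )
        svcov = sv_distance.sv_covariate(dist).to_numpy()
        for k, gi in enumerate(sv_idx):
            z[gi] += config.sv_effect * (np.log10(sv_distance.MAX_DISTANCE + 1.0)
                                         - svcov[k])
    expression = pd.DataFrame(
        np.maximum(np.exp2(z) - 1.0, 0.0),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=pd.Index(samples, name="sample_id"),
    )

    # --- methylation -------------------------------------------------------
    probe_ids = [f"cg{i:07d}" for i in range(config.n_probes)]
    probe_gene_idx = np.arange(config.n_probes)
    logit_base = rng.normal(-1.0, 1.0, config.n_probes)
    logit_vals = logit_base[:, None] + rng.normal(
        0.0, config.meth_noise_sd, (config.n_probes, n)
    )
    meth_set = set(int(x) for x in meth_idx)
    for pi, gi in enumerate(probe_gene_idx):
        if gi in meth_set:
            logit_vals[pi, carrier_sets[gi]] += config.effect_size_meth
    betas = pd.DataFrame(
        1.0 / (1.0 + np.exp(-logit_vals)),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=pd.Index(samples, name="sample_id"),
    )
    manifest = _make_manifest(config, genes, probe_ids, probe_gene_idx, rng)

    copy_number = pd.DataFrame(
        copy_mat, index=pd.Index(gene_ids, name="gene_id"),
        columns=pd.Index(samples, name="sample_id"),
    )

    tf_sites = _make_tf_sites(config, genes, rng)

    # --- truth ledger ------------------------------------------------------
    label = pd.Series("null", index=gene_ids)
    label.iloc[expr_idx] = "expr_effect"
    label.iloc[cna_idx] = "cna_confounded"
    label.iloc[sv_idx] = "sv_confounded"
    gene_truth = pd.DataFrame(
        {
            "feature_id": gene_ids,
            "feature_type": "gene",
            "label": label.to_numpy(),
            "region": config.effect_region.value,
            "effect_size": [
                config.effect_size_expr if lab == "expr_effect" else 0.0
                for lab in label
            ],
        }
    )
    probe_truth = pd.DataFrame(
        {
            "feature_id": probe_ids,
            "feature_type": "probe",
            "label": [
                "meth_effect" if gi in meth_set else "null" for gi in probe_gene_idx
            ],
            "region": config.effect_region.value,
            "effect_size": [
                config.effect_size_meth if gi in meth_set else 0.0
                for gi in probe_gene_idx
            ],
        }
    )
    truth = pd.concat([gene_truth, probe_truth], ignore_index=True)

    return SimBundle(
        config=config, samples=samples, snvs=snvs, genes=genes,
        expression=expression, betas=betas, manifest=manifest,
        breakends=breakends, copy_number=copy_number, covariates=covariates,
        tf_sites=tf_sites, truth=truth,
    )


def _to_snv_records(rows: list[tuple[str, int]], rng: np.random.Generator) -> list[SNVRecord]:
    refs = rng.integers(0, 4, len(rows))
    alts = (refs + rng.integers(1, 4, len(rows))) % 4
    return [
        SNVRecord(sample, "chr1", pos, BASES[r], BASES[a])
        for (sample, pos), r, a in zip(rows, refs, alts)
    ]


def _make_manifest(config, genes, probe_ids, probe_gene_idx, rng) -> pd.DataFrame:
    rows = []
    for pid, gi in zip(probe_ids, probe_gene_idx):
        g = genes[gi]
        tss = g.tx_start if g.strand == "+" else g.tx_end - 1
        cls = POSITION_CLASS_CHOICES[
            int(rng.choice(len(POSITION_CLASS_CHOICES),
                           p=[0.3, 0.2, 0.1, 0.1, 0.2, 0.1]))
        ]
        promoter = cls in ("TSS200", "TSS1500") or rng.random() < 0.2
        rows.append(
            (pid, g.chrom, int(tss + rng.integers(-200, 201)), f"CGI_{g.gene_id}",
             g.gene_id, cls, int(promoter))
        )
    # decoys removed by the CGI/autosome filter
    for i in range(config.n_decoy_probes):
        on_x = i % 2 == 0
        rows.append(
            (f"cgDECOY{i:03d}", "chrX" if on_x else "chr1",
             int(rng.integers(0, config.genome_length)),
             f"CGI_X{i}" if on_x else "", "", "Body", 0)
        )
    df = pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "cgi_id", "gene",
                       "position_class", "promoter_associated"],
    )
    df["promoter_associated"] = df["promoter_associated"].astype(bool)
    return df.set_index("probe_id", drop=False)


def _make_tf_sites(config, genes, rng) -> pd.DataFrame:
    from .annotate import REPRESSOR_TFS

    repressors = sorted(REPRESSOR_TFS)
    others = ["MAX", "JUN", "FOS", "MYC", "SP1"]
    rows = []
    chosen = rng.choice(len(genes), min(config.n_tf_site_genes, len(genes)),
                        replace=False)
    for gi in np.sort(chosen):
        g = genes[gi]
        tss = g.tx_start if g.strand == "+" else g.tx_end - 1
        for _ in range(int(rng.integers(1, 4))):
            width = int(rng.integers(50, 400))
            if g.strand == "+":
                start = int(rng.integers(max(0, tss - 2000), max(1, tss - width + 1)))
            else:
                start = int(rng.integers(tss + 1, tss + 2000))
            name = repressors[int(rng.integers(len(repressors)))] \
                if rng.random() < 0.8 else others[int(rng.integers(len(others)))]
            rows.append((g.chrom, start, start + width, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tf_name"])


# ---------------------------------------------------------------------------
# recovery evaluation


_NESTED_COMPAT = {
    RegionKind.UP1KB.value: {RegionKind.UP1KB.value, RegionKind.UP2KB.value,
                             RegionKind.UP20KB.value},
    RegionKind.UP2KB.value: {RegionKind.UP2KB.value, RegionKind.UP20KB.value},
}


def evaluate_recovery(
    results: pd.DataFrame,
    truth: pd.DataFrame,
    q_threshold: float = 0.10,
    *,
    require_cna_pass: bool = True,
    feature_type: str | None = None,
) -> dict:
    """Score a screen's result table against the truth ledger.

    A *call* is a (feature, region) row with q below the threshold (and
    passing the copy-number filter unless ``require_cna_pass`` is False).
    A call is true when the feature carries a planted effect and the called
    region contains the planted window (a 1 kb-upstream effect is genuinely
    present in the 2 kb and 20 kb windows too, so those calls count as
    true).  Sensitivity counts planted features recovered in their exact
    planted region.  Realized FDR is false calls over all calls (absent when
    there are no calls).  Leakage is the fraction of copy-number-confounded
    features, called before the copy refit, that still pass it.
    """
    truth = truth.set_index("feature_id") if "feature_id" in truth.columns else truth
    if feature_type is not None:
        truth = truth[truth["feature_type"] == feature_type]
    unknown = set(results["feature_id"]) - set(truth.index)
    if unknown:
        raise ValueError(f"results contain features absent from truth: "
                         f"{sorted(unknown)[:5]}")
    effect_labels = {"expr_effect", "meth_effect"}
    planted = truth[truth["label"].isin(effect_labels)]

    called_mask = results["q_snv"] < q_threshold
    if require_cna_pass:
        called_mask &= results["passes_cna_filter"].astype(bool)
    calls = results[called_mask]

    def is_true_call(row) -> bool:
        t = truth.loc[row.feature_id]
        if t["label"] not in effect_labels:
            return False
        compat = _NESTED_COMPAT.get(t["region"], {t["region"]})
        return row.region in compat

    n_true = sum(is_true_call(r) for r in calls.itertuples(index=False))
    n_calls = len(calls)

    recovered = 0
    for fid, t in planted.iterrows():
        hit = calls[(calls["feature_id"] == fid) & (calls["region"] == t["region"])]
        if len(hit):
            recovered += 1
    sensitivity = recovered / len(planted) if len(planted) else np.nan
    fdr = (n_calls - n_true) / n_calls if n_calls else np.nan

    cna_feats = set(truth.index[truth["label"] == "cna_confounded"])
    pre = results[(results["q_snv"] < q_threshold)
                  & results["feature_id"].isin(cna_feats)]
    pre_called = pre["feature_id"].nunique()
    leaked = pre[pre["passes_cna_filter"].astype(bool)]["feature_id"].nunique()
    leakage = leaked / pre_called if pre_called else np.nan

    return {
        "n_planted": int(len(planted)),
        "n_recovered": int(recovered),
        "sensitivity": float(sensitivity) if len(planted) else np.nan,
        "n_calls": int(n_calls),
        "n_false_calls": int(n_calls - n_true),
        "realized_fdr": float(fdr) if n_calls else np.nan,
        "cna_confounded_called_prefilter": int(pre_called),
        "cna_confounded_leaked": int(leaked),
        "cna_leakage_rate": float(leakage) if pre_called else np.nan,
    }


# ---------------------------------------------------------------------------
# bundle writer (the simulate subcommand's output doubles as an
# end-to-end integration fixture in the pipeline's own input formats)


def write_bundle(bundle: SimBundle, outdir: str | Path, *, vcf: bool = True) -> dict:
    """Write the bundle in the pipeline's external formats; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "snvs": outdir / ("snvs.vcf" if vcf else "snvs.tsv"),
        "genes": outdir / "genes.gtf",
        "expression": outdir / "expression.tsv",
        "betas": outdir / "betas.tsv",
        "manifest": outdir / "probe_manifest.tsv",
        "breakends": outdir / "sv.bedpe",
        "copy_number": outdir / "copy_number.tsv",
        "covariates": outdir / "covariates.tsv",
        "tf_sites": outdir / "tf_sites.bed",
        "truth": outdir / "truth.tsv",
    }
    if vcf:
        io_formats.write_vcf(bundle.snvs, bundle.samples, paths["snvs"])
    else:
        io_formats.write_snv_table(bundle.snvs, paths["snvs"])
    io_formats.write_gtf(bundle.genes, paths["genes"])
    io_formats.write_matrix(bundle.expression, paths["expression"])
    io_formats.write_matrix(bundle.betas, paths["betas"])
    bundle.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    io_formats.write_bedpe(bundle.breakends, paths["breakends"])
    io_formats.write_matrix(bundle.copy_number, paths["copy_number"])
    bundle.covariates.to_csv(paths["covariates"], sep="\t")
    io_formats.write_bed(bundle.tf_sites, paths["tf_sites"])
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def null_config(**overrides) -> SimConfig:
    """A cohort with no planted effects or confounders (calibration runs)."""
    base = dict(
        n_effect_genes_expr=0, n_effect_genes_meth=0,
        n_cna_confounded=0, n_sv_confounded=0,
    )
    base.update(overrides)
    return SimConfig(**base)


def recovery_config(**overrides) -> SimConfig:
    """The parameter-recovery condition: 20 planted genes, no confounders."""
    base = dict(
        n_effect_genes_expr=20, n_effect_genes_meth=0,
        n_cna_confounded=0, n_sv_confounded=0,
    )
    base.update(overrides)
    return SimConfig(**base)
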