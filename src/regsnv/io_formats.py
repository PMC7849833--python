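"""Readers and writers for the external formats the pipeline touches.

Every coordinate exposed by this module is 0-based, half-open.  VCF (1-based)
and GTF (1-based, closed) inputs are converted on read; BED-family inputs are
already in the internal convention.  Genome build is caller-declared metadata:
no liftover is performed, and sample identifiers are taken as-is (the caller
must supply identifiers that are consistent across data types).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SNVRecord:
    """One somatic single-nucleotide variant call in one sample (0-based pos)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    filter_pass: bool = True

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos} for {self.sample_id}")
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"non-ACGT allele {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class SVBreakend:
    """One structural-variant breakend position in one sample (0-based)."""

    sample_id: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative breakend position {self.pos}")


@dataclass
class GeneModel:
    """Gene coordinates for one canonical transcript, 0-based half-open.

    ``exons`` are sorted, disjoint intervals within ``[tx_start, tx_end)``.
    ``cds_start``/``cds_end`` are absent for non-coding genes, in which case
    UTR windows are empty.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene has zero exons")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = self.tx_start - 1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon outside transcript span")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e


def read_snvs(
    path: str | Path,
    format: str = "vcf",
    *,
    default_sample: str | None = None,
) -> list[SNVRecord]:
    """Read somatic SNVs from a VCF or a MAF-like tab table.

    VCF positions (1-based) are converted to 0-based; records that fail
    FILTER are dropped; multi-allelic records are split per ALT allele.
    For a multi-sample VCF, one record is emitted per sample carrying the
    alternate allele.  For a VCF without genotype columns the caller must
    pass ``default_sample``.

    The ``table`` format is tab-separated with header columns
    ``sample_id chrom pos ref alt filter`` where ``pos`` is 0-based and
    ``filter`` is PASS or a failure reason.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_snvs_vcf(path, default_sample)
    if format == "table":
        return _read_snvs_table(path)
    raise ValueError(f"unknown SNV format {format!r}")


def _read_snvs_vcf(path: Path, default_sample: str | None) -> list[SNVRecord]:
    from cyvcf2 import VCF

    out: list[SNVRecord] = []
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for var in vcf:
        if var.FILTER is not None:  # None <=> PASS / '.'
            continue
        if len(var.REF) != 1 or var.REF not in VALID_BASES:
            continue  # not an SNV
        for ai, alt in enumerate(var.ALT):
            if len(alt) != 1 or alt not in VALID_BASES:
                continue
            if samples:
                allele = ai + 1
                genos = var.genotypes
                for si, g in enumerate(genos):
                    if allele in g[:-1]:
                        out.append(
                            SNVRecord(samples[si], var.CHROM, var.POS - 1, var.REF, alt)
                        )
            else:
                if default_sample is None:
                    raise ValueError(
                        f"{path}: VCF has no sample columns; pass default_sample"
                    )
                out.append(
                    SNVRecord(default_sample, var.CHROM, var.POS - 1, var.REF, alt)
                )
    return out


_TABLE_COLS = ["sample_id", "chrom", "pos", "ref", "alt", "filter"]


def _read_snvs_table(path: Path) -> list[SNVRecord]:
    out: list[SNVRecord] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return out
        if header[: len(_TABLE_COLS)] != _TABLE_COLS:
            raise ValueError(f"{path}: expected header columns {_TABLE_COLS}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < len(_TABLE_COLS):
                raise ValueError(f"{path}: malformed line {lineno}")
            sample, chrom, pos, ref, alt, filt = row[:6]
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: bad pos {pos!r}") from exc
            if filt != "PASS":
                continue
            try:
                out.append(SNVRecord(sample, chrom, pos_i, ref, alt))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
    return out


def write_snv_table(snvs: Iterable[SNVRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLS) + "\n")
        for s in snvs:
            fh.write(f"{s.sample_id}\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\tPASS\n")


def read_gene_models(path: str | Path, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF or BED12, one canonical transcript per gene.

    When a gene has several transcripts the longest (by genomic span; ties
    broken by lexicographically smallest transcript id) is retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gtf":
        return _read_gene_models_gtf(path)
    if format == "bed12":
        return _read_gene_models_bed12(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def _read_gene_models_gtf(path: Path) -> list[GeneModel]:
    import pyranges as pr

    df = pr.read_gtf(str(path)).df  # already 0-based half-open
    if "transcript_id" not in df.columns:
        raise ValueError(f"{path}: GTF lacks transcript_id attributes")
    exons = df[df.Feature == "exon"]
    if exons.empty:
        raise ValueError(f"{path}: GTF contains no exon features")
    cds = df[df.Feature == "CDS"]

    # canonical transcript per gene: longest span, ties -> smallest tx id
    tx = (
        exons.groupby(["gene_id", "transcript_id"], sort=True)
        .agg(
            chrom=("Chromosome", "first"),
            strand=("Strand", "first"),
            start=("Start", "min"),
            end=("End", "max"),
        )
        .reset_index()
    )
    tx["span"] = tx.end - tx.start
    tx = tx.sort_values(["gene_id", "span", "transcript_id"],
                        ascending=[True, False, True])
    canonical = tx.drop_duplicates("gene_id", keep="first")

    symbol_col = "gene_name" if "gene_name" in df.columns else "gene_id"
    symbols = (
        df.dropna(subset=[symbol_col]).groupby("gene_id")[symbol_col].first()
        if symbol_col in df.columns
        else None
    )

    cds_bounds = (
        cds.groupby("transcript_id").agg(cs=("Start", "min"), ce=("End", "max"))
        if not cds.empty
        else pd.DataFrame(columns=["cs", "ce"])
    )
    exon_groups = exons.groupby("transcript_id")

    models: list[GeneModel] = []
    for row in canonical.itertuples():
        ex = exon_groups.get_group(row.transcript_id)
        exon_list = sorted(zip(ex.Start.astype(int), ex.End.astype(int)))
        cs = ce = None
        if row.transcript_id in cds_bounds.index:
            cs = int(cds_bounds.loc[row.transcript_id, "cs"])
            ce = int(cds_bounds.loc[row.transcript_id, "ce"])
        sym = row.gene_id
        if symbols is not None and row.gene_id in symbols.index:
            sym = str(symbols.loc[row.gene_id])
        models.append(
            GeneModel(
                gene_id=str(row.gene_id),
                symbol=sym,
                chrom=str(row.chrom),
                strand=str(row.strand),
                tx_start=int(row.start),
                tx_end=int(row.end),
                exons=exon_list,
                cds_start=cs,
                cds_end=ce,
            )
        )
    models.sort(key=lambda g: g.gene_id)
    return models


def _read_gene_models_bed12(path: Path) -> list[GeneModel]:
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {lineno}: BED12 needs 12 columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}: line {lineno}: blockCount mismatch")
            exons = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
            cs = ce = None
            if thick_end > thick_start:
                cs, ce = thick_start, thick_end
            models.append(
                GeneModel(
                    gene_id=name, symbol=name, chrom=chrom, strand=strand,
                    tx_start=start, tx_end=end, exons=exons,
                    cds_start=cs, cds_end=ce,
                )
            )
    return models


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal GTF (internal 0-based -> 1-based closed)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            tx_attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\tregsnv\tgene\t{g.tx_start + 1}\t{g.tx_end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tregsnv\ttranscript\t{g.tx_start + 1}\t{g.tx_end}\t.\t{g.strand}\t.\t{tx_attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tregsnv\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tx_attrs}\n"
                )
            if g.cds_start is not None and g.cds_end is not None:
                for s, e in g.exons:
                    cs, ce = max(s, g.cds_start), min(e, g.cds_end)
                    if cs < ce:
                        fh.write(
                            f"{g.chrom}\tregsnv\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\t{tx_attrs}\n"
                        )


def write_vcf(
    snvs: Iterable[SNVRecord], samples: Sequence[str], path: str | Path
) -> None:
    """Write SNVs as a multi-sample VCF with 0/1 genotypes for carriers."""
    grouped: dict[tuple[str, int, str, str], set[str]] = {}
    chroms: list[str] = []
    for s in snvs:
        key = (s.chrom, s.pos, s.ref, s.alt)
        grouped.setdefault(key, set()).add(s.sample_id)
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    sample_idx = {s: i for i, s in enumerate(samples)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for (chrom, pos, ref, alt), carriers in sorted(grouped.items()):
            gts = ["0/0"] * len(samples)
            for c in carriers:
                gts[sample_idx[c]] = "0/1"
            fh.write(
                f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_breakends(path: str | Path) -> list[SVBreakend]:
    """Read SV breakends from BEDPE; both ends of each record contribute."""
    path = Path(path)
    out: list[SVBreakend] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ValueError(f"{path}: line {lineno}: BEDPE needs >=7 columns")
            chrom1, s1, _e1, chrom2, s2, _e2, name = f[:7]
            out.append(SVBreakend(name, chrom1, int(s1)))
            out.append(SVBreakend(name, chrom2, int(s2)))
    return out


def write_bedpe(breakends: Sequence[SVBreakend], path: str | Path) -> None:
    """Write breakends pairwise as BEDPE (consecutive ends of one sample pair up;
    an unpaired trailing end is written as both ends of its record)."""
    by_sample: dict[str, list[SVBreakend]] = {}
    for b in breakends:
        by_sample.setdefault(b.sample_id, []).append(b)
    with open(path, "w") as fh:
        for sample in sorted(by_sample):
            ends = by_sample[sample]
            for i in range(0, len(ends), 2):
                a = ends[i]
                b = ends[i + 1] if i + 1 < len(ends) else ends[i]
                fh.write(
                    f"{a.chrom}\t{a.pos}\t{a.pos + 1}\t{b.chrom}\t{b.pos}\t{b.pos + 1}\t{sample}\n"
                )


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labelled numeric TSV matrix (rows = genes/probes, cols = samples).

    Duplicate row labels are rejected; "NA"/empty cells become missing values
    (NaN), never zero; ragged rows raise.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row labels {dups[:5]}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric columns {non_numeric[:5]}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "id", na_rep="NA")


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the per-sample covariate TSV (cancer_type, gender, log2_burden)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    required = {"cancer_type", "gender", "log2_burden"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing covariate columns {sorted(missing)}")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def make_covariates(
    snvs: Iterable[SNVRecord],
    samples: Sequence[str],
    cancer_type: pd.Series | dict,
    gender: pd.Series | dict,
) -> pd.DataFrame:
    """Assemble the covariate table; log2_burden = log2 of total passing SNVs."""
    counts = pd.Series(0, index=pd.Index(samples, name="sample_id"), dtype=int)
    for s in snvs:
        if s.sample_id in counts.index:
            counts[s.sample_id] += 1
    if (counts < 1).any():
        zero = counts.index[counts < 1].tolist()
        raise ValueError(f"samples with zero SNVs cannot have log2 burden: {zero[:5]}")
    ct = pd.Series(cancer_type).reindex(counts.index)
    gd = pd.Series(gender).reindex(counts.index)
    return pd.DataFrame(
        {
            "cancer_type": ct.astype(str),
            "gender": gd.astype(str),
            "log2_burden": np.log2(counts.astype(float)),
        }
    )


def read_probe_manifest(path: str | Path) -> pd.DataFrame:
    """Read the methylation probe manifest TSV.

    Columns: probe_id, chrom, pos (0-based), cgi_id, gene, position_class,
    promoter_associated (0/1).
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"probe_id": str, "chrom": str, "cgi_id": str, "gene": str},
        keep_default_na=False, na_values=[],
    )
    required = ["probe_id", "chrom", "pos", "cgi_id", "gene",
                "position_class", "promoter_associated"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing manifest columns {missing}")
    df["pos"] = df["pos"].astype(int)
    df["promoter_associated"] = df["promoter_associated"].astype(int).astype(bool)
    return df.set_index("probe_id", drop=False)


def read_tf_sites(path: str | Path) -> pd.DataFrame:
    """Read TF binding sites from 4+-column BED (name column = TF)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}: line {lineno}: TF BED needs >=4 columns")
            rows.append((f[0], int(f[1]), int(f[2]), f[3]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tf_name"])


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
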