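"""Downstream annotation of significant genes.

Covers the elevated-expression flag (>0.4 SD above the cohort median),
overlap of upstream SNVs with repressor transcription-factor binding sites,
per-patient SNV density, hot-mutation-region detection (>=5 patients,
>=10 SNVs, inter-SNV gaps <=30 bp), and the intron/exon-boundary check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneModel

#: The repressor/chromatin-factor set whose binding-site disruption is scored.
REPRESSOR_TFS = frozenset({
    "BAF170", "BRG1", "CEBPB", "CTCF", "E2F1", "E2F6", "ELK4", "EZH2",
    "GABPA", "IRF3", "JUND", "NRSF", "PRDM1", "REST", "RFX5", "SMARCA4",
    "SREBF2", "STAT3", "TCF7L2", "ZHX1",
})

DEFAULT_Z_CUT = 0.4


def flag_elevated(
    expression_row: pd.Series, sample_id: str, z_cut: float = DEFAULT_Z_CUT
) -> bool:
    """True iff the sample's value exceeds the row median by > z_cut SDs.

    The centre is the cohort median, the scale the n-1 sample SD; a
    zero-variance row flags nobody.
    """
    if sample_id not in expression_row.index:
        raise KeyError(f"sample {sample_id!r} not in expression row")
    vals = expression_row.to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 3:
        raise ValueError("need at least 3 observed values")
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        return False
    z = (float(expression_row[sample_id]) - float(np.median(vals))) / sd
    return bool(z > z_cut)


def elevated_samples(
    expression_row: pd.Series, z_cut: float = DEFAULT_Z_CUT
) -> list[str]:
    """All samples flagged elevated for this gene, in column order."""
    vals = expression_row.to_numpy(dtype=float)
    obs = vals[np.isfinite(vals)]
    if obs.size < 3:
        return []
    sd = float(np.std(obs, ddof=1))
    if sd == 0:
        return []
    med = float(np.median(obs))
    z = (vals - med) / sd
    return [s for s, zi, v in zip(expression_row.index, z, vals)
            if np.isfinite(v) and zi > z_cut]


def tf_overlap(
    snv_events: pd.DataFrame,
    sites: pd.DataFrame,
    repressors: frozenset[str] = REPRESSOR_TFS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate SNV events with overlapping repressor TF binding sites.

    ``snv_events`` has columns gene_id, sample_id, chrom, pos (one row per
    event, typically SNVs in the 1-2 kb upstream windows of significant
    genes restricted to samples with elevated expression).  ``sites`` is the
    TF BED table (chrom, start, end, tf_name).  Returns (associations,
    per_tf, summary): one association row per (event, TF) overlap — an SNV
    inside two sites yields two rows — per-TF event counts, and the overall
    fraction of events hitting any repressor site.
    """
    site_sub = sites[sites["tf_name"].isin(repressors)]
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in site_sub.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), tf) for s, e, tf in zip(grp.start, grp.end, grp.tf_name)
            if s < e
        )
    assoc_rows = []
    n_in_sites = 0
    for row in snv_events.itertuples(index=False):
        tree = trees.get(row.chrom)
        hits = sorted(iv.data for iv in tree[row.pos]) if tree is not None else []
        if hits:
            n_in_sites += 1
        for tf in hits:
            assoc_rows.append(
                (row.gene_id, row.sample_id, row.chrom, row.pos, tf)
            )
    assoc = pd.DataFrame(
        assoc_rows, columns=["gene_id", "sample_id", "chrom", "pos", "tf_name"]
    )
    per_tf = (
        assoc.groupby("tf_name").size().rename("n_events").reset_index()
        if not assoc.empty
        else pd.DataFrame(columns=["tf_name", "n_events"])
    )
    n_events = len(snv_events)
    summary = pd.DataFrame(
        [{
            "n_events": n_events,
            "n_in_sites": n_in_sites,
            "fraction_in_sites": (n_in_sites / n_events) if n_events else 0.0,
        }]
    )
    return assoc, per_tf, summary


def snv_density(
    significant_genes: Sequence[str],
    region_events: pd.DataFrame,
    elevated: Mapping[str, Sequence[str]],
    cancer_type: pd.Series,
) -> pd.DataFrame:
    """Average SNVs per patient among elevated carriers, per significant gene.

    ``region_events`` holds one row per (gene, SNV) event with columns
    gene_id, sample_id, pos; ``elevated`` maps gene -> samples flagged with
    elevated expression.  For each gene the events are restricted to
    elevated samples; density is total events / number of such patients,
    and the dominant cancer type is the plurality type among them (ties
    broken lexicographically).  Genes with zero elevated carriers are
    omitted.
    """
    rows = []
    grouped = region_events.groupby("gene_id")
    for gene in significant_genes:
        if gene not in grouped.groups:
            continue
        ev = grouped.get_group(gene)
        elev = set(elevated.get(gene, ()))
        ev = ev[ev["sample_id"].isin(elev)]
        patients = ev["sample_id"].unique()
        if len(patients) == 0:
            continue
        density = len(ev) / len(patients)
        types = cancer_type.reindex(patients).dropna()
        if len(types):
            counts = types.value_counts()
            top = counts[counts == counts.max()].index.min()
        else:
            top = ""
        rows.append({
            "gene_id": gene,
            "n_patients_elevated": int(len(patients)),
            "snvs_per_patient": float(density),
            "dominant_cancer_type": top,
        })
    return pd.DataFrame(
        rows, columns=["gene_id", "n_patients_elevated", "snvs_per_patient",
                       "dominant_cancer_type"],
    )


@dataclass(frozen=True)
class HotRegion:
    """A positional cluster of SNVs dense enough to suggest TF-site disruption."""

    chrom: str
    start: int  # 0-based, inclusive of the first member SNV
    end: int    # half-open; last member SNV is at end - 1
    snv_count: int
    patient_count: int
    member_index: tuple[int, ...]  # row positions into the input event table


def find_hot_regions(
    snv_events: pd.DataFrame,
    min_patients: int = 5,
    min_snvs: int = 10,
    max_gap: int = 30,
) -> list[HotRegion]:
    """Greedy single-linkage chaining of SNV events along the genome.

    Events (columns sample_id, chrom, pos) are sorted by position within
    each chromosome; maximal chains whose successive positions are at most
    ``max_gap`` apart are emitted when they contain at least ``min_snvs``
    events from at least ``min_patients`` distinct patients.  Output is
    independent of input row order.
    """
    out: list[HotRegion] = []
    if snv_events.empty:
        return out
    df = snv_events.reset_index(drop=True)
    for chrom in sorted(df["chrom"].unique()):
        sub = df[df["chrom"] == chrom]
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        pos = sub["pos"].to_numpy()[order]
        samples = sub["sample_id"].to_numpy()[order]
        idx = sub.index.to_numpy()[order]
        chain_start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > max_gap:
                members = slice(chain_start, i)
                n_snvs = i - chain_start
                n_pat = len(set(samples[members]))
                if n_snvs >= min_snvs and n_pat >= min_patients:
                    out.append(
                        HotRegion(
                            chrom=chrom,
                            start=int(pos[chain_start]),
                            end=int(pos[i - 1]) + 1,
                            snv_count=n_snvs,
                            patient_count=n_pat,
                            member_index=tuple(sorted(int(j) for j in idx[members])),
                        )
                    )
                chain_start = i
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


def exon_boundary_flag(
    snv_pos: int, gene: GeneModel, boundary_window: int = 10
) -> bool:
    """True iff an intronic SNV lies within ``boundary_window`` bases of an
    exon-intron junction.

    Distance counts bases from the junction: the first intronic base next to
    an exon has distance 1.  Raises if the position is not intronic.
    """
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        if e1 <= snv_pos < s2:
            dist = min(snv_pos - e1 + 1, s2 - snv_pos)
            return bool(dist <= boundary_window)
    raise ValueError(
        f"position {snv_pos} is not intronic in gene {gene.gene_id}"
    )
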