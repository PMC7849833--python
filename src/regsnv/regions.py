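"""Genomic region windows relative to genes, and the SNV presence matrix.

Seven windows are defined per gene: 20 kb / 2 kb / 1 kb upstream of the TSS
(nested), the union of introns, 1 kb downstream, and the 3' / 5' UTRs.
"Upstream" is 5' of the transcription start on the coding strand; all
intervals are 0-based half-open, so an SNV exactly at the TSS base belongs
to the gene body, not upstream.  The presence matrix marks, per gene and
sample, whether the sample carries at least one passing SNV in the window —
presence, never a count.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, SNVRecord

DEFAULT_WINDOW_SIZES = {"up20kb": 20000, "up2kb": 2000, "up1kb": 1000, "down1kb": 1000}


class RegionKind(str, Enum):
    UP20KB = "up20kb"
    UP2KB = "up2kb"
    UP1KB = "up1kb"
    INTRON = "intron"
    DOWN1KB = "down1kb"
    UTR3 = "utr3"
    UTR5 = "utr5"


ALL_REGIONS = list(RegionKind)
UPSTREAM_NESTING = [RegionKind.UP1KB, RegionKind.UP2KB, RegionKind.UP20KB]


@dataclass
class RegionWindow:
    gene_id: str
    kind: RegionKind
    intervals: list[tuple[str, int, int]]  # (chrom, start, end), disjoint, sorted

    @property
    def empty(self) -> bool:
        return not self.intervals


def build_region_window(
    gene: GeneModel,
    kind: RegionKind,
    window_sizes: Mapping[str, int] | None = None,
) -> RegionWindow:
    """Construct one region window for a gene; intervals clipped at base 0.

    A UTR window for a gene without CDS, or the intron window of a
    single-exon gene, is empty (flagged via ``RegionWindow.empty``), not an
    error.
    """
    sizes = dict(DEFAULT_WINDOW_SIZES)
    if window_sizes:
        sizes.update(window_sizes)
    c = gene.chrom
    plus = gene.strand == "+"
    ivals: list[tuple[str, int, int]] = []

    if kind in (RegionKind.UP20KB, RegionKind.UP2KB, RegionKind.UP1KB):
        w = sizes[kind.value]
        if plus:
            ivals = [(c, max(0, gene.tx_start - w), gene.tx_start)]
        else:
            ivals = [(c, gene.tx_end, gene.tx_end + w)]
    elif kind is RegionKind.DOWN1KB:
        w = sizes["down1kb"]
        if plus:
            ivals = [(c, gene.tx_end, gene.tx_end + w)]
        else:
            ivals = [(c, max(0, gene.tx_start - w), gene.tx_start)]
    elif kind is RegionKind.INTRON:
        for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
            if e1 < s2:
                ivals.append((c, e1, s2))
    elif kind in (RegionKind.UTR3, RegionKind.UTR5):
        if gene.cds_start is None or gene.cds_end is None:
            ivals = []
        else:
            left = []  # exonic bases 5' of CDS in genomic order
            right = []  # exonic bases 3' of CDS in genomic order
            for s, e in gene.exons:
                if s < gene.cds_start:
                    left.append((c, s, min(e, gene.cds_start)))
                if e > gene.cds_end:
                    right.append((c, max(s, gene.cds_end), e))
            if kind is RegionKind.UTR5:
                ivals = left if plus else right
            else:
                ivals = right if plus else left
    else:  # pragma: no cover
        raise ValueError(f"unknown region kind {kind}")

    ivals = [(ch, s, e) for ch, s, e in ivals if s < e]
    return RegionWindow(gene.gene_id, kind, sorted(ivals))


@dataclass
class PresenceMatrix:
    """Binary gene x sample SNV-presence indicator for one region kind."""

    kind: RegionKind
    values: pd.DataFrame  # genes x samples, int8 in {0, 1}

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


class _SNVIndex:
    """Per-chromosome position-sorted SNV arrays for fast window queries."""

    def __init__(self, snvs: Sequence[SNVRecord], sample_to_idx: Mapping[str, int]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.n_skipped_samples = 0
        chrom_pos: dict[str, list[int]] = {}
        chrom_smp: dict[str, list[int]] = {}
        for s in snvs:
            si = sample_to_idx.get(s.sample_id)
            if si is None:
                self.n_skipped_samples += 1
                continue
            chrom_pos.setdefault(s.chrom, []).append(s.pos)
            chrom_smp.setdefault(s.chrom, []).append(si)
        for chrom, positions in chrom_pos.items():
            pos = np.asarray(positions, dtype=np.int64)
            smp = np.asarray(chrom_smp[chrom], dtype=np.int64)
            order = np.argsort(pos, kind="stable")
            self.by_chrom[chrom] = (pos[order], smp[order])

    def samples_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return np.empty(0, dtype=np.int64)
        pos, smp = entry
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return smp[lo:hi]


def build_presence_matrix(
    snvs: Sequence[SNVRecord],
    genes: Sequence[GeneModel],
    kind: RegionKind,
    samples: Sequence[str],
    window_sizes: Mapping[str, int] | None = None,
    *,
    index: "_SNVIndex | None" = None,
) -> PresenceMatrix:
    """Gene x sample 0/1 matrix: 1 iff the sample has >=1 SNV in the window.

    Samples with no SNVs anywhere get an all-zero row, not missing values.
    SNVs on chromosomes absent from the annotation simply never overlap any
    window.  ``index`` lets callers reuse one sorted SNV index across region
    kinds.
    """
    sample_to_idx = {s: i for i, s in enumerate(samples)}
    if len(sample_to_idx) != len(samples):
        raise ValueError("duplicate sample labels")
    if index is None:
        index = _SNVIndex(snvs, sample_to_idx)
    mat = np.zeros((len(genes), len(samples)), dtype=np.int8)
    for gi, gene in enumerate(genes):
        window = build_region_window(gene, kind, window_sizes)
        for chrom, start, end in window.intervals:
            hit = index.samples_in(chrom, start, end)
            if hit.size:
                mat[gi, hit] = 1
    values = pd.DataFrame(
        mat, index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=pd.Index(list(samples), name="sample_id"),
    )
    return PresenceMatrix(kind, values)


def build_all_presence_matrices(
    snvs: Sequence[SNVRecord],
    genes: Sequence[GeneModel],
    samples: Sequence[str],
    window_sizes: Mapping[str, int] | None = None,
    kinds: Iterable[RegionKind] = ALL_REGIONS,
) -> dict[RegionKind, PresenceMatrix]:
    """All requested presence matrices from one shared sorted SNV index."""
    sample_to_idx = {s: i for i, s in enumerate(samples)}
    index = _SNVIndex(snvs, sample_to_idx)
    return {
        kind: build_presence_matrix(
            snvs, genes, kind, samples, window_sizes, index=index
        )
        for kind in kinds
    }


def carriers(matrix: PresenceMatrix, gene_id: str) -> list[str]:
    """Samples carrying >=1 SNV in the gene's window, in column order."""
    if gene_id not in matrix.values.index:
        raise KeyError(f"gene {gene_id!r} not in presence matrix")
    row = matrix.values.loc[gene_id]
    return list(row.index[row.to_numpy() == 1])


def region_snv_events(
    snvs: Sequence[SNVRecord],
    genes: Sequence[GeneModel],
    kind: RegionKind,
    window_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-event table of SNVs inside the given region window of each gene.

    One row per (gene, SNV) event — a single SNV can hit the windows of
    several genes.  Columns: gene_id, sample_id, chrom, pos.
    """
    rows = []
    by_chrom: dict[str, list[SNVRecord]] = {}
    for s in snvs:
        by_chrom.setdefault(s.chrom, []).append(s)
    pos_index: dict[str, tuple[np.ndarray, list[SNVRecord]]] = {}
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda r: r.pos)
        pos_index[chrom] = (np.asarray([r.pos for r in recs]), recs)
    for gene in genes:
        window = build_region_window(gene, kind, window_sizes)
        for chrom, start, end in window.intervals:
            if chrom not in pos_index:
                continue
            pos, recs = pos_index[chrom]
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            for r in recs[lo:hi]:
                rows.append((gene.gene_id, r.sample_id, r.chrom, r.pos))
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "chrom", "pos"])
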