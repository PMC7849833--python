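"""Gene-level SV breakpoint distance covariate.

For every gene and sample, the distance from the gene start (strand-aware:
tx_start on +, last transcribed base on -) to the sample's nearest SV
breakend on the same chromosome, capped at 1 Mb; 1 Mb is imputed when the
sample has no breakend in range.  The screen enters log10(distance + 1),
since raw distances span six orders of magnitude.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, SVBreakend

MAX_DISTANCE = 1_000_000


def gene_start(gene: GeneModel) -> int:
    """Strand-aware transcription start base (0-based)."""
    return gene.tx_start if gene.strand == "+" else gene.tx_end - 1


def breakpoint_distance_matrix(
    breakends: Sequence[SVBreakend],
    genes: Sequence[GeneModel],
    samples: Sequence[str],
) -> pd.DataFrame:
    """Genes x samples matrix of nearest-breakend distances, capped at 1 Mb."""
    sample_to_idx = {s: i for i, s in enumerate(samples)}
    # (sample, chrom) -> sorted breakend positions
    by_key: dict[tuple[int, str], list[int]] = {}
    for b in breakends:
        si = sample_to_idx.get(b.sample_id)
        if si is None:
            continue
        by_key.setdefault((si, b.chrom), []).append(b.pos)
    sorted_keys = {k: np.sort(np.asarray(v, dtype=np.int64)) for k, v in by_key.items()}

    starts_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {g.chrom for g in genes}:
        gi = np.array([i for i, g in enumerate(genes) if g.chrom == chrom])
        st = np.array([gene_start(genes[i]) for i in gi], dtype=np.int64)
        starts_by_chrom[chrom] = (gi, st)

    mat = np.full((len(genes), len(samples)), float(MAX_DISTANCE))
    for (si, chrom), pos in sorted_keys.items():
        entry = starts_by_chrom.get(chrom)
        if entry is None:
            continue
        gi, starts = entry
        j = np.searchsorted(pos, starts)
        right = np.where(j < pos.size, pos[np.minimum(j, pos.size - 1)] - starts,
                         MAX_DISTANCE)
        left = np.where(j > 0, starts - pos[np.maximum(j - 1, 0)], MAX_DISTANCE)
        mat[gi, si] = np.minimum(np.minimum(left, right), MAX_DISTANCE)
    return pd.DataFrame(
        mat,
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=pd.Index(list(samples), name="sample_id"),
    )


def sv_covariate(distance_matrix: pd.DataFrame) -> pd.DataFrame:
    """log10(distance + 1): monotone in distance, bounded by log10(1e6 + 1)."""
    if (distance_matrix.to_numpy() < 0).any():
        raise ValueError("negative breakpoint distance")
    return np.log10(distance_matrix + 1.0)
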