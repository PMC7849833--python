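"""Methylation arm: CGI probe filtering, logit betas, and the SNV screen.

Array probes are restricted to CpG islands on autosomes (sex chromosomes
are excluded because their methylation tracks patient gender, not somatic
events).  Beta values are logit-transformed for linear modelling, probes
are joined to genes through the manifest's own gene annotation, and the
identical screening engine used for expression is applied with the probe
response swapped in.  Downstream, hits are broken down by promoter
association and probe position class, correlated with expression, and
overlapped with the expression-arm hit list.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import (
    ScreenLog,
    encode_covariates,
    ols_fit,
    CollinearError,
    run_screen,
    storey_qvalues,
)
from .regions import PresenceMatrix, RegionKind

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})

POSITION_CLASSES = ["TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR",
                    "intergenic"]


def filter_cgi_probes(manifest: pd.DataFrame) -> pd.DataFrame:
    """Keep probes inside a CGI (non-empty cgi_id) on autosomes."""
    for col in ("cgi_id", "chrom"):
        if col not in manifest.columns:
            raise ValueError(f"manifest lacks required column {col!r}")
    keep = manifest["cgi_id"].astype(str).str.len() > 0
    keep &= ~manifest["chrom"].isin(SEX_CHROMS)
    return manifest[keep].copy()


def logit_beta(beta, eps: float = 1e-6):
    """ln(b / (1-b)) with b clipped to [eps, 1-eps]; beta must be in [0,1]."""
    arr = np.asarray(beta, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(arr, eps, 1.0 - eps)
    out = np.log(b / (1.0 - b))
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return float(out)
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    return out


def inverse_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def run_methylation_screen(
    presence: Mapping[RegionKind, PresenceMatrix],
    beta_matrix: pd.DataFrame,
    probe_gene: Mapping[str, str] | pd.Series,
    covariates: pd.DataFrame,
    sv_matrix: pd.DataFrame,
    copy_matrix: pd.DataFrame | None,
    *,
    eps: float = 1e-6,
    min_carriers: int = 3,
    fdr_threshold: float = 0.10,
    cna_alpha: float = 0.05,
    log: ScreenLog | None = None,
) -> pd.DataFrame:
    """SNV screen with logit-beta response, one row per probe x region.

    Identical modelling contract to the expression screen: the shared engine
    is called with the response transform swapped and probes mapped to the
    genes of their CGIs.
    """
    mapping = dict(probe_gene) if not isinstance(probe_gene, pd.Series) else probe_gene.to_dict()
    probes = [p for p in beta_matrix.index if p in mapping]
    response = logit_beta(beta_matrix.loc[probes], eps=eps)
    return run_screen(
        presence, response, covariates, sv_matrix, copy_matrix,
        {p: mapping[p] for p in probes},
        min_carriers=min_carriers, fdr_threshold=fdr_threshold,
        cna_alpha=cna_alpha, log=log,
    )


def context_breakdown(
    hits_by_direction: Mapping[str, Sequence[str]],
    tested_probes: Sequence[str],
    manifest: pd.DataFrame,
) -> pd.DataFrame:
    """Promoter-fraction and position-class composition of hit probes.

    For each direction ('+' = gained methylation with SNV, '-' = lost),
    compares the hit probes against the full tested background: fraction of
    promoter-associated probes with a 2x2 chi-square p, and the composition
    over position classes with a classes x {hits, background} chi-square p.
    Empty hit sets report absent (NaN) fractions.
    """
    bg = manifest.loc[[p for p in tested_probes if p in manifest.index]]
    rows = []
    for direction, probes in hits_by_direction.items():
        probes = [p for p in probes if p in manifest.index]
        sub = manifest.loc[probes]
        row: dict = {"direction": direction, "n_hits": len(probes),
                     "n_background": len(bg)}
        if len(probes) == 0:
            row.update({"promoter_fraction": np.nan,
                        "background_promoter_fraction": np.nan,
                        "promoter_chi2_p": np.nan, "position_chi2_p": np.nan})
            for cls in POSITION_CLASSES:
                row[f"frac_{cls}"] = np.nan
            rows.append(row)
            continue
        hit_prom = int(sub["promoter_associated"].sum())
        bg_prom = int(bg["promoter_associated"].sum())
        row["promoter_fraction"] = hit_prom / len(probes)
        row["background_promoter_fraction"] = bg_prom / len(bg) if len(bg) else np.nan
        table = np.array(
            [[hit_prom, len(probes) - hit_prom], [bg_prom, len(bg) - bg_prom]]
        )
        row["promoter_chi2_p"] = _chi2_p(table)
        comp = sub["position_class"].value_counts()
        bg_comp = bg["position_class"].value_counts()
        for cls in POSITION_CLASSES:
            row[f"frac_{cls}"] = comp.get(cls, 0) / len(probes)
        classes = [c for c in POSITION_CLASSES if bg_comp.get(c, 0) > 0 or comp.get(c, 0) > 0]
        table2 = np.array(
            [[comp.get(c, 0) for c in classes], [bg_comp.get(c, 0) for c in classes]]
        )
        row["position_chi2_p"] = _chi2_p(table2)
        rows.append(row)
    return pd.DataFrame(rows)


def _chi2_p(table: np.ndarray) -> float:
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return np.nan
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def methylation_expression_correlation(
    beta_matrix: pd.DataFrame,
    expression_log2: pd.DataFrame,
    probe_gene: Mapping[str, str] | pd.Series,
    covariates: pd.DataFrame,
    copy_matrix: pd.DataFrame | None,
    *,
    eps: float = 1e-6,
    min_samples: int = 10,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per probe-gene pair: OLS of log2 expression on logit beta + covariates.

    Covariates are cancer type and, when available, the gene's copy values.
    Two-sided p for the methylation coefficient; Storey q across all pairs,
    significance at FDR < 5% by default.  Pairs with fewer than
    ``min_samples`` complete observations, or a constant beta row, are
    skipped.
    """
    mapping = dict(probe_gene) if not isinstance(probe_gene, pd.Series) else probe_gene.to_dict()
    common = [s for s in covariates.index
              if s in beta_matrix.columns and s in expression_log2.columns]
    if not common:
        raise ValueError("no shared samples between beta and expression matrices")
    enc = encode_covariates(covariates.loc[common, ["cancer_type"]]
                            if "cancer_type" in covariates.columns else
                            covariates.loc[common, []])
    base = np.column_stack([np.ones(len(common)), enc.to_numpy(dtype=float)]) \
        if enc.shape[1] else np.ones((len(common), 1))
    rows = []
    for probe, gene in mapping.items():
        if probe not in beta_matrix.index or gene not in expression_log2.index:
            continue
        b = logit_beta(beta_matrix.loc[probe, common].to_numpy(dtype=float), eps=eps)
        y = expression_log2.loc[gene, common].to_numpy(dtype=float)
        cols = [base, b[:, None]]
        if copy_matrix is not None and gene in copy_matrix.index:
            copy_col = copy_matrix.loc[gene, common].to_numpy(dtype=float)
            finite = copy_col[np.isfinite(copy_col)]
            if finite.size and np.ptp(finite) > 0:  # constant copy is dropped
                cols.append(copy_col[:, None])
        X = np.column_stack(cols)
        mask = np.isfinite(X).all(axis=1) & np.isfinite(y)
        if mask.sum() < min_samples:
            continue
        Xm, ym = X[mask], y[mask]
        if np.ptp(Xm[:, base.shape[1]]) == 0:  # constant beta row
            continue
        try:
            fit = ols_fit(Xm, ym)
        except CollinearError:
            continue
        coef_idx = base.shape[1]
        coef = float(fit.beta[coef_idx])
        p = float(fit.p[coef_idx])
        if fit.zero_residual and coef != 0.0:
            # exact fit: infinite t; report the minimum representable p
            p = float(np.finfo(float).tiny)
        rows.append({
            "probe_id": probe, "gene_id": gene, "n_used": int(mask.sum()),
            "coef": coef, "p": p,
        })
    out = pd.DataFrame(rows, columns=["probe_id", "gene_id", "n_used", "coef", "p"])
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    qres = storey_qvalues(out["p"].to_numpy())
    out["q"] = qres.qvalues
    out["significant"] = out["q"] < fdr_threshold
    return out


def overlap_expression_methylation_hits(
    expr_hit_genes: Sequence[str],
    methyl_hit_genes: Sequence[str],
    universe: Sequence[str],
) -> dict:
    """Observed vs expected overlap of two gene sets with hypergeometric p.

    ``universe`` is the explicit shared set of genes tested in both arms;
    the p-value is the upper tail (one-sided enrichment, as a Fisher exact
    test on the 2x2 table would give).
    """
    uni = set(universe)
    a = set(expr_hit_genes) & uni
    b = set(methyl_hit_genes) & uni
    if len(set(expr_hit_genes)) > len(uni) or len(set(methyl_hit_genes)) > len(uni):
        raise ValueError("hit set larger than the stated universe")
    n_uni = len(uni)
    overlap = len(a & b)
    expected = len(a) * len(b) / n_uni if n_uni else np.nan
    if n_uni:
        p = float(stats.hypergeom.sf(overlap - 1, n_uni, len(a), len(b)))
    else:
        p = np.nan
    return {
        "n_universe": n_uni, "n_expr_hits": len(a), "n_methyl_hits": len(b),
        "observed_overlap": overlap, "expected_overlap": expected,
        "fisher_p_one_sided": p,
        "overlap_genes": sorted(a & b),
    }
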