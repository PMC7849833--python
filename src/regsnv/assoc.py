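"""Covariate-adjusted linear screen of SNV presence against a response.

The expression arm regresses log2 expression of each gene on the 0/1
presence of nearby SNVs, adjusting for cancer type, gender, log2 mutation
burden and the gene-level SV breakpoint-distance covariate.  Genes need at
least three carriers to be tested.  Per region, Storey-Tibshirani q-values
call significance (FDR < 10% by default), and every hit is refit with the
gene's copy number added: the association must survive (P < 0.05 for the
SNV term) to count as copy-number independent.  The same engine drives the
methylation arm (logit-beta response, probes mapped to genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, linalg, stats

from .regions import PresenceMatrix, RegionKind

# ---------------------------------------------------------------------------
# transforms


def log_transform(raw_expression: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(x + pseudocount); negative input is an error."""
    vals = raw_expression.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise ValueError("expression values must be non-negative")
    out = raw_expression.astype(float).copy()
    out[:] = np.log2(vals + pseudocount)
    out.attrs["transform"] = f"log2(x + {pseudocount})"
    return out


# ---------------------------------------------------------------------------
# OLS core


@dataclass
class OLSFit:
    beta: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    p: np.ndarray
    df_resid: int
    zero_residual: bool = False


class CollinearError(ValueError):
    """Design matrix is rank-deficient after encoding."""


def ols_fit(X: np.ndarray, y: np.ndarray) -> OLSFit:
    """OLS with two-sided t-test p-values per coefficient.

    Columns are scaled to unit norm before a QR factorisation for numerical
    stability; a (near-)zero diagonal of R flags collinearity.  Zero residual
    variance yields p = 1 for every term, flagged on the result.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise CollinearError(f"n={n} samples for k={k} coefficients")
    norms = np.sqrt((X * X).sum(axis=0))
    if (norms == 0).any():
        raise CollinearError("all-zero design column")
    Xs = X / norms
    Q, R = np.linalg.qr(Xs)
    diag = np.abs(np.diag(R))
    if diag.min() < 1e-8 * max(diag.max(), 1.0):
        raise CollinearError("rank-deficient design")
    beta_s = linalg.solve_triangular(R, Q.T @ y)
    resid = y - Xs @ beta_s
    rss = float(resid @ resid)
    df_resid = n - k
    tss = float(((y - y.mean()) ** 2).sum())
    Rinv = linalg.solve_triangular(R, np.eye(k))
    unscaled_cov = Rinv @ Rinv.T
    zero_resid = rss <= 1e-12 * max(tss, 1.0)
    sigma2 = rss / df_resid
    se_s = np.sqrt(np.maximum(sigma2 * np.diag(unscaled_cov), 0.0))
    beta = beta_s / norms
    se = se_s / norms
    if zero_resid:
        tstat = np.zeros(k)
        p = np.ones(k)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    return OLSFit(beta, se, tstat, p, df_resid, zero_residual=zero_resid)


def encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns for the sample covariates (no intercept).

    Cancer type is one-hot encoded with the first (lexicographic) level as
    reference; gender becomes indicator columns the same way.  Constant
    columns (e.g. gender within a single-sex cohort) are dropped.
    """
    parts = []
    for col in ("cancer_type", "gender"):
        if col in covariates.columns:
            dummies = pd.get_dummies(
                covariates[col].astype(str), prefix=col, drop_first=True, dtype=float
            )
            parts.append(dummies)
    if "log2_burden" in covariates.columns:
        parts.append(covariates[["log2_burden"]].astype(float))
    design = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=covariates.index)
    keep = [c for c in design.columns if design[c].nunique() > 1]
    return design[keep]


@dataclass
class SNVFit:
    beta: float
    p: float
    n_used: int
    n_carriers: int
    reason: str | None = None  # None = fitted; "collinear", "zero_residual", ...


def fit_snv_model(
    y: pd.Series,
    snv: pd.Series,
    covariates: pd.DataFrame,
    sv_cov: pd.Series | None = None,
    copy: pd.Series | None = None,
    min_carriers: int = 3,
) -> SNVFit:
    """Fit one gene: OLS of y on [1, snv, covariates, sv, (copy)].

    Samples are the index intersection; missing y, covariates or copy values
    drop the sample listwise.  Returns the SNV coefficient and its two-sided
    t-test p, or a reason code when the gene cannot be fitted.
    """
    samples = y.index.intersection(covariates.index)
    frame = pd.DataFrame({"y": y.reindex(samples), "snv": snv.reindex(samples)})
    enc = encode_covariates(covariates.loc[samples])
    frame = pd.concat([frame, enc], axis=1)
    if sv_cov is not None:
        frame["sv_cov"] = sv_cov.reindex(samples)
    if copy is not None:
        frame["copy"] = copy.reindex(samples)
    frame = frame.dropna()
    n_carriers = int(frame["snv"].sum())
    if n_carriers < min_carriers:
        return SNVFit(np.nan, np.nan, len(frame), n_carriers, reason="too_few_carriers")
    X = np.column_stack(
        [np.ones(len(frame)), frame["snv"].to_numpy()]
        + [frame[c].to_numpy(dtype=float) for c in frame.columns[2:]]
    )
    try:
        fit = ols_fit(X, frame["y"].to_numpy())
    except CollinearError:
        return SNVFit(np.nan, np.nan, len(frame), n_carriers, reason="collinear")
    reason = "zero_residual" if fit.zero_residual else None
    return SNVFit(float(fit.beta[1]), float(fit.p[1]), len(frame), n_carriers, reason)


# ---------------------------------------------------------------------------
# Storey-Tibshirani q-values


@dataclass
class QValueResult:
    pvalues: np.ndarray
    pi0: float
    qvalues: np.ndarray


def storey_qvalues(
    pvalues: Sequence[float],
    *,
    pi0: float | None = None,
    lambdas: np.ndarray | None = None,
) -> QValueResult:
    """Storey-Tibshirani q-values.

    pi0 is estimated on the lambda grid 0.05..0.95 via a natural cubic
    spline through pi0(lambda), evaluated at lambda = 0.95 and clamped to
    [0, 1]; for fewer than 100 p-values pi0 is pinned to 1 (reducing the
    procedure to Benjamini-Hochberg).  Passing ``pi0`` explicitly overrides
    the estimate.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            pi0 = 1.0
        else:
            lams = np.arange(0.05, 0.96, 0.05) if lambdas is None else np.asarray(lambdas)
            pi0_lam = np.array([(p > lam).mean() / (1.0 - lam) for lam in lams])
            spline = interpolate.CubicSpline(lams, pi0_lam, bc_type="natural")
            pi0 = float(np.clip(spline(lams[-1]), 0.0, 1.0))
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError("pi0 must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(p, pi0, q)


# ---------------------------------------------------------------------------
# the screen engine


@dataclass
class ScreenLog:
    """Per-region bookkeeping: why genes were skipped, and totals."""

    tested: dict[str, int] = field(default_factory=dict)
    skipped: dict[str, dict[str, int]] = field(default_factory=dict)

    def note_skip(self, region: str, reason: str) -> None:
        self.skipped.setdefault(region, {})[reason] = (
            self.skipped.setdefault(region, {}).get(reason, 0) + 1
        )


RESULT_COLUMNS = [
    "feature_id", "gene_id", "region", "n_carriers", "n_used",
    "beta_snv", "p_snv", "q_snv", "direction",
    "p_snv_with_cna", "passes_cna_filter", "significant",
]


def run_screen(
    presence: Mapping[RegionKind, PresenceMatrix],
    response: pd.DataFrame,
    covariates: pd.DataFrame,
    sv_matrix: pd.DataFrame,
    copy_matrix: pd.DataFrame | None,
    feature_to_gene: Mapping[str, str] | None = None,
    *,
    min_carriers: int = 3,
    fdr_threshold: float = 0.10,
    cna_alpha: float = 0.05,
    log: ScreenLog | None = None,
) -> pd.DataFrame:
    """Run the covariate-adjusted SNV screen over all regions.

    ``response`` rows are features (genes, or probes already mapped to genes
    through ``feature_to_gene``), columns samples.  q-values are computed
    within each region across the features actually fitted; features with
    q < ``fdr_threshold`` are refit with the gene's copy values, and pass
    the copy-number filter iff the refit SNV p stays below ``cna_alpha``.
    """
    log = log if log is not None else ScreenLog()
    first = next(iter(presence.values()))
    common = [
        s for s in covariates.index
        if s in response.columns and s in first.values.columns and s in sv_matrix.columns
    ]
    if not common:
        raise ValueError("no samples shared between response, covariates and matrices")
    enc = encode_covariates(covariates.loc[common]).to_numpy(dtype=float)
    base = np.column_stack([np.ones(len(common)), enc])
    n = len(common)

    features = list(response.index)
    if feature_to_gene is None:
        feature_to_gene = {f: f for f in features}
    resp_np = response[common].to_numpy(dtype=float)
    sv_genes = {g: i for i, g in enumerate(sv_matrix.index)}
    sv_np = sv_matrix[common].to_numpy(dtype=float)
    if copy_matrix is not None:
        copy_genes = {g: i for i, g in enumerate(copy_matrix.index)}
        copy_np = copy_matrix[common].to_numpy(dtype=float)

    rows: list[dict] = []
    for kind, pm in presence.items():
        region = kind.value if isinstance(kind, RegionKind) else str(kind)
        pres_genes = {g: i for i, g in enumerate(pm.values.index)}
        pres_np = pm.values[common].to_numpy()
        n_tested = 0
        region_rows: list[dict] = []
        for fi, feat in enumerate(features):
            gene = feature_to_gene.get(feat)
            if gene is None or gene not in pres_genes:
                log.note_skip(region, "gene_not_in_annotation")
                continue
            if gene not in sv_genes:
                log.note_skip(region, "gene_not_in_sv_matrix")
                continue
            y = resp_np[fi]
            mask = np.isfinite(y)
            snv = pres_np[pres_genes[gene]]
            n_carriers = int(snv[mask].sum())
            if n_carriers < min_carriers:
                log.note_skip(region, "too_few_carriers")
                continue
            yy = y[mask]
            X = np.column_stack(
                [base[mask], sv_np[sv_genes[gene], mask], snv[mask].astype(float)]
            )
            try:
                fit = ols_fit(X, yy)
            except CollinearError:
                log.note_skip(region, "collinear")
                continue
            if fit.zero_residual:
                log.note_skip(region, "zero_residual")
                continue
            n_tested += 1
            beta = float(fit.beta[-1])
            region_rows.append(
                {
                    "feature_id": feat, "gene_id": gene, "region": region,
                    "n_carriers": n_carriers, "n_used": int(mask.sum()),
                    "beta_snv": beta, "p_snv": float(fit.p[-1]),
                    "direction": "+" if beta >= 0 else "-",
                    "_fi": fi, "_mask": mask, "_X": X,
                }
            )
        log.tested[region] = n_tested
        if not region_rows:
            continue
        qres = storey_qvalues([r["p_snv"] for r in region_rows])
        for r, q in zip(region_rows, qres.qvalues):
            r["q_snv"] = float(q)
            r["p_snv_with_cna"] = np.nan
            r["passes_cna_filter"] = False
            if q < fdr_threshold:
                r["passes_cna_filter"], r["p_snv_with_cna"] = _cna_refit(
                    r, resp_np, copy_np if copy_matrix is not None else None,
                    copy_genes if copy_matrix is not None else None,
                    cna_alpha, log, region,
                )
            r["significant"] = bool(q < fdr_threshold and r["passes_cna_filter"])
            del r["_fi"], r["_mask"], r["_X"]
        rows.extend(region_rows)

    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if not out.empty:
        out = out.sort_values(["region", "q_snv", "p_snv", "feature_id"]).reset_index(
            drop=True
        )
    return out


def _cna_refit(row, resp_np, copy_np, copy_genes, cna_alpha, log, region):
    """Refit one hit with the gene's copy values added to the design."""
    if copy_np is None or row["gene_id"] not in copy_genes:
        log.note_skip(region, "no_copy_data_for_refit")
        return True, np.nan
    mask = row["_mask"]
    copy_row = copy_np[copy_genes[row["gene_id"]], mask]
    cmask = np.isfinite(copy_row)
    if np.ptp(copy_row[cmask]) == 0:
        # constant copy column carries no information (encoder drops it);
        # the refit degenerates to the original fit
        return bool(row["p_snv"] < cna_alpha), row["p_snv"]
    X = np.column_stack([row["_X"][cmask], copy_row[cmask]])
    y = resp_np[row["_fi"]][mask][cmask]
    # SNV column sits at index -2 after appending copy
    try:
        fit = ols_fit(X, y)
    except CollinearError:
        log.note_skip(region, "collinear_cna_refit")
        return False, np.nan
    p = float(fit.p[-2])
    return bool(p < cna_alpha), p


def run_expression_screen(
    presence: Mapping[RegionKind, PresenceMatrix],
    expression_log2: pd.DataFrame,
    covariates: pd.DataFrame,
    sv_matrix: pd.DataFrame,
    copy_matrix: pd.DataFrame | None,
    *,
    min_carriers: int = 3,
    fdr_threshold: float = 0.10,
    cna_alpha: float = 0.05,
    log: ScreenLog | None = None,
) -> pd.DataFrame:
    """Expression arm: features are genes themselves (identity mapping)."""
    return run_screen(
        presence, expression_log2, covariates, sv_matrix, copy_matrix, None,
        min_carriers=min_carriers, fdr_threshold=fdr_threshold,
        cna_alpha=cna_alpha, log=log,
    )


def snv_permutation_pvalues(
    presence: PresenceMatrix,
    response: pd.DataFrame,
    covariates: pd.DataFrame,
    sv_matrix: pd.DataFrame,
    n_permutations: int,
    rng: np.random.Generator,
    *,
    min_carriers: int = 3,
) -> np.ndarray:
    """Pooled SNV-term p-values after permuting sample labels of the SNV column.

    Breaking the SNV-response link while keeping everything else intact
    yields p-values that should be uniform; used to check test calibration.
    """
    common = [
        s for s in covariates.index
        if s in response.columns and s in presence.values.columns and s in sv_matrix.columns
    ]
    enc = encode_covariates(covariates.loc[common]).to_numpy(dtype=float)
    base = np.column_stack([np.ones(len(common)), enc])
    resp_np = response[common].to_numpy(dtype=float)
    pres_np = presence.values[common].to_numpy()
    pres_genes = {g: i for i, g in enumerate(presence.values.index)}
    sv_np = sv_matrix[common].to_numpy(dtype=float)
    sv_genes = {g: i for i, g in enumerate(sv_matrix.index)}
    n = len(common)
    out = []
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        for fi, feat in enumerate(response.index):
            if feat not in pres_genes or feat not in sv_genes:
                continue
            snv = pres_np[pres_genes[feat]][perm].astype(float)
            if snv.sum() < min_carriers or snv.sum() >= n:
                continue
            X = np.column_stack([base, sv_np[sv_genes[feat]], snv])
            try:
                fit = ols_fit(X, resp_np[fi])
            except CollinearError:
                continue
            if not fit.zero_residual:
                out.append(float(fit.p[-1]))
    return np.asarray(out)
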