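"""Methylation arm: probe filter, logit transform, breakdowns, overlaps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regsnv import methyl
from regsnv.methyl import (
    context_breakdown,
    filter_cgi_probes,
    inverse_logit,
    logit_beta,
    methylation_expression_correlation,
    overlap_expression_methylation_hits,
)


def _manifest(rows):
    df = pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "cgi_id", "gene",
                       "position_class", "promoter_associated"],
    )
    df["promoter_associated"] = df["promoter_associated"].astype(bool)
    return df.set_index("probe_id", drop=False)


class TestFilterCgiProbes:
    def test_hand_filter_on_fabricated_manifest(self):
        rows = [
            ("p1", "chr1", 100, "CGI_1", "g1", "TSS200", 1),   # keep
            ("p2", "chrX", 100, "CGI_2", "g2", "Body", 0),     # sex chrom
            ("p3", "chr2", 100, "", "g3", "Body", 0),          # no CGI
            ("p4", "chrY", 100, "CGI_4", "g4", "TSS1500", 1),  # sex chrom
            ("p5", "chr3", 100, "CGI_5", "g5", "3'UTR", 0),    # keep
            ("p6", "X", 100, "CGI_6", "g6", "Body", 0),        # sex chrom, bare name
        ]
        kept = filter_cgi_probes(_manifest(rows))
        assert list(kept["probe_id"]) == ["p1", "p5"]

    def test_missing_columns_error(self):
        with pytest.raises(ValueError, match="cgi_id"):
            filter_cgi_probes(pd.DataFrame({"chrom": ["chr1"]}))


class TestLogitBeta:
    def test_closed_forms(self):
        assert logit_beta(0.5) == 0.0
        assert logit_beta(0.8) == pytest.approx(np.log(4), abs=1e-12)

    def test_clipping_keeps_extremes_finite(self):
        v = logit_beta(1.0, eps=1e-6)
        assert np.isfinite(v)
        assert v == pytest.approx(np.log((1 - 1e-6) / 1e-6), abs=1e-9)
        assert np.isfinite(logit_beta(0.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            logit_beta(1.2)

    def test_round_trip_inside_clip_range(self, rng):
        b = rng.uniform(1e-5, 1 - 1e-5, 1000)
        assert np.allclose(inverse_logit(logit_beta(b)), b, atol=1e-9)


class TestScreenSharedEngine:
    def test_methylation_equals_expression_path_on_identical_inputs(self, small_bundle):
        """Same engine: a logit-beta matrix fed to both screens gives equal fits."""
        from regsnv import assoc, sv_distance
        from regsnv.regions import build_all_presence_matrices

        b = small_bundle
        presence = build_all_presence_matrices(b.snvs, b.genes, b.samples)
        svc = sv_distance.sv_covariate(
            sv_distance.breakpoint_distance_matrix(b.breakends, b.genes, b.samples)
        )
        kept = filter_cgi_probes(b.manifest)
        logit = methyl.logit_beta(b.betas)
        # expression-arm path with the logit responses renamed to their genes
        mapping = kept["gene"].to_dict()
        renamed = logit.rename(index=mapping)
        renamed = renamed[~renamed.index.duplicated()]
        res_expr_path = assoc.run_screen(
            presence, renamed, b.covariates, svc, b.copy_number, None
        )
        res_meth = methyl.run_methylation_screen(
            presence, b.betas.loc[[p for p in b.betas.index
                                   if mapping.get(p) in set(renamed.index)]],
            kept["gene"], b.covariates, svc, b.copy_number,
        )
        merged = res_meth.merge(
            res_expr_path, left_on=["gene_id", "region"],
            right_on=["feature_id", "region"], suffixes=("_m", "_e"),
        )
        assert len(merged) > 50
        assert np.allclose(merged["beta_snv_m"], merged["beta_snv_e"], atol=1e-12)
        assert np.allclose(merged["p_snv_m"], merged["p_snv_e"], atol=1e-12)

    def test_probe_with_too_few_carriers_not_tested(self, small_bundle):
        from regsnv import sv_distance
        from regsnv.regions import RegionKind, build_all_presence_matrices

        b = small_bundle
        presence = build_all_presence_matrices(b.snvs, b.genes, b.samples)
        svc = sv_distance.sv_covariate(
            sv_distance.breakpoint_distance_matrix(b.breakends, b.genes, b.samples)
        )
        kept = filter_cgi_probes(b.manifest)
        res = methyl.run_methylation_screen(
            presence, b.betas, kept["gene"], b.covariates, svc, b.copy_number
        )
        pm = presence[RegionKind.UP1KB].values
        tested = set(res[res["region"] == "up1kb"]["gene_id"])
        under = set(pm.index[pm.sum(axis=1) < 3])
        assert not tested & under


class TestContextBreakdown:
    def test_contingency_oracle(self):
        rows = [(f"h{i}", "chr1", i, "CGI", f"g{i}", "TSS200", 1) for i in range(10)]
        rows += [(f"b{i}", "chr1", i, "CGI", f"g{i}", "Body",
                  1 if i < 10 else 0) for i in range(20)]
        man = _manifest(rows)
        hits = [f"h{i}" for i in range(10)]
        tested = [r[0] for r in rows]
        out = context_breakdown({"+": hits}, tested, man)
        row = out.iloc[0]
        assert row["promoter_fraction"] == 1.0
        assert row["background_promoter_fraction"] == pytest.approx(20 / 30)
        table = np.array([[10, 0], [20, 10]])
        _, p_hand, _, _ = stats.chi2_contingency(table, correction=False)
        assert row["promoter_chi2_p"] == pytest.approx(p_hand, abs=1e-12)

    def test_hit_set_equal_to_background_no_enrichment(self):
        rows = [(f"p{i}", "chr1", i, "CGI", f"g{i}", "TSS200", i % 2)
                for i in range(12)]
        man = _manifest(rows)
        tested = [r[0] for r in rows]
        out = context_breakdown({"+": tested}, tested, man)
        assert out.iloc[0]["promoter_chi2_p"] == pytest.approx(1.0)

    def test_composition_sums_to_one(self, small_bundle):
        man = filter_cgi_probes(small_bundle.manifest)
        hits = list(man["probe_id"][:15])
        out = context_breakdown({"+": hits}, list(man["probe_id"]), man)
        frac_cols = [c for c in out.columns if c.startswith("frac_")]
        assert out.iloc[0][frac_cols].sum() == pytest.approx(1.0)

    def test_empty_hit_set_reports_absent(self):
        rows = [("p1", "chr1", 1, "CGI", "g1", "Body", 0)]
        out = context_breakdown({"-": []}, ["p1"], _manifest(rows))
        assert np.isnan(out.iloc[0]["promoter_fraction"])


class TestMethylationExpressionCorrelation:
    def _inputs(self, n=30, anti=True, rng=None):
        rng = rng or np.random.default_rng(3)
        samples = [f"s{i}" for i in range(n)]
        logit = rng.normal(0, 1, n)
        betas = pd.DataFrame([1 / (1 + np.exp(-logit))], index=["p1"],
                             columns=samples)
        expr = pd.DataFrame([-logit if anti else rng.normal(size=n)],
                            index=["g1"], columns=samples)
        cov = pd.DataFrame({"cancer_type": ["A"] * n}, index=samples)
        return betas, expr, cov

    def test_perfect_anticorrelation(self):
        betas, expr, cov = self._inputs(anti=True)
        out = methylation_expression_correlation(betas, expr, {"p1": "g1"}, cov, None)
        assert out.iloc[0]["coef"] < 0
        assert out.iloc[0]["p"] <= np.finfo(float).tiny * 10

    def test_null_rate_about_five_percent(self):
        rng = np.random.default_rng(11)
        n, pairs = 40, 100
        samples = [f"s{i}" for i in range(n)]
        betas = pd.DataFrame(rng.uniform(0.1, 0.9, (pairs, n)),
                             index=[f"p{i}" for i in range(pairs)], columns=samples)
        expr = pd.DataFrame(rng.normal(8, 1, (pairs, n)),
                            index=[f"g{i}" for i in range(pairs)], columns=samples)
        cov = pd.DataFrame({"cancer_type": ["A"] * n}, index=samples)
        out = methylation_expression_correlation(
            betas, expr, {f"p{i}": f"g{i}" for i in range(pairs)}, cov, None
        )
        assert 0 <= (out["p"] < 0.05).sum() <= 13  # ~5 expected of 100

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        n = 30
        samples = [f"s{i}" for i in range(n)]
        b = rng.uniform(0.2, 0.8, n)
        betas = pd.DataFrame([b], index=["p1"], columns=samples)
        y = rng.normal(size=n)
        expr = pd.DataFrame([y], index=["g1"], columns=samples)
        cov = pd.DataFrame({"cancer_type": ["A"] * 15 + ["B"] * 15}, index=samples)
        out = methylation_expression_correlation(betas, expr, {"p1": "g1"}, cov, None)
        X = np.column_stack([np.ones(n), (np.array(cov["cancer_type"]) == "B"),
                             logit_beta(b)])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta_hat = XtX_inv @ X.T @ y
        resid = y - X @ beta_hat
        sigma2 = resid @ resid / (n - 3)
        se = np.sqrt(np.diag(XtX_inv) * sigma2)
        p = 2 * stats.t.sf(abs(beta_hat[2] / se[2]), n - 3)
        assert out.iloc[0]["coef"] == pytest.approx(beta_hat[2], abs=1e-8)
        assert out.iloc[0]["p"] == pytest.approx(p, abs=1e-8)

    def test_constant_beta_row_skipped(self):
        samples = [f"s{i}" for i in range(20)]
        betas = pd.DataFrame([[0.5] * 20], index=["p1"], columns=samples)
        expr = pd.DataFrame([np.random.default_rng(0).normal(size=20)],
                            index=["g1"], columns=samples)
        cov = pd.DataFrame({"cancer_type": ["A"] * 20}, index=samples)
        out = methylation_expression_correlation(betas, expr, {"p1": "g1"}, cov, None)
        assert out.empty


class TestOverlapHits:
    def test_identical_sets(self):
        uni = [f"g{i}" for i in range(20)]
        res = overlap_expression_methylation_hits(uni[:5], uni[:5], uni)
        assert res["observed_overlap"] == 5
        # smallest possible p for this configuration
        assert res["fisher_p_one_sided"] == pytest.approx(
            float(stats.hypergeom.sf(4, 20, 5, 5)), abs=1e-15
        )

    def test_brute_force_hypergeometric_tail(self):
        # |A|=5, |B|=5, N=20, overlap=3: sum the exact tail by enumeration
        from math import comb

        p_brute = sum(
            comb(5, k) * comb(15, 5 - k) for k in range(3, 6)
        ) / comb(20, 5)
        uni = [f"g{i}" for i in range(20)]
        a = uni[:5]
        b = uni[2:5] + uni[10:12]  # overlap exactly 3
        res = overlap_expression_methylation_hits(a, b, uni)
        assert res["observed_overlap"] == 3
        assert res["fisher_p_one_sided"] == pytest.approx(p_brute, abs=1e-12)
        assert res["expected_overlap"] == pytest.approx(25 / 20)

    def test_disjoint_sets_large_universe(self):
        uni = [f"g{i}" for i in range(10_000)]
        res = overlap_expression_methylation_hits(uni[:5], uni[5:10], uni)
        assert res["observed_overlap"] == 0
        assert res["fisher_p_one_sided"] == pytest.approx(1.0, abs=0.05)

    def test_universe_smaller_than_set_errors(self):
        with pytest.raises(ValueError):
            overlap_expression_methylation_hits(["a", "b"], ["a"], ["a"])
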