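"""Linear-model engine, Storey q-values, and the expression screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regsnv import assoc
from regsnv.assoc import (
    CollinearError,
    QValueResult,
    encode_covariates,
    fit_snv_model,
    log_transform,
    ols_fit,
    storey_qvalues,
)


class TestLogTransform:
    def test_values(self):
        df = pd.DataFrame({"s1": [0.0, 7.0]}, index=["g1", "g2"])
        out = log_transform(df, pseudocount=1.0)
        assert out.loc["g1", "s1"] == 0.0
        assert out.loc["g2", "s1"] == 3.0

    def test_round_trip(self, rng):
        df = pd.DataFrame(rng.uniform(0, 1e4, size=(5, 4)))
        back = np.exp2(log_transform(df)) - 1.0
        assert np.allclose(back.to_numpy(), df.to_numpy(), atol=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(pd.DataFrame({"s": [-0.1]}))


def _normal_equations_oracle(X, y):
    """Independent oracle: explicit (X'X)^-1 X'y plus t-distribution p-values."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, p


class TestOlsFit:
    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(20, 60))
            k = int(rng.integers(2, 6))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
            y = rng.normal(size=n)
            fit = ols_fit(X, y)
            beta, se, p = _normal_equations_oracle(X, y)
            assert np.allclose(fit.beta, beta, atol=1e-8)
            assert np.allclose(fit.se, se, atol=1e-8)
            assert np.allclose(fit.p, np.clip(p, np.finfo(float).tiny, 1), atol=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = np.column_stack([np.ones(30), rng.normal(size=(30, 3))])
        y = rng.normal(size=30) + X[:, 1]
        fit = ols_fit(X, y)
        ref = sm.OLS(y, X).fit()
        assert np.allclose(fit.beta, ref.params, atol=1e-10)
        assert np.allclose(fit.p, ref.pvalues, atol=1e-10)

    def test_collinear_raises(self):
        X = np.column_stack([np.ones(10), np.arange(10), 2 * np.arange(10)])
        with pytest.raises(CollinearError):
            ols_fit(X, np.random.default_rng(0).normal(size=10))

    def test_zero_residual_flagged_p_one(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = 3.0 + 2.0 * np.arange(10.0)  # exact fit
        fit = ols_fit(X, y)
        assert fit.zero_residual
        assert (fit.p == 1.0).all()
        assert fit.beta[1] == pytest.approx(2.0, abs=1e-10)


def _covariates(n, types=("A",), rng=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {
            "cancer_type": [types[i % len(types)] for i in range(n)],
            "gender": ["F" if rng.random() < 0.5 else "M" for _ in range(n)],
            "log2_burden": rng.normal(10, 1, n),
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestFitSnvModel:
    def test_exact_interpolation_zero_noise(self):
        # 12 samples, one cancer type, planted +2 shift on 4 carriers
        cov = _covariates(12)
        cov["log2_burden"] = 10.0
        y = pd.Series([5.0] * 12, index=cov.index)
        snv = pd.Series(0, index=cov.index)
        snv.iloc[:4] = 1
        y.iloc[:4] += 2.0
        fit = fit_snv_model(y, snv, cov[["cancer_type"]], min_carriers=3)
        assert fit.beta == pytest.approx(2.0, abs=1e-10)
        assert fit.reason == "zero_residual"

    def test_matches_oracle_with_noise(self, rng):
        n = 40
        cov = _covariates(n, types=("A", "B"), rng=rng)
        snv = pd.Series((rng.random(n) < 0.3).astype(int), index=cov.index)
        y = pd.Series(rng.normal(size=n) + 0.8 * snv.to_numpy(), index=cov.index)
        sv = pd.Series(rng.uniform(0, 6, n), index=cov.index)
        fit = fit_snv_model(y, snv, cov, sv_cov=sv)
        enc = encode_covariates(cov)
        X = np.column_stack([np.ones(n), snv.to_numpy(float), enc.to_numpy(float),
                             sv.to_numpy()])
        beta, _, p = _normal_equations_oracle(X, y.to_numpy())
        assert fit.beta == pytest.approx(beta[1], abs=1e-8)
        assert fit.p == pytest.approx(p[1], abs=1e-8)

    def test_snv_identical_to_covariate_is_collinear(self):
        cov = _covariates(20)
        snv = pd.Series([1] * 10 + [0] * 10, index=cov.index)
        cov["log2_burden"] = snv.to_numpy(float)  # duplicate column
        y = pd.Series(np.random.default_rng(1).normal(size=20), index=cov.index)
        fit = fit_snv_model(y, snv, cov)
        assert fit.reason == "collinear"

    def test_fewer_than_three_carriers_not_fitted(self):
        cov = _covariates(20)
        snv = pd.Series([1, 1] + [0] * 18, index=cov.index)
        y = pd.Series(np.random.default_rng(1).normal(size=20), index=cov.index)
        fit = fit_snv_model(y, snv, cov)
        assert fit.reason == "too_few_carriers"

    def test_constant_gender_dropped_automatically(self):
        cov = _covariates(20)
        cov["gender"] = "F"  # single-sex cohort
        snv = pd.Series([1] * 5 + [0] * 15, index=cov.index)
        y = pd.Series(np.random.default_rng(2).normal(size=20), index=cov.index)
        fit = fit_snv_model(y, snv, cov)
        assert fit.reason is None


class TestStoreyQvalues:
    def test_all_p_one(self):
        res = storey_qvalues([1.0] * 50)
        assert (res.qvalues == 1.0).all()
        assert res.pi0 == 1.0  # m < 100 pins pi0

    def test_bh_equivalence_with_pi0_pinned(self):
        res = storey_qvalues([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        assert np.allclose(res.qvalues, [0.04, 0.04, 0.04, 0.04])

    def test_bh_equivalence_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1, int(rng.integers(5, 400)))
            res = storey_qvalues(p, pi0=1.0)
            # independent BH oracle via statsmodels
            from statsmodels.stats.multitest import multipletests

            _, q_bh, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(res.qvalues, q_bh, atol=1e-12)

    def test_pi0_on_uniform_pvalues(self):
        rng = np.random.default_rng(12345)
        p = rng.uniform(size=5000)
        res = storey_qvalues(p)
        assert 0.85 <= res.pi0 <= 1.0

    def test_qvalues_monotone_in_p(self, rng):
        p = rng.uniform(1e-8, 1, 500)
        res = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(res.qvalues[order]) >= -1e-15).all()
        assert ((res.qvalues >= 0) & (res.qvalues <= 1)).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            storey_qvalues([1.5])


class TestScreen:
    def test_invariant_to_sample_column_order(self, small_bundle):
        from regsnv.regions import build_all_presence_matrices
        from regsnv import sv_distance

        b = small_bundle
        presence = build_all_presence_matrices(b.snvs, b.genes, b.samples)
        svc = sv_distance.sv_covariate(
            sv_distance.breakpoint_distance_matrix(b.breakends, b.genes, b.samples)
        )
        expr = log_transform(b.expression)
        res1 = assoc.run_expression_screen(presence, expr, b.covariates, svc,
                                           b.copy_number)
        shuffled = expr[expr.columns[::-1]]
        res2 = assoc.run_expression_screen(presence, shuffled, b.covariates, svc,
                                           b.copy_number)
        pd.testing.assert_frame_equal(res1, res2)

    def test_empty_sample_intersection_errors(self, small_bundle):
        from regsnv.regions import build_all_presence_matrices
        from regsnv import sv_distance

        b = small_bundle
        presence = build_all_presence_matrices(b.snvs, b.genes, b.samples)
        svc = sv_distance.sv_covariate(
            sv_distance.breakpoint_distance_matrix(b.breakends, b.genes, b.samples)
        )
        expr = log_transform(b.expression).rename(columns=lambda s: s + "_other")
        with pytest.raises(ValueError, match="no samples"):
            assoc.run_expression_screen(presence, expr, b.covariates, svc,
                                        b.copy_number)

    def test_results_sorted_by_region_then_q(self, small_bundle):
        from regsnv.regions import build_all_presence_matrices
        from regsnv import sv_distance

        b = small_bundle
        presence = build_all_presence_matrices(b.snvs, b.genes, b.samples)
        svc = sv_distance.sv_covariate(
            sv_distance.breakpoint_distance_matrix(b.breakends, b.genes, b.samples)
        )
        res = assoc.run_expression_screen(
            presence, log_transform(b.expression), b.covariates, svc, b.copy_number
        )
        for region, grp in res.groupby("region"):
            assert (np.diff(grp["q_snv"].to_numpy()) >= -1e-15).all()
        assert (res["n_carriers"] >= 3).all()
        assert (res["direction"] == np.where(res["beta_snv"] >= 0, "+", "-")).all()
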