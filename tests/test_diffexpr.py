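"""Design construction, OLS, empirical-Bayes moderation, adjustment, pi0.

Independent oracles: normal-equations OLS, statsmodels OLS, brute-force BH
enumeration, a numerical maximum-likelihood fit of the variance prior, an
SLSQP convex-mixture fit for pi0, and R limma (lmFit/eBayes, convest) run
through Rscript.
"""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, stats

import crossarray as ca
from crossarray import diffexpr as de
from crossarray.exceptions import (
    DegeneratePriorError,
    InsufficientDFError,
    InvalidArgumentError,
    InvalidInputError,
    RankDeficiencyError,
)
from conftest import bh_brute_force, pi0_slsqp_oracle, simulate_variances


def _meta(study, pe, ga):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(study))],
        "study": study, "pe": pe, "ga_weeks": ga,
    })


class TestBuildDesign:
    def test_three_studies_five_columns(self):
        meta = _meta([1, 1, 2, 2, 3, 3], [0, 1, 0, 1, 0, 1],
                     [20, 25, 30, 35, 38, 40])
        design = de.build_design(meta)
        assert list(design.columns) == ["intercept", "study2", "study3", "pe", "ga_weeks"]

    def test_interaction_column(self):
        meta = _meta([1, 1, 2, 2, 3, 3], [0, 1, 0, 1, 0, 1],
                     [20, 25, 30, 35, 38, 40])
        design = de.build_design(meta, include_interaction=True)
        assert list(design.columns)[-1] == "pe_x_ga"
        np.testing.assert_allclose(
            design["pe_x_ga"], design["pe"] * design["ga_weeks"]
        )

    def test_single_study_no_pe_degenerates(self):
        meta = _meta([1] * 5, [0] * 5, [14, 18, 22, 38, 40])
        design = de.build_design(meta)
        assert list(design.columns) == ["intercept", "ga_weeks"]

    def test_collinear_design_names_columns(self):
        # PE perfectly aligned with the study-2 dummy
        meta = _meta([1, 1, 2, 2], [0, 0, 1, 1], [20, 25, 30, 35])
        with pytest.raises(RankDeficiencyError) as err:
            de.build_design(meta)
        assert "pe" in err.value.columns

    def test_missing_covariates_rejected(self):
        meta = _meta([1, 1, 2], [0, 1, None], [20, 25, 30])
        with pytest.raises(InvalidInputError):
            de.build_design(meta)


class TestFitLinear:
    @pytest.fixture()
    def design(self):
        meta = _meta([1]*6 + [2]*6 + [3]*6,
                     [0, 0, 0, 1, 1, 1] * 3,
                     list(np.linspace(15, 40, 18)))
        return de.build_design(meta)

    def test_noise_free_exact_recovery(self, design):
        rng = np.random.default_rng(0)
        X = design.to_numpy()
        B = rng.normal(size=(7, X.shape[1]))
        Y = pd.DataFrame((X @ B.T).T, index=[f"f{i}" for i in range(7)],
                         columns=design.index)
        fit = de.fit_linear(Y, design)
        np.testing.assert_allclose(fit.beta, B, atol=1e-9)
        np.testing.assert_allclose(fit.sigma, 0.0, atol=1e-9)

    def test_equals_normal_equations_oracle(self, design):
        rng = np.random.default_rng(1)
        X = design.to_numpy()
        Y = pd.DataFrame(rng.normal(size=(50, len(design))),
                         index=[f"f{i}" for i in range(50)], columns=design.index)
        fit = de.fit_linear(Y, design)
        xtx_inv = np.linalg.inv(X.T @ X)
        beta_oracle = (xtx_inv @ X.T @ Y.to_numpy().T).T
        np.testing.assert_allclose(fit.beta, beta_oracle, atol=1e-10)
        resid = Y.to_numpy().T - X @ beta_oracle.T
        s_oracle = np.sqrt((resid**2).sum(axis=0) / (len(design) - X.shape[1]))
        np.testing.assert_allclose(fit.sigma, s_oracle, atol=1e-10)
        np.testing.assert_allclose(fit.stdev_unscaled, np.sqrt(np.diag(xtx_inv)))

    def test_matches_statsmodels(self, design):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        y = rng.normal(size=len(design))
        Y = pd.DataFrame([y], index=["f0"], columns=design.index)
        fit = de.fit_linear(Y, design)
        res = sm.OLS(y, design.to_numpy()).fit()
        np.testing.assert_allclose(fit.beta[0], res.params, atol=1e-10)
        np.testing.assert_allclose(fit.sigma[0] ** 2, res.mse_resid, atol=1e-10)

    def test_sample_permutation_invariance(self, design):
        rng = np.random.default_rng(3)
        Y = pd.DataFrame(rng.normal(size=(10, len(design))),
                         index=[f"f{i}" for i in range(10)], columns=design.index)
        fit = de.fit_linear(Y, design)
        perm = rng.permutation(len(design))
        fit_p = de.fit_linear(Y.iloc[:, perm], design.iloc[perm])
        np.testing.assert_allclose(fit.beta, fit_p.beta, atol=1e-10)
        np.testing.assert_allclose(fit.sigma, fit_p.sigma, atol=1e-10)

    def test_insufficient_df_rejected(self, design):
        Y = pd.DataFrame(np.zeros((3, 4)), columns=design.index[:4])
        with pytest.raises(InsufficientDFError):
            de.fit_linear(Y, design.iloc[:4])


class TestEbayes:
    def test_identical_variances_give_infinite_d0(self):
        fit = de.LinearFit(
            feature_ids=pd.Index([f"f{i}" for i in range(20)]),
            coef_names=["intercept"],
            beta=np.ones((20, 1)),
            sigma=np.full(20, 2.0),
            df_resid=5,
            stdev_unscaled=np.array([0.3]),
        )
        res = de.ebayes_moderate(fit)
        assert np.isinf(res.d0)
        np.testing.assert_allclose(res.post_var, 4.0)

    def test_d0_zero_bypass_equals_ordinary_t(self):
        rng = np.random.default_rng(4)
        n_feat, df = 30, 6
        sigma = rng.gamma(2.0, size=n_feat)
        beta = rng.normal(size=(n_feat, 1))
        fit = de.LinearFit(
            feature_ids=pd.Index([f"f{i}" for i in range(n_feat)]),
            coef_names=["x"], beta=beta, sigma=sigma, df_resid=df,
            stdev_unscaled=np.array([0.5]),
        )
        res = de.ebayes_moderate(fit, d0_override=0.0)
        ordinary_t = beta[:, 0] / (sigma * 0.5)
        np.testing.assert_allclose(res.t[:, 0], ordinary_t, atol=1e-12)
        np.testing.assert_allclose(
            res.p[:, 0], 2 * stats.t.sf(np.abs(ordinary_t), df), atol=1e-12
        )

    def test_infinite_d0_limit_is_z_like(self):
        rng = np.random.default_rng(5)
        sigma = rng.gamma(2.0, size=25)
        beta = rng.normal(size=(25, 1))
        fit = de.LinearFit(
            feature_ids=pd.Index([f"f{i}" for i in range(25)]),
            coef_names=["x"], beta=beta, sigma=sigma, df_resid=8,
            stdev_unscaled=np.array([0.4]),
        )
        res = de.ebayes_moderate(fit, d0_override=np.inf)
        np.testing.assert_allclose(
            res.t[:, 0], beta[:, 0] / (np.sqrt(res.s0_sq) * 0.4), atol=1e-12
        )

    def test_prior_recovery_against_numerical_mle(self):
        d0_true, s0_true, df, n = 4.0, 1.0, 10, 5000
        s2 = simulate_variances(d0_true, s0_true, df, n, seed=6)
        d0_hat, s0_hat = de.estimate_variance_prior(s2, df)
        assert abs(d0_hat - d0_true) / d0_true < 0.2
        assert abs(s0_hat - s0_true) / s0_true < 0.2

        def nll(params):
            ld0, ls0 = params
            d0, s0sq = np.exp(ld0), np.exp(ls0)
            # s2 ~ s0sq * F(df, d0)
            return -stats.f.logpdf(s2 / s0sq, df, d0).sum() + len(s2) * ls0

        mle = optimize.minimize(nll, [np.log(2.0), np.log(0.5)], method="Nelder-Mead")
        d0_mle, s0_mle = np.exp(mle.x)
        assert abs(d0_hat - d0_mle) / d0_mle < 0.15
        assert abs(s0_hat - s0_mle) / s0_mle < 0.05

    def test_all_zero_variances_rejected(self):
        fit = de.LinearFit(
            feature_ids=pd.Index(["f0", "f1"]), coef_names=["x"],
            beta=np.ones((2, 1)), sigma=np.zeros(2), df_resid=4,
            stdev_unscaled=np.array([1.0]),
        )
        with pytest.raises(DegeneratePriorError):
            de.ebayes_moderate(fit)

    def test_matches_limma_ebayes(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(7)
        n_feat, n_samp = 80, 12
        X = np.column_stack([np.ones(n_samp), rng.integers(0, 2, n_samp)])
        design = pd.DataFrame(X, columns=["intercept", "grp"],
                              index=[f"s{i}" for i in range(n_samp)])
        design.index.name = "sample_id"
        sigma2 = simulate_variances(4.0, 0.5, n_samp - 2, n_feat, seed=8)
        Y = (X @ rng.normal(size=(2, n_feat))).T + rng.normal(
            size=(n_feat, n_samp)) * np.sqrt(sigma2)[:, None]
        mat = pd.DataFrame(Y, index=[f"f{i}" for i in range(n_feat)],
                           columns=design.index)
        res = de.ebayes_moderate(de.fit_linear(mat, design))

        mat.to_csv(tmp_path / "y.tsv", sep="\t")
        design.to_csv(tmp_path / "x.tsv", sep="\t")
        script = tmp_path / "limma_check.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"y <- as.matrix(read.delim('{tmp_path}/y.tsv', row.names=1))\n"
            f"x <- as.matrix(read.delim('{tmp_path}/x.tsv', row.names=1))\n"
            "fit <- eBayes(lmFit(y, x))\n"
            "out <- data.frame(t=fit$t[,2], p=fit$p.value[,2])\n"
            "cat(fit$df.prior, fit$s2.prior, '\\n')\n"
            f"write.table(out, '{tmp_path}/limma_out.tsv', sep='\\t', quote=FALSE)\n"
        )
        proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        d0_r, s0_r = map(float, proc.stdout.split()[:2])
        limma_out = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t")
        assert abs(res.d0 - d0_r) / d0_r < 1e-4
        assert abs(res.s0_sq - s0_r) / s0_r < 1e-4
        j = res.coef_names.index("grp")
        np.testing.assert_allclose(res.t[:, j], limma_out["t"], rtol=1e-6)
        np.testing.assert_allclose(res.p[:, j], limma_out["p"], rtol=1e-6)


class TestAdjustPvalues:
    def test_paper_family_threshold_to_3sf(self):
        _, formatted = de.bonferroni_threshold(0.05, 33088)
        assert formatted == "1.51e-06"

    def test_identity_for_single_test(self):
        adj, thr = de.adjust_pvalues([0.03], m=1, method="bonferroni")
        np.testing.assert_allclose(adj, [0.03])
        assert thr == 0.05

    def test_bonferroni_formula(self):
        adj, _ = de.adjust_pvalues([0.01, 0.5, 1e-5], m=100, method="bonferroni")
        np.testing.assert_allclose(adj, [1.0, 1.0, 1e-3])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40),
           st.integers(0, 50))
    def test_bh_equals_enumeration_oracle(self, p, extra_family):
        m = len(p) + extra_family
        adj, _ = de.adjust_pvalues(p, m=m, method="bh")
        np.testing.assert_allclose(adj, bh_brute_force(p, m), atol=1e-12)

    def test_bh_matches_statsmodels_for_exact_family(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(9)
        p = rng.random(200)
        adj, _ = de.adjust_pvalues(p, method="bh")
        _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, sm_adj, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidInputError):
            de.adjust_pvalues([0.5, 1.2], method="bonferroni")


class TestFoldChange:
    @pytest.mark.parametrize("beta,fc", [(1.0, 2.0), (-1.0, -2.0), (0.0, 1.0),
                                         (np.log2(1.057), 1.057)])
    def test_values(self, beta, fc):
        np.testing.assert_allclose(de.signed_fold_change([beta]), [fc], rtol=1e-12)

    @given(st.floats(-20, 20, allow_nan=False))
    def test_magnitude_and_sign(self, beta):
        fc = de.signed_fold_change([beta])[0]
        assert abs(fc) >= 1.0
        assert np.sign(fc) == (1.0 if beta >= 0 else -1.0)


class TestPi0:
    def test_all_ones_degenerate(self):
        est = de.estimate_pi0(np.ones(500))
        assert est.pi0 > 0.99

    def test_uniform_null(self):
        rng = np.random.default_rng(10)
        est = de.estimate_pi0(rng.random(10000))
        assert 0.95 <= est.pi0 <= 1.0

    def test_mixture_recovery_and_convex_oracle(self):
        rng = np.random.default_rng(11)
        n, pi0_true = 10000, 0.7
        is_null = rng.random(n) < pi0_true
        p = np.where(is_null, rng.random(n), rng.beta(0.2, 3.0, size=n))
        est = de.estimate_pi0(p)
        assert abs(est.pi0 - pi0_true) < 0.1
        oracle = pi0_slsqp_oracle(p)
        assert abs(est.pi0 - oracle) < 0.05

    def test_matches_limma_convest(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(12)
        n = 4000
        is_null = rng.random(n) < 0.6
        p = np.where(is_null, rng.random(n), rng.beta(0.3, 4.0, size=n))
        np.savetxt(tmp_path / "p.txt", p)
        script = tmp_path / "convest.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"p <- scan('{tmp_path}/p.txt', quiet=TRUE)\n"
            "cat(convest(p), '\\n')\n"
        )
        proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        pi0_r = float(proc.stdout.split()[0])
        est = de.estimate_pi0(p)
        assert abs(est.pi0 - pi0_r) < 0.05

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            de.estimate_pi0([])



class TestSummaries:
    @pytest.fixture()
    def pairs(self):
        return ca.ProbePairTable(pd.DataFrame({
            "affy_probeset_id": ["A1", "A2", "A3", "A4"],
            "ilmn_probe_id": ["I1", "I1", "I1", "I1"],
            "transcript_id": ["T1", "T1", "T1", "T1"],
            "gene_symbol": ["G1", "G1", "G1", "G1"],
        }))

    def test_no_significant_pairs(self, pairs):
        results = pd.DataFrame({"bonferroni_p": [0.9, 1.0, 0.6, 0.2]},
                               index=pairs.pair_ids)
        out = de.summarize_transcript_level(results, pairs)
        assert out == {"n_significant_pairs": 0, "n_transcripts": 0, "n_genes": 0}

    def test_four_pairs_one_transcript(self, pairs):
        results = pd.DataFrame({"bonferroni_p": [1e-3] * 4}, index=pairs.pair_ids)
        out = de.summarize_transcript_level(results, pairs)
        assert out == {"n_significant_pairs": 4, "n_transcripts": 1, "n_genes": 1}

    def test_counts_equal_set_oracle(self):
        rng = np.random.default_rng(13)
        n = 60
        table = pd.DataFrame({
            "affy_probeset_id": [f"A{i}" for i in range(n)],
            "ilmn_probe_id": [f"I{i % 20}" for i in range(n)],
            "transcript_id": [f"T{i % 15}" for i in range(n)],
            "gene_symbol": [f"G{i % 10}" for i in range(n)],
        })
        pairs = ca.ProbePairTable(table)
        results = pd.DataFrame({"bonferroni_p": rng.random(n)}, index=pairs.pair_ids)
        out = de.summarize_transcript_level(results, pairs, alpha=0.5)
        sig_mask = results["bonferroni_p"].to_numpy() < 0.5
        assert out["n_significant_pairs"] == int(sig_mask.sum())
        assert out["n_transcripts"] == len(set(table["transcript_id"][sig_mask]))
        assert out["n_genes"] == len(set(table["gene_symbol"][sig_mask]))
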