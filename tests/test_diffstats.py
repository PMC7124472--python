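import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from phosphopipe import diffstats, mq_io
from phosphopipe.errors import ConfigError, ContractError


class TestQuantileNormalize:
    def test_hand_computed_two_by_two(self):
        df = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
        out = diffstats.quantile_normalize(df)
        assert out["a"].tolist() == [1.5, 3.5]
        assert out["b"].tolist() == [1.5, 3.5]

    def test_permuted_columns_unchanged_up_to_permutation(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": rng.permutation(x)})
        out = diffstats.quantile_normalize(df)
        # distributions already equal: each column keeps its own ordering
        assert np.argsort(out["a"].to_numpy()).tolist() == np.argsort(
            x
        ).tolist()
        np.testing.assert_allclose(np.sort(out["a"]), np.sort(out["b"]))

    def test_all_columns_share_sorted_vector(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 6)))
        out = diffstats.quantile_normalize(df).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_ties_get_mean_of_rank_range(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = diffstats.quantile_normalize(df)
        target = (np.sort(df["a"]) + np.sort(df["b"])) / 2  # [1.5, 2.5, 5.5]
        assert out["a"].tolist() == [2.0, 2.0, 5.5]
        assert out["b"].tolist() == target.tolist()

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ContractError):
            diffstats.quantile_normalize(df)


def _one_strain_design(batch_constant=True):
    design = mq_io.make_design(strains=("wt_as",))
    if batch_constant:
        design["batch"] = 1
    return design


class TestLinearModel:
    def test_balanced_groups_recover_group_means(self, rng):
        design = _one_strain_design()
        X = diffstats.build_design_matrix(design)
        y = pd.DataFrame(
            [[1, 2, 3, 10, 11, 12.0]], columns=design["run_id"]
        )
        fit = diffstats.fit_linear_model(y, X)
        assert fit.coef.loc[0, "g_wt_as_drug"] == pytest.approx(2.0)
        assert fit.coef.loc[0, "g_wt_as_mock"] == pytest.approx(11.0)
        assert fit.df_resid == 4

    def test_planted_batch_shift_recovered_and_contrast_unbiased(self, rng):
        design = mq_io.make_design(strains=("wt_as", "pka_as"))
        X = diffstats.build_design_matrix(design)
        base = rng.normal(20, 1, size=(40, 1))
        y = np.tile(base, (1, 12))
        shift = np.array(
            [1.0 if b == 2 else 0.0 for b in design["batch"]]
        )
        y = y + shift
        y = pd.DataFrame(y, columns=design["run_id"])
        fit = diffstats.fit_linear_model(y, X)
        np.testing.assert_allclose(fit.coef["batch_2"], 1.0, atol=1e-10)
        c = diffstats.contrast_vector(X.columns, "pka_as")
        logfc = fit.coef.to_numpy() @ c.reindex(fit.coef.columns).to_numpy()
        np.testing.assert_allclose(logfc, 0.0, atol=1e-10)

    def test_matches_lstsq_oracle_per_peptide(self, rng):
        design = mq_io.make_design(strains=("wt_as", "pka_as"))
        X = diffstats.build_design_matrix(design)
        y = pd.DataFrame(
            rng.normal(size=(20, 12)), columns=design["run_id"]
        )
        fit = diffstats.fit_linear_model(y, X)
        Xm = X.to_numpy()
        for i in range(20):
            beta, *_ = np.linalg.lstsq(Xm, y.iloc[i].to_numpy(), rcond=None)
            np.testing.assert_allclose(
                fit.coef.iloc[i].to_numpy(), beta, atol=1e-10
            )
            resid = y.iloc[i].to_numpy() - Xm @ beta
            s2 = (resid**2).sum() / fit.df_resid
            assert fit.s2.iloc[i] == pytest.approx(s2, rel=1e-10)

    def test_rank_deficient_design_names_aliased_column(self):
        design = mq_io.make_design(strains=("wt_as",))
        X = diffstats.build_design_matrix(design)
        X["dup"] = X["g_wt_as_drug"]
        y = pd.DataFrame(np.zeros((2, 6)), columns=design["run_id"])
        with pytest.raises(ConfigError, match="dup"):
            diffstats.fit_linear_model(y, X)


class TestPrior:
    def test_recovery_from_scaled_chi_square(self, rng):
        d0_true, s0_true, d = 4.0, 0.04, 18
        n = 5000
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        prior = diffstats.estimate_prior(s2, d)
        assert prior.d0 == pytest.approx(d0_true, rel=0.25)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_identical_variances_give_infinite_d0(self):
        prior = diffstats.estimate_prior(np.full(100, 0.3), 4)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.3)

    def test_permutation_invariance(self, rng):
        s2 = rng.chisquare(5, 500) / 5
        a = diffstats.estimate_prior(s2, 10)
        b = diffstats.estimate_prior(rng.permutation(s2), 10)
        assert a.d0 == pytest.approx(b.d0, rel=1e-12)
        assert a.s0_sq == pytest.approx(b.s0_sq, rel=1e-12)

    def test_trigamma_inverse_is_an_inverse(self):
        from scipy.special import polygamma

        for y in (1e-5, 0.01, 0.5, 2.0, 1e4):
            x = diffstats.trigamma_inverse(y)
            assert float(polygamma(1, x)) == pytest.approx(y, rel=1e-6)


class TestModeratedT:
    def _fixture(self, rng, n=30):
        design = _one_strain_design()
        X = diffstats.build_design_matrix(design)
        y = pd.DataFrame(
            rng.normal(20, 1, size=(n, 6)), columns=design["run_id"]
        )
        y.iloc[: n // 2, :3] += rng.normal(1.0, 0.2, size=(n // 2, 3))
        fit = diffstats.fit_linear_model(y, X)
        c = diffstats.contrast_vector(X.columns, "wt_as")
        return y, fit, c

    def test_d0_zero_reduces_to_classical_two_sample_t(self, rng):
        y, fit, c = self._fixture(rng)
        prior = diffstats.EBayesPrior(d0=0.0, s0_sq=1.0)
        res = diffstats.moderated_t(fit, prior, c)
        for i in range(len(y)):
            t_cls, p_cls = stats.ttest_ind(
                y.iloc[i, :3], y.iloc[i, 3:], equal_var=True
            )
            assert res["t_mod"][i] == pytest.approx(t_cls, abs=1e-10)
            assert res["p"][i] == pytest.approx(p_cls, abs=1e-10)

    def test_d0_infinite_is_fixed_variance_z(self, rng):
        y, fit, c = self._fixture(rng)
        s0 = float(fit.s2.mean())
        prior = diffstats.EBayesPrior(d0=float("inf"), s0_sq=s0)
        res = diffstats.moderated_t(fit, prior, c)
        se = np.sqrt(s0 * (1 / 3 + 1 / 3))
        z = res["logFC"].to_numpy() / se
        np.testing.assert_allclose(res["t_mod"], z, atol=1e-10)
        np.testing.assert_allclose(
            res["p"], 2 * stats.norm.sf(np.abs(z)), atol=1e-12
        )

    def test_zero_logfc_gives_t_zero_p_one(self):
        design = _one_strain_design()
        X = diffstats.build_design_matrix(design)
        y = pd.DataFrame([[5.0, 6, 7, 5, 6, 7]], columns=design["run_id"])
        fit = diffstats.fit_linear_model(y, X)
        c = diffstats.contrast_vector(X.columns, "wt_as")
        res = diffstats.moderated_t(
            fit, diffstats.EBayesPrior(4.0, 0.02), c
        )
        assert res["t_mod"][0] == pytest.approx(0.0, abs=1e-10)
        assert res["p"][0] == pytest.approx(1.0, abs=1e-10)
        assert res["FC"][0] == pytest.approx(1.0, abs=1e-12)

    def test_posterior_variance_formula(self, rng):
        y, fit, c = self._fixture(rng, n=10)
        prior = diffstats.EBayesPrior(d0=3.0, s0_sq=0.5)
        res = diffstats.moderated_t(fit, prior, c)
        d = fit.df_resid
        s2_post = (3.0 * 0.5 + d * fit.s2.to_numpy()) / (3.0 + d)
        se = np.sqrt(s2_post * (1 / 3 + 1 / 3))
        np.testing.assert_allclose(
            res["t_mod"], res["logFC"] / se, atol=1e-12
        )
        assert (res["df_total"] == d + 3.0).all()


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not on PATH")
class TestAgainstLimma:
    R_CODE = """
    suppressMessages(library(limma))
    args <- commandArgs(trailingOnly=TRUE)
    y <- as.matrix(read.delim(args[1], row.names=1, check.names=FALSE))
    X <- as.matrix(read.delim(args[2], row.names=1, check.names=FALSE))
    fit <- lmFit(y, X)
    cm <- matrix(0, ncol(X), 1)
    rownames(cm) <- colnames(X)
    cm["g_wt_as_drug", 1] <- 1
    cm["g_wt_as_mock", 1] <- -1
    fit2 <- contrasts.fit(fit, cm)
    eb <- eBayes(fit2)
    out <- data.frame(logFC=eb$coefficients[,1], t=eb$t[,1],
                      p=eb$p.value[,1], d0=eb$df.prior, s0=eb$s2.prior)
    write.table(out, args[3], sep="\\t", quote=FALSE)
    """

    def test_moderated_statistics_match_limma(self, tmp_path, rng):
        design = mq_io.make_design(strains=("wt_as",))
        X = diffstats.build_design_matrix(design)
        n = 100
        scale = rng.choice([0.3, 1.0, 3.0], size=(n, 1))
        y = pd.DataFrame(
            rng.normal(20, 1, size=(n, 6)) * scale,
            columns=design["run_id"],
            index=[f"p{i}" for i in range(n)],
        )
        y.iloc[:10, :3] += 1.0
        ypath, xpath, opath = (
            tmp_path / "y.tsv", tmp_path / "x.tsv", tmp_path / "out.tsv"
        )
        y.to_csv(ypath, sep="\t")
        X.to_csv(xpath, sep="\t")
        script = tmp_path / "limma_oracle.R"
        script.write_text(self.R_CODE)
        subprocess.run(
            ["Rscript", "--vanilla", str(script), str(ypath), str(xpath),
             str(opath)],
            check=True, capture_output=True,
        )
        ref = pd.read_csv(opath, sep="\t")
        fit = diffstats.fit_linear_model(y, X)
        prior = diffstats.estimate_prior(fit.s2.to_numpy(), fit.df_resid)
        c = diffstats.contrast_vector(X.columns, "wt_as")
        res = diffstats.moderated_t(fit, prior, c)
        assert np.isfinite(prior.d0)
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert prior.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(res["logFC"], ref["logFC"], rtol=1e-8)
        np.testing.assert_allclose(res["t_mod"], ref["t"], rtol=1e-4)
        np.testing.assert_allclose(res["p"], ref["p"], rtol=1e-4)


class TestBHAdjust:
    @staticmethod
    def _brute_force(p):
        p = np.asarray(p, dtype=float)
        n = len(p)
        adj = np.empty(n)
        for i in range(n):
            rank = (p <= p[i]).sum()
            candidates = [
                p[j] * n / (p <= p[j]).sum()
                for j in range(n)
                if p[j] >= p[i]
            ]
            adj[i] = min(1.0, min(candidates))
        return adj

    def test_worked_example(self):
        out = diffstats.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert diffstats.bh_adjust([0.3]).tolist() == [0.3]
        assert diffstats.bh_adjust([1.0, 1.0]).tolist() == [1.0, 1.0]

    def test_matches_brute_force_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(5):
            p = rng.uniform(size=25)
            ours = diffstats.bh_adjust(p)
            np.testing.assert_allclose(ours, self._brute_force(p),
                                       atol=1e-12)
            _, sm, *_ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(ours, sm, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_properties(self, pvals):
        out = diffstats.bh_adjust(pvals)
        assert ((out >= np.asarray(pvals) - 1e-15) & (out <= 1.0)).all()
        order = np.argsort(pvals)
        assert (np.diff(out[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            diffstats.bh_adjust([0.5, 1.5])
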