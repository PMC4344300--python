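"""Beta/M transforms and per-CpG linear models."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from telomethyl.cpg_association import (
    MethylationMatrix,
    beta_from_m,
    beta_values,
    fit_cpg_associations,
    m_values,
)
from telomethyl.synthetic_data import SimulationConfig, simulate_study


class TestTransforms:
    def test_beta_examples(self):
        assert beta_values(100.0, 100.0) == pytest.approx(0.5)
        assert beta_values(300.0, 100.0) == pytest.approx(0.75)

    def test_beta_matches_direct_ratio(self, rng):
        m = rng.uniform(0, 5000, size=200)
        u = rng.uniform(1, 5000, size=200)
        np.testing.assert_allclose(beta_values(m, u), m / (m + u), atol=2e-6)

    def test_beta_zero_total_is_missing(self):
        out = beta_values(np.array([0.0, 10.0]), np.array([0.0, 10.0]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(0.5)

    def test_beta_clamped_inside_unit_interval(self):
        out = beta_values(np.array([10.0, 0.0]), np.array([0.0, 10.0]))
        assert 0 < out[1] and out[0] < 1

    def test_m_value_examples(self):
        assert m_values(0.5) == pytest.approx(0.0)
        assert m_values(0.8) == pytest.approx(2.0)  # log2(4)

    def test_m_round_trip(self):
        grid = np.linspace(0.01, 0.99, 197)
        np.testing.assert_allclose(beta_from_m(m_values(grid)), grid, atol=1e-12)

    def test_extreme_beta_stays_finite(self):
        assert np.isfinite(m_values(0.0)) and np.isfinite(m_values(1.0))


def _single_cpg_matrix(values, sample_ids):
    return MethylationMatrix(
        values=pd.DataFrame([values], index=pd.Index(["cg1"], name="cpg_id"),
                            columns=sample_ids),
        coords=pd.DataFrame({"chrom": ["chr1"], "pos": [100]},
                            index=pd.Index(["cg1"], name="cpg_id")),
    )


class TestOls:
    def test_matches_hand_computed_ols_on_six_samples(self):
        # independent oracle: explicit normal equations + t formula
        ts = np.array([0.6, 0.8, 0.9, 1.1, 1.2, 1.5])
        y = np.array([1.0, 1.4, 1.3, 1.9, 2.1, 2.4])
        sample_ids = [f"s{i}" for i in range(6)]
        samples = pd.DataFrame({"ts_ratio": ts}, index=sample_ids)
        out = fit_cpg_associations(
            _single_cpg_matrix(y, sample_ids), samples, moderate_variance=False
        )
        X = np.column_stack([np.ones(6), ts])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / 4
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        t_stat = beta[1] / se
        assert out.loc["cg1", "slope"] == pytest.approx(beta[1], rel=1e-12)
        assert out.loc["cg1", "t"] == pytest.approx(t_stat, rel=1e-12)
        assert out.loc["cg1", "p_value"] == pytest.approx(
            2 * stats.t.sf(abs(t_stat), 4), rel=1e-12
        )

    def test_near_noiseless_signal(self, rng):
        ts = rng.normal(1.0, 0.3, size=12)
        y = 0.5 + 2.0 * ts + rng.normal(0, 1e-6, size=12)
        sample_ids = [f"s{i}" for i in range(12)]
        samples = pd.DataFrame({"ts_ratio": ts}, index=sample_ids)
        out = fit_cpg_associations(
            _single_cpg_matrix(y, sample_ids), samples, moderate_variance=False
        )
        assert out.loc["cg1", "p_value"] < 1e-10
        assert out.loc["cg1", "slope"] > 0

    def test_exact_linear_cpg_has_undefined_t(self):
        ts = np.linspace(0.5, 1.5, 10)
        sample_ids = [f"s{i}" for i in range(10)]
        samples = pd.DataFrame({"ts_ratio": ts}, index=sample_ids)
        out = fit_cpg_associations(
            _single_cpg_matrix(1.0 + 2.0 * ts, sample_ids), samples,
            moderate_variance=False,
        )
        assert np.isnan(out.loc["cg1", "t"]) and np.isnan(out.loc["cg1", "p_value"])
        assert out.loc["cg1", "slope"] == pytest.approx(2.0)

    def test_sign_equivariance(self, small_study):
        _, _, _, samples, matrix, _ = small_study
        flipped = samples.copy()
        flipped["ts_ratio"] = -flipped["ts_ratio"]
        a = fit_cpg_associations(matrix, samples, moderate_variance=False)
        b = fit_cpg_associations(matrix, flipped, moderate_variance=False)
        np.testing.assert_allclose(b["slope"], -a["slope"], rtol=1e-9)
        np.testing.assert_allclose(b["t"], -a["t"], rtol=1e-9)
        np.testing.assert_allclose(b["p_value"], a["p_value"], rtol=1e-9)

    def test_orthogonal_covariate_rescales_t_by_df_only(self, rng):
        n = 12
        ts = rng.normal(1.0, 0.3, size=n)
        y = 0.3 + 1.5 * ts + rng.normal(0, 0.5, size=n)
        # Gram-Schmidt a covariate orthogonal to [1, ts] and to y
        z = rng.normal(size=n)
        basis = np.column_stack([np.ones(n), ts, y])
        z -= basis @ np.linalg.lstsq(basis, z, rcond=None)[0]
        sample_ids = [f"s{i}" for i in range(n)]
        base = fit_cpg_associations(
            _single_cpg_matrix(y, sample_ids),
            pd.DataFrame({"ts_ratio": ts}, index=sample_ids),
            moderate_variance=False,
        )
        with_cov = fit_cpg_associations(
            _single_cpg_matrix(y, sample_ids),
            pd.DataFrame({"ts_ratio": ts, "z": z}, index=sample_ids),
            moderate_variance=False,
        )
        assert with_cov.loc["cg1", "slope"] == pytest.approx(
            base.loc["cg1", "slope"], rel=1e-9
        )
        # RSS unchanged but residual df drops by one, inflating s^2:
        # t scales by sqrt((n-3)/(n-2))
        factor = np.sqrt((n - 3) / (n - 2))
        assert with_cov.loc["cg1", "t"] == pytest.approx(
            base.loc["cg1", "t"] * factor, rel=1e-9
        )

    def test_rank_deficient_design_names_columns(self, rng):
        n = 10
        ts = rng.normal(1.0, 0.3, size=n)
        sample_ids = [f"s{i}" for i in range(n)]
        samples = pd.DataFrame(
            {"ts_ratio": ts, "dup": 2 * ts}, index=sample_ids
        )
        with pytest.raises(ValueError, match="rank deficient"):
            fit_cpg_associations(
                _single_cpg_matrix(rng.normal(size=n), sample_ids), samples
            )

    def test_too_few_samples_rejected(self, rng):
        sample_ids = ["a", "b", "c"]
        samples = pd.DataFrame({"ts_ratio": [0.8, 1.0, 1.2]}, index=sample_ids)
        with pytest.raises(ValueError, match="n_samples"):
            fit_cpg_associations(
                _single_cpg_matrix([1.0, 2.0, 3.0], sample_ids), samples
            )


class TestModeration:
    def test_global_null_p_values_uniform(self):
        cfg = SimulationConfig(seed=7, fraction_planted_genes=0.0,
                               n_genes=1250, cpgs_per_gene_fixed=True)
        _, _, _, samples, matrix, _ = simulate_study(cfg)
        assert len(matrix.cpg_ids) == 10_000
        for moderate in (False, True):
            assoc = fit_cpg_associations(matrix, samples, moderate_variance=moderate)
            ks = stats.kstest(assoc["p_value"].dropna(), "uniform")
            assert ks.pvalue > 0.01

    def test_moderated_t_matches_limma(self, small_study, tmp_path):
        # limma's eBayes is the independent reference for the shrinkage
        _, _, _, samples, matrix, _ = small_study
        ours = fit_cpg_associations(matrix, samples, moderate_variance=True)
        matrix.values.to_csv(tmp_path / "M.tsv", sep="\t")
        pd.DataFrame(
            {"intercept": 1.0, "ts_ratio": samples["ts_ratio"]}, index=samples.index
        ).to_csv(tmp_path / "design.tsv", sep="\t")
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            'args <- commandArgs(trailingOnly=TRUE)\n'
            'M <- as.matrix(read.delim(args[1], row.names=1))\n'
            'design <- as.matrix(read.delim(args[2], row.names=1))\n'
            'fit <- eBayes(lmFit(M, design))\n'
            'out <- data.frame(t=fit$t[, "ts_ratio"], p=fit$p.value[, "ts_ratio"])\n'
            'write.table(out, args[3], sep="\\t", quote=FALSE)\n'
        )
        subprocess.run(
            ["Rscript", str(script), str(tmp_path / "M.tsv"),
             str(tmp_path / "design.tsv"), str(tmp_path / "out.tsv")],
            check=True, capture_output=True,
        )
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
        # same method-of-moments family; tiny differences in the prior fit
        assert np.abs(ref["t"] - ours["t"]).max() < 0.02
        rho = stats.spearmanr(ref["t"], ours["t"]).statistic
        assert rho > 0.99999

    def test_moderation_off_is_plain_ols(self, small_study):
        _, _, _, samples, matrix, _ = small_study
        plain = fit_cpg_associations(matrix, samples, moderate_variance=False)
        # spot-check one CpG against statsmodels-free manual OLS
        ts = samples["ts_ratio"].to_numpy()
        X = np.column_stack([np.ones(len(ts)), ts])
        cpg = matrix.cpg_ids[5]
        y = matrix.values.loc[cpg].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (len(ts) - 2)
        t_stat = beta[1] / np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert plain.loc[cpg, "t"] == pytest.approx(t_stat, rel=1e-10)
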