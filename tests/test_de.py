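import numpy as np
import pandas as pd
import pytest
from scipy import stats

from p53targets import de
from p53targets.de import (
    EBayesHyperparams,
    bh_adjust,
    de_posterior,
    estimate_prior_variance,
    fit_contrast,
    moderate,
    moderated_t,
    quantile_normalize,
    select_de_genes,
)
from oracles import bh_oracle, pooled_t_oracle


class TestQuantileNormalize:
    def test_mean_of_order_statistics(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        assert np.allclose(out["a"], [2.5, 3.5, 4.5])
        assert np.allclose(out["b"], [2.5, 3.5, 4.5])

    def test_identical_columns_fixed_point(self, rng):
        col = rng.normal(size=50)
        m = pd.DataFrame({"a": col, "b": col.copy()})
        assert np.allclose(quantile_normalize(m), m)

    def test_idempotent_and_columns_identical_sorted(self, rng):
        m = pd.DataFrame(rng.normal(size=(200, 4)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        assert np.allclose(once, twice)
        ref = np.sort(once.to_numpy()[:, 0])
        for j in range(4):
            assert np.allclose(np.sort(once.to_numpy()[:, j]), ref)

    def test_nonfinite_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError):
            quantile_normalize(m)


class TestFitContrast:
    def test_constant_groups(self):
        m = pd.DataFrame([[1.0, 1, 1, 2, 2, 2]], index=["p1"])
        out = fit_contrast(m, ["vector"] * 3 + ["sh"] * 3)
        assert out.loc["p1", "log2fc"] == 1.0
        assert out.loc["p1", "s2"] == 0.0
        assert out.loc["p1", "df"] == 4

    def test_equal_arms_zero_contrast(self, rng):
        vals = rng.normal(size=(5, 3))
        m = pd.DataFrame(np.hstack([vals, vals]))
        out = fit_contrast(m, ["vector"] * 3 + ["sh"] * 3)
        assert np.allclose(out["log2fc"], 0)

    def test_matches_pooled_oracle(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 6)))
        labels = ["sh"] * 3 + ["vector"] * 3
        out = fit_contrast(m, labels)
        for i in range(50):
            x, y = m.iloc[i, :3].to_numpy(), m.iloc[i, 3:].to_numpy()
            fc, s2, _ = pooled_t_oracle(x, y)
            assert np.isclose(out["log2fc"].iloc[i], fc)
            assert np.isclose(out["s2"].iloc[i], s2)

    def test_small_arm_rejected(self):
        m = pd.DataFrame(np.ones((3, 3)))
        with pytest.raises(ValueError):
            fit_contrast(m, ["vector", "sh", "sh"])


class TestModerate:
    def test_no_shrinkage_limit(self, rng):
        s2 = rng.chisquare(4, 100) / 4
        post, df_tot, _ = moderate(s2, 4, EBayesHyperparams(d0=1e-12, s0sq=1.0))
        assert np.allclose(post, s2)
        assert np.isclose(df_tot, 4)

    def test_full_shrinkage_limit(self, rng):
        s2 = rng.chisquare(4, 100) / 4
        post, _, _ = moderate(s2, 4, EBayesHyperparams(d0=1e12, s0sq=0.05))
        assert np.allclose(post, 0.05, atol=1e-6)

    def test_hyperparameter_recovery(self):
        """Moment estimator recovers planted (d0=4, s0sq=0.05) on scaled-F draws."""
        rng = np.random.default_rng(20150319)
        d0_true, s0sq_true, df, n = 4.0, 0.05, 4, 5000
        sigma2 = s0sq_true * d0_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        d0_hat, s0sq_hat = estimate_prior_variance(s2, df)
        assert abs(d0_hat - d0_true) / d0_true < 0.2
        assert abs(s0sq_hat - s0sq_true) / s0sq_true < 0.1

    def test_all_zero_variances_actionable_error(self):
        with pytest.raises(ValueError, match="constant or duplicated"):
            estimate_prior_variance(np.zeros(10), 4)

    def test_homoscedastic_data_reports_large_d0(self, rng):
        s2 = np.full(5000, 0.09) * rng.chisquare(4, 5000) / 4
        d0_hat, s0sq_hat = estimate_prior_variance(s2, 4)
        # no real excess spread beyond chi-square sampling noise: the prior df
        # should dwarf the per-gene df, i.e. shrinkage is nearly total
        assert d0_hat > 10 * 4
        assert 0.05 < s0sq_hat < 0.15


class TestModeratedT:
    def test_zero_fc(self):
        t, p = moderated_t(np.array([0.0]), np.array([0.5]), 3, 3, 10)
        assert t[0] == 0 and p[0] == 1

    def test_classical_t_with_degenerate_prior(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=5)
        fc, s2, t_ref = pooled_t_oracle(x, y)
        post, df_tot, _ = moderate(np.array([s2]), 8, EBayesHyperparams(d0=1e-300, s0sq=1.0))
        t, p = moderated_t(np.array([fc]), post, 5, 5, df_tot)
        assert abs(t[0] - t_ref) < 1e-10
        p_ref = 2 * stats.t.sf(abs(t_ref), 8)
        assert abs(p[0] - p_ref) < 1e-10

    def test_linearity_in_fc(self):
        t1, _ = moderated_t(np.array([1.0]), np.array([0.4]), 3, 3, 10)
        t2, _ = moderated_t(np.array([2.0]), np.array([0.4]), 3, 3, 10)
        assert np.isclose(t2, 2 * t1)

    def test_zero_variance_limit(self):
        t, p = moderated_t(np.array([1.0]), np.array([0.0]), 3, 3, 10)
        assert np.isinf(t[0]) and t[0] > 0
        assert p[0] == np.finfo(float).tiny


class TestBHAdjust:
    def test_stepup_by_hand(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust(np.array([0.2]))[0] == 0.2
        assert np.all(bh_adjust(np.ones(5)) == 1.0)

    def test_matches_oracle_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), bh_oracle(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


class TestDEPosterior:
    def test_null_favoring_at_zero(self):
        assert de_posterior(np.array([0.0]), 10, p0=0.01)[0] < 0.5

    def test_monotone_in_abs_t(self):
        grid = np.linspace(0, 12, 60)
        pde = de_posterior(grid, 10)
        assert np.all(np.diff(pde) > 0)
        assert np.allclose(de_posterior(-grid, 10), pde)

    def test_synthetic_default_separation(self, default_result):
        """Planted responsive genes get high pDE, nulls get low pDE."""
        truth = default_result.truth.table
        tbl = default_result.de_table
        resp = truth.loc[tbl.index, "responsive"].to_numpy()
        assert np.median(tbl["pDE"].to_numpy()[resp]) > 0.9
        assert np.median(tbl["pDE"].to_numpy()[~resp]) < 0.1

    def test_calibration_monotone_over_deciles(self, default_result):
        truth = default_result.truth.table
        tbl = default_result.de_table
        resp = truth.loc[tbl.index, "responsive"].to_numpy().astype(float)
        deciles = pd.qcut(tbl["pDE"].rank(method="first"), 10, labels=False)
        frac = pd.Series(resp).groupby(deciles.to_numpy()).mean()
        # top deciles strictly richer in true responders than bottom ones
        assert frac.iloc[-1] > 0.9
        assert frac.iloc[0] < 0.05
        assert (frac.rolling(3).mean().dropna().diff().dropna() >= -0.05).all()


class TestSelectDEGenes:
    def test_rule_application(self):
        tbl = pd.DataFrame(
            {
                "q": [0.005, 0.02, 0.005, 0.001, 0.5, 0.009],
                "log2fc": [0.5, 2.0, -1.2, 0.6, 3.0, -0.58],
            },
            index=[f"p{i}" for i in range(6)],
        )
        got = set(select_de_genes(tbl))
        # p0 fails lfc, p1 fails q, p5 fails strict |lfc| > 0.58
        assert got == {"p2", "p3"}

    def test_null_fdr_controlled(self):
        """Global null: realized FDR of the q<0.01 & |lfc| rule stays tiny."""
        rng = np.random.default_rng(5)
        false_rates = []
        for _ in range(200):
            m = pd.DataFrame(rng.normal(8.0, 0.3, size=(400, 6)))
            vec, sh = m.iloc[:, :3], m.iloc[:, 3:]
            res = de.run_de(vec, sh, normalize=False)
            n_called = len(select_de_genes(res))
            false_rates.append(n_called / max(n_called, 1) if n_called else 0.0)
        assert np.mean(false_rates) <= 0.02
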