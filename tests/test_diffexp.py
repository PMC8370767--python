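import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mesreg.diffexp import (
    DesignInfo,
    bh_adjust,
    eb_moderate,
    fit_gene_models,
    make_signature,
    moderated_test,
)


def _design(n_per_group=6, batches=("B1",), mes="MES"):
    samples, group, batch = [], [], []
    i = 0
    for g in (mes, "nonMES"):
        for j in range(n_per_group):
            samples.append(f"s{i}")
            group.append(g)
            batch.append(batches[i % len(batches)])
            i += 1
    idx = pd.Index(samples)
    return DesignInfo(group=pd.Series(group, index=idx), batch=pd.Series(batch, index=idx))


class TestFitGeneModels:
    def test_zero_effect_when_group_means_equal(self):
        design = _design(4)
        row = np.array([1.0, 2.0, 3.0, 4.0, 4.0, 3.0, 2.0, 1.0])
        values = pd.DataFrame([row], index=["g1"], columns=design.group.index)
        fits = fit_gene_models(values, design)
        assert fits.loc["g1", "effect"] == pytest.approx(0.0, abs=1e-12)

    def test_single_batch_effect_is_difference_of_group_means(self, rng):
        design = _design(5)
        values = pd.DataFrame(
            rng.normal(size=(10, 10)), index=[f"g{i}" for i in range(10)],
            columns=design.group.index,
        )
        fits = fit_gene_models(values, design)
        mes = design.group == "MES"
        diff = values.loc[:, mes.to_numpy()].mean(axis=1) - values.loc[:, (~mes).to_numpy()].mean(axis=1)
        np.testing.assert_allclose(fits["effect"], diff, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        """20 genes, 12 samples, 2 batches: coefficients from an explicit
        (X'X)^-1 X'y solve must agree to 1e-8."""
        design = _design(6, batches=("B1", "B2"))
        values = pd.DataFrame(
            rng.normal(size=(20, 12)), index=[f"g{i}" for i in range(20)],
            columns=design.group.index,
        )
        fits = fit_gene_models(values, design)
        x = design.design_matrix().to_numpy()
        gi = list(design.design_matrix().columns).index("group")
        for g in values.index:
            y = values.loc[g].to_numpy()
            beta = np.linalg.solve(x.T @ x, x.T @ y)
            assert fits.loc[g, "effect"] == pytest.approx(beta[gi], abs=1e-8)

    def test_batch_shift_absorbed_by_batch_indicators(self, rng):
        design = _design(6, batches=("B1", "B2"))
        values = pd.DataFrame(
            rng.normal(size=(15, 12)), index=[f"g{i}" for i in range(15)],
            columns=design.group.index,
        )
        base = fit_gene_models(values, design)
        shifted = values.copy()
        b2 = (design.batch == "B2").to_numpy()
        shifted.loc[:, b2] += 3.5
        after = fit_gene_models(shifted, design)
        np.testing.assert_allclose(base["effect"], after["effect"], atol=1e-8)

    def test_rank_deficient_design_names_aliased_columns(self):
        samples = pd.Index([f"s{i}" for i in range(8)])
        group = pd.Series(["MES"] * 4 + ["nonMES"] * 4, index=samples)
        batch = pd.Series(["B1"] * 4 + ["B2"] * 4, index=samples)  # batch == group
        design = DesignInfo(group=group, batch=batch)
        with pytest.raises(ValueError, match="aliased.*batch_B2"):
            design.design_matrix()


class TestEbModerate:
    def test_identical_variances_hit_infinite_prior_branch(self):
        s2 = np.full(50, 2.5)
        d0, s0sq, post = eb_moderate(s2, df_resid=8)
        assert np.isinf(d0)
        assert s0sq == pytest.approx(2.5)
        np.testing.assert_allclose(post, 2.5)

    def test_prior_recovery_from_scaled_f_simulation(self):
        """s2 ~ s0^2 * (chi2_df/df) / (chi2_d0/d0) with d0=4, s0^2=1."""
        rng = np.random.default_rng(11)
        n_genes, df, d0_true, s0sq_true = 5000, 10, 4.0, 1.0
        s2 = (
            s0sq_true
            * (rng.chisquare(df, n_genes) / df)
            / (rng.chisquare(d0_true, n_genes) / d0_true)
        )
        d0, s0sq, _ = eb_moderate(s2, df_resid=df)
        assert 2.5 <= d0 <= 6.0
        assert 0.8 <= s0sq <= 1.25

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            eb_moderate(np.array([1.0] * 20 + [0.0]), df_resid=5)


class TestModeratedTest:
    def test_zero_effect_gives_zero_t_and_unit_p(self, rng):
        design = _design(4)
        values = pd.DataFrame(
            rng.normal(size=(20, 8)), index=[f"g{i}" for i in range(20)],
            columns=design.group.index,
        )
        fits = fit_gene_models(values, design)
        fits.loc["g0", "effect"] = 0.0
        res = moderated_test(fits, design)
        assert res.loc["g0", "t_mod"] == 0.0
        assert res.loc["g0", "p"] == pytest.approx(1.0)

    def test_no_shrinkage_matches_classical_t_test(self, rng):
        """With d0 forced to 0 the moderated p must equal the textbook
        two-sample-with-covariates t-test p to 1e-8 (statsmodels OLS)."""
        import statsmodels.api as sm

        design = _design(6, batches=("B1", "B2"))
        values = pd.DataFrame(
            rng.normal(size=(12, 12)), index=[f"g{i}" for i in range(12)],
            columns=design.group.index,
        )
        fits = fit_gene_models(values, design)
        res = moderated_test(fits, design, no_shrinkage=True)
        x = design.design_matrix()
        for g in values.index:
            fit = sm.OLS(values.loc[g].to_numpy(), x.to_numpy()).fit()
            assert res.loc[g, "p"] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_moderated_p_interpolates_between_t_and_normal(self, rng):
        design = _design(5)
        values = pd.DataFrame(
            rng.normal(size=(30, 10)), index=[f"g{i}" for i in range(30)],
            columns=design.group.index,
        )
        fits = fit_gene_models(values, design)
        res0 = moderated_test(fits, design, no_shrinkage=True)
        df = float(fits["df_resid"].iloc[0])
        np.testing.assert_allclose(
            res0["p"], 2 * stats.t.sf(np.abs(res0["t_mod"]), df), atol=1e-12
        )
        # identical s2 across genes drives d0 to infinity: normal-theory p
        flat = fits.copy()
        flat["s2"] = 1.7
        res_inf = moderated_test(flat, design)
        assert np.isinf(res_inf.attrs["d0"])
        np.testing.assert_allclose(
            res_inf["p"], 2 * stats.norm.sf(np.abs(res_inf["t_mod"])), atol=1e-12
        )

    def test_q_dominates_p_and_is_monotone(self, rng):
        design = _design(5)
        values = pd.DataFrame(
            rng.normal(size=(40, 10)), index=[f"g{i}" for i in range(40)],
            columns=design.group.index,
        )
        res = moderated_test(fit_gene_models(values, design), design)
        assert (res["q"] >= res["p"] - 1e-15).all()
        srt = res.sort_values("p")
        assert (np.diff(srt["q"]) >= -1e-15).all()


def test_bh_hand_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


class TestMakeSignature:
    def test_all_insignificant_gives_empty_lists(self, rng):
        res = pd.DataFrame(
            {"effect": rng.normal(size=10), "t_mod": rng.normal(size=10),
             "p": np.ones(10), "q": np.ones(10)},
            index=[f"g{i}" for i in range(10)],
        )
        with pytest.warns(UserWarning, match="no genes"):
            up, down, top = make_signature(res)
        assert up == [] and down == []

    def test_planted_up_genes_recovered(self, rng):
        design = _design(30)
        values = pd.DataFrame(
            rng.normal(size=(500, 60)), index=[f"g{i:03d}" for i in range(500)],
            columns=design.group.index,
        )
        planted = [f"g{i:03d}" for i in range(50)]
        values.loc[planted, (design.group == "MES").to_numpy()] += 2.0
        res = moderated_test(fit_gene_models(values, design), design)
        up, down, _ = make_signature(res, q_threshold=0.05)
        assert set(planted) <= set(up)

    def test_top_n_covering_all_genes_orders_by_q(self, rng):
        design = _design(4)
        values = pd.DataFrame(
            rng.normal(size=(15, 8)), index=[f"g{i}" for i in range(15)],
            columns=design.group.index,
        )
        res = moderated_test(fit_gene_models(values, design), design)
        _, _, top = make_signature(res, top_n=15)
        assert len(top) == 15
        qs = res.loc[top, "q"].to_numpy()
        assert (np.diff(qs) >= -1e-15).all()
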