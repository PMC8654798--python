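"""Interaction-model fitting, ORM-PCs, variance decomposition, SNP scans."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poemod.errors import ConfigurationError, DataError, RankDeficiencyError
from poemod.scan import (
    TrioSpec,
    _ols,
    build_orm_pcs,
    conditional_interaction_fit,
    fit_poe_model,
    poe_by_snp_scan,
    variance_decomposition,
)
from poemod.synthio import ModifierSpec

from conftest import make_cohort


def normal_equations_oracle(X, y):
    """Textbook (X'X)^-1 X'y with classical SEs — the independent path."""
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta, se, t, p


class TestOlsCore:
    def test_matches_normal_equations_on_random_designs(self, rng):
        """OLS estimates, SEs, t and p equal the explicit normal-equations
        oracle on 100 random small designs."""
        for _ in range(100):
            n = int(rng.integers(15, 25))
            p = int(rng.integers(2, 6))
            X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
            y = rng.standard_normal(n)
            names = [f"c{j}" for j in range(p)]
            terms, resid, r2 = _ols(X, y, names)
            b, se, t, pv = normal_equations_oracle(X, y)
            np.testing.assert_allclose(terms["estimate"], b, rtol=1e-9)
            np.testing.assert_allclose(terms["se"], se, rtol=1e-9)
            np.testing.assert_allclose(terms["t"], t, rtol=1e-9)
            np.testing.assert_allclose(terms["p"], pv, rtol=1e-8, atol=1e-300)

    def test_rank_deficiency_names_columns(self, rng):
        X = rng.standard_normal((30, 3))
        X = np.column_stack([X, X[:, 1]])
        with pytest.raises(RankDeficiencyError) as exc:
            _ols(X, rng.standard_normal(30), ["a", "b", "c", "b_copy"])
        assert set(exc.value.columns) & {"b", "b_copy"}


class TestFitPoeModel:
    def test_noise_free_recovery(self, trio):
        """With vanishing noise the generative coefficients are recovered to
        high precision."""
        data, cfg = make_cohort(seed=17, n_families=900, noise_sd=1e-8,
                                interaction_beta=0.3, trio_fraction=1.0)
        fit = fit_poe_model(trio, data)
        assert fit.estimate("Add") == pytest.approx(cfg.beta_add, abs=1e-6)
        assert fit.estimate("POE") == pytest.approx(cfg.beta_poe, abs=1e-6)
        assert fit.estimate("POE:Mod") == pytest.approx(0.3, abs=1e-6)
        assert fit.estimate("Mod") == pytest.approx(0.2, abs=1e-6)
        assert fit.r2_full > 0.999

    def test_modifier_duplicated_as_covariate_raises(self, cohort, trio):
        covs = cohort.covariates.drop(columns=["cell3"]).copy()
        covs["mod_copy"] = cohort.modifiers["mod"] - cohort.modifiers["mod"].mean()
        with pytest.raises(RankDeficiencyError):
            fit_poe_model(trio, cohort, covariates=covs)

    def test_zero_variance_modifier_rejected(self, cohort):
        bad = TrioSpec(mqtl="rs00000", cpg="cg00000", modifier="flat")
        cohort.modifiers["flat"] = 1.0
        try:
            with pytest.raises(DataError, match="zero variance"):
                fit_poe_model(bad, cohort)
        finally:
            cohort.modifiers.drop(columns="flat", inplace=True)

    def test_smoking_dropped_when_it_is_the_modifier(self, cohort):
        trio_smoke = TrioSpec(mqtl="rs00000", cpg="cg00000", modifier="smoking")
        fit = fit_poe_model(trio_smoke, cohort)
        assert "smoking" not in fit.terms.index or "Mod" in fit.terms.index
        # the smoking covariate column must not appear alongside Mod
        assert list(fit.terms.index).count("smoking") == 0

    def test_dom_interaction_behind_flag(self, cohort, trio):
        fit = fit_poe_model(trio, cohort)
        assert "Dom:Mod" not in fit.terms.index
        fit2 = fit_poe_model(trio, cohort, include_dom_interaction=True)
        assert "Dom:Mod" in fit2.terms.index


class TestVarianceDecomposition:
    def test_increments_sum_identity(self, cohort, trio):
        """Sequential increments sum to r2_full - r2_base to 1e-10."""
        dec = variance_decomposition(trio, cohort)
        total = sum(dec["increments"].values())
        assert total == pytest.approx(dec["r2_full"] - dec["r2_base"], abs=1e-10)

    def test_null_interaction_increment_near_zero(self):
        data, _ = make_cohort(seed=23, n_families=1500, interaction_beta=0.0)
        dec = variance_decomposition(
            TrioSpec(mqtl="rs00000", cpg="cg00000", modifier="mod"), data
        )
        # expected increment under the null ~ 1/n
        assert dec["increments"]["POE:Mod"] < 5.0 / dec["n_used"]

    def test_orthogonal_predictors_increments_equal_marginal_r2(self, cohort, trio):
        """When predictor columns are mutually orthogonal, sequential
        increments equal each column's marginal R^2 (analytic identity),
        checked by comparing against single-column fits on residualized
        data."""
        from poemod.scan import build_design

        design = build_design(trio, cohort)
        y = design.y.to_numpy()
        y = y - y.mean()
        rng = np.random.default_rng(0)
        n = len(y)
        # construct an orthonormal basis to play the role of the terms
        Q, _ = np.linalg.qr(rng.standard_normal((n, 4)))
        tss = float(y @ y)
        prev_rss = tss
        for j in range(4):
            Xj = Q[:, : j + 1]
            beta = np.linalg.lstsq(Xj, y, rcond=None)[0]
            rss = float(((y - Xj @ beta) ** 2).sum())
            increment = (prev_rss - rss) / tss
            marginal = float((Q[:, j] @ y) ** 2) / tss
            assert increment == pytest.approx(marginal, abs=1e-12)
            prev_rss = rss

    def test_block_order_configurable(self, cohort, trio):
        dec = variance_decomposition(
            trio, cohort, block_order=("base", "POE", "Mod", "Add", "Dom",
                                       "Add:Mod", "POE:Mod")
        )
        assert set(dec["increments"]) == {"POE", "Mod", "Add", "Dom",
                                          "Add:Mod", "POE:Mod"}


class TestOrmPcs:
    def test_eigenvalues_match_dense_oracle(self, rng):
        """ORM eigenvalues on a 10x4 toy matrix match a brute-force
        eigendecomposition of W W'/p."""
        meth = pd.DataFrame(rng.standard_normal((10, 4)),
                            index=[f"i{k}" for k in range(10)])
        W = meth.to_numpy()
        W = (W - W.mean(0)) / W.std(0)
        expected = np.linalg.eigvalsh(W @ W.T / 4)[::-1]
        pcs = build_orm_pcs(meth, n_pcs=10, gwas_alpha=0.0)
        got = (pcs.to_numpy() ** 2).sum(axis=0)  # scores scaled by sqrt(eval)
        np.testing.assert_allclose(got, expected[: pcs.shape[1]], atol=1e-8)

    def test_snp_associated_pc_excluded(self, rng):
        """A PC constructed to equal a SNP dosage is removed by the GWAS
        screen."""
        n = 400
        snp = rng.binomial(2, 0.3, n).astype(float)
        # probes dominated by the SNP -> leading PC tracks the SNP
        probes = np.outer(snp, rng.standard_normal(6) * 3)
        probes += rng.standard_normal((n, 6)) * 0.1
        meth = pd.DataFrame(probes, index=[f"i{k}" for k in range(n)])
        dosages = pd.DataFrame({"snp": snp}, index=meth.index)
        with_screen = build_orm_pcs(meth, dosages, n_pcs=3, gwas_alpha=5e-8)
        without = build_orm_pcs(meth, None, n_pcs=3)
        assert with_screen.shape[1] < without.shape[1]
        assert "ORM_PC1" not in with_screen.columns

    def test_constant_probe_dropped_with_warning(self, rng):
        meth = pd.DataFrame(rng.standard_normal((12, 3)))
        meth[3] = 2.5
        with pytest.warns(UserWarning, match="constant probes"):
            build_orm_pcs(meth, n_pcs=2)

    def test_single_probe_rejected(self):
        with pytest.raises(DataError):
            build_orm_pcs(pd.DataFrame({"p": [1.0, 2.0, 3.0]}))


class TestSnpLocalization:
    @pytest.fixture(scope="class")
    @staticmethod
    def score_cohort():
        data, _ = make_cohort(
            seed=29, n_families=900, trio_fraction=1.0,
            modifiers=[ModifierSpec(name="expr", kind="allele_score",
                                    n_score_snps=1, interaction_beta=1.0,
                                    target_cpg=0)],
        )
        return data

    def test_single_weight_snp_gives_same_t(self, score_cohort):
        """A modifier that is a scaled copy of one SNP's dosage yields the
        same POE x SNP t-statistic as the modifier fit (affine invariance)."""
        trio = TrioSpec(mqtl="rs00000", cpg="cg00000", modifier="expr",
                        modifier_kind="genetic")
        fit = fit_poe_model(trio, score_cohort)
        scan = poe_by_snp_scan(trio, ["expr_snp0"], score_cohort)
        assert scan.loc["expr_snp0", "t"] == pytest.approx(
            fit.terms.loc["POE:Mod", "t"], abs=1e-8
        )

    def test_bonferroni_over_snp_list(self, score_cohort, rng):
        trio = TrioSpec(mqtl="rs00000", cpg="cg00000", modifier="expr")
        # add four independent null SNPs
        for k in range(4):
            score_cohort.modifier_snps[f"null{k}"] = rng.binomial(
                2, 0.3, len(score_cohort.individuals)
            )
        scan = poe_by_snp_scan(
            trio, ["expr_snp0"] + [f"null{k}" for k in range(4)], score_cohort
        )
        assert len(scan) == 5
        np.testing.assert_allclose(
            scan["p_bonferroni"], np.minimum(scan["p"] * 5, 1.0)
        )

    def test_monomorphic_snp_skipped(self, score_cohort):
        score_cohort.modifier_snps["mono"] = 0
        trio = TrioSpec(mqtl="rs00000", cpg="cg00000", modifier="expr")
        with pytest.warns(UserWarning, match="monomorphic"):
            scan = poe_by_snp_scan(trio, ["mono", "expr_snp0"], score_cohort)
        assert list(scan.index) == ["expr_snp0"]

    def test_conditioning_on_score_snp_explains_interaction(self, score_cohort):
        """Conditioning on the single SNP behind the score makes POE x Mod
        exactly collinear -> reported as fully explained."""
        trio = TrioSpec(mqtl="rs00000", cpg="cg00000", modifier="expr")
        fit = conditional_interaction_fit(trio, ["expr_snp0"], score_cohort)
        assert fit.fully_explained

    def test_conditioning_on_irrelevant_snp_leaves_p(self, score_cohort, rng):
        trio = TrioSpec(mqtl="rs00000", cpg="cg00000", modifier="expr")
        score_cohort.modifier_snps["irrel"] = rng.binomial(
            2, 0.4, len(score_cohort.individuals)
        )
        plain = fit_poe_model(trio, score_cohort)
        cond = conditional_interaction_fit(trio, ["irrel"], score_cohort)
        assert not cond.fully_explained
        lp_plain = -np.log10(plain.p("POE:Mod"))
        lp_cond = -np.log10(cond.p("POE:Mod"))
        assert lp_cond == pytest.approx(lp_plain, rel=0.2, abs=0.5)

    def test_conditioning_on_mqtl_rejected(self, score_cohort):
        trio = TrioSpec(mqtl="rs00000", cpg="cg00000", modifier="expr")
        with pytest.raises(ConfigurationError):
            conditional_interaction_fit(trio, ["rs00000"], score_cohort)

    def test_partial_conditioning_attenuates(self):
        """Modifier from two SNPs: conditioning on one attenuates the
        interaction t relative to the unconditional fit."""
        data, _ = make_cohort(
            seed=37, n_families=1200, trio_fraction=1.0,
            modifiers=[ModifierSpec(name="expr", kind="allele_score",
                                    n_score_snps=2,
                                    target_variance_fraction=0.05,
                                    target_cpg=0)],
        )
        trio = TrioSpec(mqtl="rs00000", cpg="cg00000", modifier="expr")
        plain = fit_poe_model(trio, data)
        cond = conditional_interaction_fit(data=data, trio=trio,
                                           conditioning_snps=["expr_snp0"])
        assert abs(cond.terms.loc["POE:Mod", "t"]) < abs(
            plain.terms.loc["POE:Mod", "t"]
        )
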