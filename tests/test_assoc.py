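"""Logistic machinery: single fits, the batched GWAS, LRT and Nagelkerke R²."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest, norm

import statsmodels.api as sm

from omniprs.assoc import (
    fit_logistic,
    gwas,
    lrt,
    nagelkerke,
    orient_risk,
    pooled_design,
)
from omniprs.core import FitResult
from omniprs.syndata import simulate_cohort

from conftest import small_config


class TestFitLogistic:
    def test_contingency_table_odds_ratio(self):
        # cases: 30 exposed / 20 unexposed; controls: 10 exposed / 40 unexposed
        # contingency OR = (30*40)/(20*10) = 6.0; the logistic MLE on a single
        # binary predictor reproduces it exactly
        y = np.array([1] * 50 + [0] * 50)
        x = np.array([1] * 30 + [0] * 20 + [1] * 10 + [0] * 40)
        fit = fit_logistic(y, pd.DataFrame({"exposed": x}))
        assert np.exp(fit.params["exposed"]) == pytest.approx(6.0, rel=1e-6)
        assert fit.converged and not fit.flagged

    def test_intercept_only_closed_form(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        fit = fit_logistic(y, None)
        phat = 0.3
        expected = 10 * (phat * np.log(phat) + 0.7 * np.log(0.7))
        assert fit.llf == pytest.approx(expected, abs=1e-12)

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        X = pd.DataFrame({"x": rng.normal(size=200), "c": np.full(200, 5.0)})
        fit = fit_logistic(y, X)
        assert "c" in fit.dropped and "x" in fit.params.index

    def test_collinear_column_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = rng.integers(0, 2, 200)
        fit = fit_logistic(y, pd.DataFrame({"a": x, "b": 2 * x}))
        assert fit.dropped == ("b",)

    def test_perfect_separation_flagged_not_crashed(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(int)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.flagged
        assert np.all(np.abs(fit.params.to_numpy()) <= 30.0)

    def test_nonbinary_phenotype_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.array([0, 1, 2]), pd.DataFrame({"x": [1.0, 2, 3]}))


@pytest.fixture(scope="module")
def null_cohort():
    """Two studies with h²=0 and no drift: every SNP is null."""
    return simulate_cohort(
        small_config(seed=17, n_studies=2, cases_per_study=(150, 150),
                     controls_per_study=(150, 150), h2_liability=0.0,
                     study_drift_f=0.0, n_snps=500, n_genes=100)
    )


class TestGwas:
    def test_matches_statsmodels_per_snp(self, small_cohort):
        studies = small_cohort.studies[:3]
        stats = gwas(studies)
        y, cov, G = pooled_design(studies)
        X0 = cov.to_numpy(dtype=float)
        for j in range(0, small_cohort.config.n_snps, 97):
            g = G[:, j]
            ok = ~np.isnan(g)
            res = sm.Logit(y[ok], sm.add_constant(np.column_stack([X0[ok], g[ok]]))).fit(disp=0)
            assert stats["lnor"].iloc[j] == pytest.approx(res.params[-1], abs=1e-6)
            assert stats["se"].iloc[j] == pytest.approx(res.bse[-1], abs=1e-6)
            assert stats["n"].iloc[j] == int(ok.sum())

    def test_null_pvalues_uniform(self, null_cohort):
        stats = gwas(null_cohort.studies)
        assert kstest(stats["p"].to_numpy(), "uniform").pvalue > 0.01

    def test_monomorphic_snp_flagged(self, small_cohort):
        studies = [s.copy() for s in small_cohort.studies[:3]]
        for s in studies:
            s.dosage[:, 5] = 2.0
        stats = gwas(studies)
        assert bool(stats["flag"].iloc[5])
        assert stats["lnor"].iloc[5] == 0.0 and stats["p"].iloc[5] == 1.0

    def test_allele_recoding_equivariance(self, small_cohort):
        studies = [s.copy() for s in small_cohort.studies[:3]]
        base_stats = gwas(studies)
        snps = studies[0].snps.copy()
        snps.loc[3, ["a1", "a2"]] = snps.loc[3, ["a2", "a1"]].to_numpy()
        for s in studies:
            s.dosage[:, 3] = 2.0 - s.dosage[:, 3]
            s.snps = snps
        flipped = gwas(studies)
        assert flipped["lnor"].iloc[3] == pytest.approx(-base_stats["lnor"].iloc[3], abs=1e-6)
        assert flipped["p"].iloc[3] == pytest.approx(base_stats["p"].iloc[3], abs=1e-6)

    def test_sign_recovery_for_true_risk_allele(self, small_cohort):
        # strongest true liability effects should mostly show concordant ln(OR)
        stats = gwas(small_cohort.studies)
        beta = small_cohort.architecture.beta
        top = np.argsort(-np.abs(beta))[:25]
        concordant = np.sign(stats["lnor"].to_numpy()[top]) == np.sign(beta[top])
        assert concordant.mean() > 0.6


class TestOrientRisk:
    def test_flip_and_tie_and_idempotence(self):
        stats = pd.DataFrame(
            {"snp_id": ["s1", "s2"], "a1": ["A", "C"], "a2": ["G", "T"],
             "lnor": [-0.2, 0.0], "se": [0.1, 0.1], "p": [0.05, 1.0],
             "n": [100, 100], "flag": [False, False]}
        )
        o = orient_risk(stats)
        assert o.loc[0, "a1"] == "G" and o.loc[0, "a2"] == "A"
        assert o.loc[0, "lnor"] == pytest.approx(0.2)
        assert o.loc[1, "a1"] == "C" and o.loc[1, "lnor"] == 0.0
        pd.testing.assert_frame_equal(orient_risk(o), o)
        assert (o["lnor"] >= 0).all()

    def test_random_frames_all_nonnegative(self):
        rng = np.random.default_rng(5)
        stats = pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(50)], "a1": "A", "a2": "G",
             "lnor": rng.normal(size=50), "se": 0.1, "p": rng.uniform(size=50),
             "n": 100, "flag": False}
        )
        assert (orient_risk(stats)["lnor"] >= 0).all()


class TestLrtNagelkerke:
    def fr(self, llf):
        return FitResult(params=pd.Series(dtype=float), llf=llf, n=100, converged=True)

    def test_equal_likelihoods(self):
        stat, p = lrt(self.fr(-50.0), self.fr(-50.0), df=1)
        assert stat == 0.0 and p == 1.0

    def test_chi2_quantile_identity(self):
        stat, p = lrt(self.fr(-50.0), self.fr(-50.0 - 3.841 / 2), df=1)
        assert stat == pytest.approx(3.841)
        assert p == pytest.approx(chi2.sf(3.841, 1), abs=1e-12)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_invalid_nesting_and_nonconvergence(self):
        with pytest.raises(ValueError):
            lrt(self.fr(-10.0), self.fr(-11.0), df=0)
        with pytest.raises(RuntimeError):
            lrt(self.fr(-20.0), self.fr(-10.0), df=1)

    def test_nagelkerke_limits(self):
        assert nagelkerke(-40.0, -40.0, 100) == 0.0
        assert nagelkerke(-1e-12, -60.0, 100) == pytest.approx(1.0, abs=1e-9)

    def test_nagelkerke_hand_fixture(self):
        # n=8, y=(1,1,1,0,0,0,0,0), fitted probs p=(.8,.7,.6,.3,.2,.2,.1,.1)
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        probs = np.array([0.8, 0.7, 0.6, 0.3, 0.2, 0.2, 0.1, 0.1])
        ll_model = float(np.sum(y * np.log(probs) + (1 - y) * np.log(1 - probs)))
        phat = 3 / 8
        ll_null = 8 * (phat * np.log(phat) + (1 - phat) * np.log(1 - phat))
        expected = (1 - np.exp(2 / 8 * (ll_null - ll_model))) / (1 - np.exp(2 / 8 * ll_null))
        assert nagelkerke(ll_model, ll_null, 8) == pytest.approx(expected, abs=1e-12)

    def test_nagelkerke_monotone_in_model_likelihood(self):
        lls = np.linspace(-60, -20, 15)
        vals = [nagelkerke(ll, -60.0, 100) for ll in lls]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_nagelkerke_zero_n_rejected(self):
        with pytest.raises(ValueError):
            nagelkerke(-1.0, -2.0, 0)
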