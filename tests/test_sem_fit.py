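"""Estimation engine: closed forms, FIML oracle, indices, standardization."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from neuroasym.errors import ModelError
from neuroasym.sem import ModelSpec, fit, fit_indices, standardize


def one_factor_data(seed, n=300, loadings=(0.8, 0.7, 0.6), means=(1.0, -2.0, 0.5)):
    rng = np.random.default_rng(seed)
    f = rng.normal(size=n)
    cols = {}
    for i, (lam, mu) in enumerate(zip(loadings, means)):
        cols[f"x{i+1}"] = mu + lam * f + np.sqrt(1 - lam ** 2) * rng.normal(size=n)
    return pd.DataFrame(cols)


def one_factor_spec(columns):
    spec = ModelSpec(observed=list(columns), latent=["f"])
    for v in columns:
        spec.add_loading("f", v)
    return spec


def casewise_loglik(df, mu, Sigma):
    ll = 0.0
    for _, row in df.iterrows():
        o = np.flatnonzero(row.notna().to_numpy())
        if len(o) == 0:
            continue
        ll += multivariate_normal.logpdf(
            row.to_numpy(dtype=float)[o], mean=mu[o], cov=Sigma[np.ix_(o, o)])
    return ll


class TestClosedForms:
    def test_one_factor_three_indicators_matches_algebra(self):
        df = one_factor_data(0)
        res = fit(one_factor_spec(df.columns), df)
        S = np.cov(df.to_numpy().T, bias=True)
        l1 = np.sqrt(S[0, 1] * S[0, 2] / S[1, 2])
        l2 = np.sqrt(S[0, 1] * S[1, 2] / S[0, 2])
        l3 = np.sqrt(S[0, 2] * S[1, 2] / S[0, 1])
        for v, lam in zip(df.columns, (l1, l2, l3)):
            assert res.estimate("path", v, "f") == pytest.approx(lam, abs=1e-6)
        for i, v in enumerate(df.columns):
            assert res.estimate("var", v) == pytest.approx(
                S[i, i] - (l1, l2, l3)[i] ** 2, abs=1e-6)
            assert res.estimate("mean", v) == pytest.approx(
                df[v].mean(), abs=1e-6)
        # exactly identified: the saturated likelihood is attained
        assert res.chisq == pytest.approx(0.0, abs=1e-6)

    def test_saturated_spec_has_zero_chisq_df(self):
        df = one_factor_data(1, n=150)
        spec = ModelSpec(observed=list(df.columns))
        for i, a in enumerate(df.columns):
            for b in list(df.columns)[i + 1:]:
                spec.add_covariance(a, b)
        res = fit(spec, df)
        assert res.df == 0
        assert res.chisq == pytest.approx(0.0, abs=1e-6)
        assert res.cfi == pytest.approx(1.0, abs=1e-9)
        assert res.rmsea == 0.0
        assert fit_indices(res)["tli"] is None

    def test_univariate_standard_errors(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.normal(loc=5, scale=2, size=500)})
        spec = ModelSpec(observed=["x"])
        res = fit(spec, df)
        n = len(df)
        sd = df["x"].std(ddof=0)
        assert res.se("mean", "x") == pytest.approx(sd / np.sqrt(n), rel=0.02)
        assert res.se("var", "x") == pytest.approx(sd ** 2 * np.sqrt(2 / n), rel=0.02)

    def test_bivariate_standardized_path_equals_pearson_r(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=400)
        y = 0.4 * x + rng.normal(size=400) * 2.0  # deliberately different scales
        df = pd.DataFrame({"x": x, "y": y})
        spec = ModelSpec(observed=["x", "y"])
        spec.add_regression("y", "x")
        res = fit(spec, df)
        r = np.corrcoef(x, y)[0, 1]
        assert res.std_estimate("path", "y", "x") == pytest.approx(r, abs=1e-6)
        table = standardize(res)
        assert "std_estimate" in table.columns


class TestFiml:
    def test_loglik_matches_casewise_oracle_with_missing(self):
        df = one_factor_data(5, n=250)
        rng = np.random.default_rng(6)
        df = df.mask(rng.random(df.shape) < 0.1)
        res = fit(one_factor_spec(df.columns), df)
        Sigma = res.implied[None]["Sigma"]
        mu = res.implied[None]["mu"]
        assert casewise_loglik(df, mu, Sigma) == pytest.approx(res.loglik, abs=1e-8)

    def test_complete_data_chisq_equals_n_times_discrepancy(self):
        df = one_factor_data(7, n=200, loadings=(0.9, 0.6, 0.7))
        df["x4"] = df["x1"] * 0.3 + np.random.default_rng(8).normal(size=200)
        res = fit(one_factor_spec(df.columns), df)
        S = np.cov(df.to_numpy().T, bias=True)
        xbar = df.mean().to_numpy()
        Sig = res.implied[None]["Sigma"]
        mu = res.implied[None]["mu"]
        Si = np.linalg.inv(Sig)
        d = xbar - mu
        F = (np.log(np.linalg.det(Sig)) - np.log(np.linalg.det(S))
             + np.trace(S @ Si) - len(S) + d @ Si @ d)
        assert res.chisq == pytest.approx(len(df) * F, abs=1e-5)

    def test_missingness_increases_no_bias(self):
        complete = one_factor_data(9, n=2000)
        rng = np.random.default_rng(10)
        holed = complete.mask(rng.random(complete.shape) < 0.15)
        r_complete = fit(one_factor_spec(complete.columns), complete, compute_se=False)
        r_holed = fit(one_factor_spec(holed.columns), holed, compute_se=False)
        for v in complete.columns:
            assert r_holed.estimate("path", v, "f") == pytest.approx(
                r_complete.estimate("path", v, "f"), abs=0.08)


class TestDiagnostics:
    def test_df_accounting(self):
        df = one_factor_data(11, n=120)
        res = fit(one_factor_spec(df.columns), df)
        p = 3
        assert res.df == p * (p + 3) // 2 - res.k_free
        assert res.k_free == 9  # 3 loadings + 3 residuals + 3 means

    def test_aic_bic_definitions(self):
        df = one_factor_data(12, n=100)
        res = fit(one_factor_spec(df.columns), df)
        assert res.aic == pytest.approx(-2 * res.loglik + 2 * res.k_free)
        assert res.bic == pytest.approx(-2 * res.loglik
                                        + res.k_free * np.log(res.n))

    def test_srmr_matches_direct_recomputation(self):
        df = one_factor_data(13, n=180, loadings=(0.8, 0.5, 0.9))
        df["x4"] = one_factor_data(14, n=180)["x1"].to_numpy()
        res = fit(one_factor_spec(df.columns), df)
        S = res.saturated_moments[None]["Sigma"]
        M = res.implied[None]["Sigma"]
        sd = np.sqrt(np.diag(S))
        R = (S - M) / np.outer(sd, sd)
        iu = np.triu_indices(len(S))
        assert res.srmr == pytest.approx(np.sqrt(np.mean(R[iu] ** 2)), abs=1e-10)

    def test_data_must_exceed_parameter_count(self):
        df = one_factor_data(15, n=8)
        with pytest.raises(ModelError):
            fit(one_factor_spec(df.columns), df)

    def test_missing_column_raises(self):
        df = one_factor_data(16)
        spec = one_factor_spec(["x1", "x2", "x3", "x9"])
        with pytest.raises(ModelError):
            fit(spec, df)


class TestModelSpecSerialization:
    def test_yaml_round_trip(self):
        spec = one_factor_spec(["x1", "x2", "x3"]).complete()
        text = spec.to_yaml()
        back = ModelSpec.from_yaml(text)
        assert back.to_dict() == spec.to_dict()

    def test_duplicate_parameter_rejected(self):
        spec = one_factor_spec(["x1", "x2", "x3"])
        with pytest.raises(ValueError):
            spec.add_loading("f", "x1")

    def test_fix_and_equate_produce_copies(self):
        spec = one_factor_spec(["x1", "x2", "x3"]).complete()
        fixed = spec.fix_parameter("var", "x1", value=0.0)
        assert spec.find("var", "x1").free
        assert not fixed.find("var", "x1").free
        eq = spec.equate([("path", "x1", "f"), ("path", "x2", "f")], "lam")
        assert eq.find("path", "x1", "f").label == "lam"
        assert spec.find("path", "x1", "f").label is None
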