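"""REML engine: closed forms, dense-matrix oracles, contrasts, z test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import dense_reml_loglik
from dusgp.data_io import ValidationError
from dusgp.gblup import LayoutSpec, make_spec, prepare_data
from dusgp.mixedmodel import (
    ModelSpec,
    build_design,
    contrast,
    fit_reml,
    normal_test,
)
from dusgp.relationship import GRMatrix
from dusgp.synthdata import simulate_panel, simulate_trials


def _one_way(v=6, k=4, s_v=1.2, s_e=0.8, seed=5):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, s_v, v)
    y = u[:, None] + rng.normal(0, s_e, (v, k))
    df = pd.DataFrame({"variety": np.repeat([f"v{i}" for i in range(v)], k),
                       "value": y.ravel()})
    return df, y


class TestREMLFit:
    def test_balanced_one_way_closed_form(self):
        df, y = _one_way()
        fit = fit_reml(ModelSpec("value", [], [("variety", "identity")]), df)
        v, k = y.shape
        ybar = y.mean(axis=1)
        msb = k * np.var(ybar, ddof=1)
        mse = ((y - ybar[:, None]) ** 2).sum() / (v * (k - 1))
        assert fit.sigma2["residual"] == pytest.approx(mse, abs=1e-6)
        assert fit.sigma2["variety"] == pytest.approx(max(0, (msb - mse) / k),
                                                      abs=1e-6)
        assert fit.converged

    def test_loglik_matches_dense_oracle_at_optimum(self):
        df, _ = _one_way(seed=6)
        spec = ModelSpec("value", [], [("variety", "identity")])
        fit = fit_reml(spec, df)
        y, X, _, _, Z, terms = build_design(df, spec)
        ll = dense_reml_loglik(y, X, [Z[:, t.sl] for t in terms],
                               [fit.sigma2["variety"]], fit.sigma2["residual"])
        assert fit.loglik_reml == pytest.approx(ll, abs=1e-8)

    def test_identity_grm_reproduces_identity_fit(self):
        panel = simulate_panel(10, 40, seed=3)
        trials, _ = simulate_trials(panel, n_environments=3,
                                    n_characteristics=1, seed=4)
        df = prepare_data(trials, panel, LayoutSpec("ryegrass"), "trait_1")
        grm_spec = make_spec(LayoutSpec("ryegrass"), "trait_1",
                             GRMatrix.identity([str(v) for v in panel.varieties]))
        id_spec = ModelSpec("trait_1", ["ploidy"],
                            [("variety", "identity"), ("environment", "identity"),
                             ("env_group", "identity")])
        fg, fi = fit_reml(grm_spec, df), fit_reml(id_spec, df)
        for term in fg.sigma2:
            assert fg.sigma2[term] == pytest.approx(fi.sigma2[term], abs=1e-8)
        pd.testing.assert_series_equal(fg.blups["variety"].sort_index(),
                                       fi.blups["variety"].sort_index(),
                                       atol=1e-8, check_names=False)
        a, b = panel.varieties[0], panel.varieties[1]
        assert contrast(fg, "variety", a, b) == pytest.approx(
            contrast(fi, "variety", a, b), abs=1e-8)

    def test_boundary_component_pinned(self):
        # equal variety means: the variety component must hit the boundary
        rng = np.random.default_rng(11)
        y = rng.normal(0, 1, (8, 6))
        y -= y.mean(axis=1, keepdims=True)
        df = pd.DataFrame({"variety": np.repeat([f"v{i}" for i in range(8)], 6),
                           "value": y.ravel()})
        fit = fit_reml(ModelSpec("value", [], [("variety", "identity")]), df)
        assert fit.sigma2["variety"] < 1e-6
        assert "variety" in fit.pinned

    def test_aliased_fixed_column_dropped(self):
        df, _ = _one_way()
        df["dup"] = 1.0  # aliased with the intercept
        fit = fit_reml(ModelSpec("value", ["dup"], [("variety", "identity")]), df)
        assert "dup" in fit.meta["dropped_fixed"]

    def test_no_residual_df_raises(self):
        df = pd.DataFrame({"variety": ["a"], "value": [1.0]})
        with pytest.raises(ValidationError):
            fit_reml(ModelSpec("value", [], [("variety", "identity")]), df)

    def test_fixed_sigma2_skips_estimation(self):
        df, _ = _one_way()
        fit = fit_reml(ModelSpec("value", [], [("variety", "identity")]), df,
                       fixed_sigma2={"variety": 1.0, "residual": 1.0})
        assert fit.n_iter == 0 and fit.converged


class TestContrast:
    def _toy_fit(self):
        # 4 varieties, explicit GRM, fixed components -> dense MME oracle
        rng = np.random.default_rng(21)
        G = np.array([[1.0, 0.5, 0.2, 0.0], [0.5, 1.0, 0.1, 0.0],
                      [0.2, 0.1, 1.0, 0.3], [0.0, 0.0, 0.3, 1.0]])
        labels = ["a", "b", "c", "d"]
        k = 3
        df = pd.DataFrame({
            "variety": np.repeat(labels, k),
            "value": rng.normal(5, 1, 4 * k),
        })
        sig = {"variety": 0.8, "residual": 0.5}
        spec = ModelSpec("value", [], [("variety", "grm")],
                         grm=GRMatrix(labels, G, 1.0))
        fit = fit_reml(spec, df, fixed_sigma2=sig)
        return fit, df, G, sig, labels, k

    def test_matches_dense_mme_inversion(self):
        fit, df, G, sig, labels, k = self._toy_fit()
        n = len(df)
        Z = np.kron(np.eye(4), np.ones((k, 1)))
        X = np.ones((n, 1))
        R = sig["residual"]
        C = np.block([
            [X.T @ X / R, X.T @ Z / R],
            [Z.T @ X / R, Z.T @ Z / R + np.linalg.inv(sig["variety"] * G)],
        ])
        rhs = np.concatenate([X.T @ df.value / R, Z.T @ df.value / R])
        sol = np.linalg.solve(C, rhs)
        Cinv = np.linalg.inv(C)
        est, sed = contrast(fit, "variety", "a", "b")
        assert est == pytest.approx(sol[1] - sol[2], abs=1e-8)
        exp_sed = np.sqrt(Cinv[1, 1] + Cinv[2, 2] - 2 * Cinv[1, 2])
        assert sed == pytest.approx(exp_sed, abs=1e-8)

    def test_degenerate_self_contrast(self):
        fit, *_ = self._toy_fit()
        assert contrast(fit, "variety", "a", "a") == (0.0, 0.0)

    def test_variety_without_data_shrinks_to_zero_under_identity_grm(self):
        rng = np.random.default_rng(31)
        labels = ["a", "b", "c"]
        df = pd.DataFrame({"variety": np.repeat(["a", "b"], 4),
                           "value": rng.normal(0, 1, 8)})
        spec = ModelSpec("value", [], [("variety", "grm")],
                         grm=GRMatrix.identity(labels))
        fit = fit_reml(spec, df, fixed_sigma2={"variety": 1.0, "residual": 1.0})
        assert fit.blups["variety"]["c"] == pytest.approx(0.0, abs=1e-12)
        est, _ = contrast(fit, "variety", "c", "b")
        assert est == pytest.approx(-fit.blups["variety"]["b"])

    def test_unknown_variety_raises(self):
        fit, *_ = self._toy_fit()
        with pytest.raises(ValidationError):
            contrast(fit, "variety", "a", "nope")


class TestNormalTest:
    @pytest.mark.parametrize("est,sed,alpha,expect", [
        (3.0, 1.0, 0.01, True),        # z = 3.0 > 2.5758
        (2.0, 1.0, 0.01, False),       # z = 2.0 < 2.5758
        (2.0, 1.0, 0.05, True),        # z = 2.0 > 1.96
    ])
    def test_decisions(self, est, sed, alpha, expect):
        z, p, distinct = normal_test(est, sed, alpha)
        assert distinct is expect
        assert p == pytest.approx(2 * stats.norm.sf(abs(est) / sed))

    def test_zero_estimate(self):
        z, p, distinct = normal_test(0.0, 1.0, 0.01)
        assert p == 1.0 and not distinct

    def test_threshold_is_exact_normal_quantile(self):
        zc = stats.norm.ppf(1 - 0.01 / 2)
        assert normal_test(zc + 1e-9, 1.0, 0.01)[2]
        assert not normal_test(zc - 1e-9, 1.0, 0.01)[2]

    def test_nonpositive_sed_rejected(self):
        with pytest.raises(ValidationError):
            normal_test(1.0, 0.0, 0.01)
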