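import numpy as np
import pandas as pd
import pytest
import scipy.stats

from lexsys.aoa_inference import (
    boxcox_z,
    compare,
    correlation_report,
    fit_linear,
    pca_disentangle,
    rf_regression,
    run_nested_suite,
    simple_slopes,
)


class TestBoxcoxZ:
    def test_lambda_one_is_affine(self, rng):
        df = pd.DataFrame({"x": rng.gamma(2.0, 1.0, 500)})
        out, spec = boxcox_z(df, ["x"], lambdas={"x": 1.0})
        r = np.corrcoef(df["x"], out["x"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)
        assert spec.lambdas["x"] == 1.0

    def test_lambda_zero_is_log(self, rng):
        df = pd.DataFrame({"x": rng.gamma(2.0, 1.0, 500) + 0.1})
        out, _ = boxcox_z(df, ["x"], lambdas={"x": 0.0})
        logged = np.log(df["x"])
        z = (logged - logged.mean()) / logged.std(ddof=0)
        np.testing.assert_allclose(out["x"], z, atol=1e-10)

    def test_mle_recovers_log_for_lognormal(self, rng):
        df = pd.DataFrame({"x": np.exp(rng.normal(0, 1, 5000))})
        _, spec = boxcox_z(df, ["x"])
        assert abs(spec.lambdas["x"]) <= 0.1

    def test_mle_matches_scipy_profile_llf_oracle(self, rng):
        x = rng.gamma(3.0, 2.0, 400)
        _, spec = boxcox_z(pd.DataFrame({"x": x}), ["x"])
        grid = np.linspace(-3, 3, 601)
        llf = np.array([scipy.stats.boxcox_llf(l, x) for l in grid])
        assert spec.lambdas["x"] == pytest.approx(grid[np.argmax(llf)])

    def test_z_scoring_exact(self, rng):
        df = pd.DataFrame({"x": rng.gamma(2.0, 1.0, 300), "y": rng.normal(0, 3, 300)})
        out, _ = boxcox_z(df, ["x", "y"])
        for c in ("x", "y"):
            assert abs(out[c].mean()) < 1e-10
            assert abs(out[c].std(ddof=0) - 1) < 1e-10

    def test_negative_values_shifted(self, rng):
        df = pd.DataFrame({"x": rng.normal(-5, 1, 200)})
        out, spec = boxcox_z(df, ["x"])
        assert spec.shifts["x"] > 0
        assert np.isfinite(out["x"]).all()

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            boxcox_z(pd.DataFrame({"x": [1.0] * 10}), ["x"])

    def test_spec_reapplies_exactly(self, rng):
        df = pd.DataFrame({"x": rng.gamma(2.0, 1.0, 300)})
        out, spec = boxcox_z(df, ["x"])
        again = spec.apply(df)
        np.testing.assert_allclose(out["x"], again["x"], atol=1e-12)


class TestFitLinear:
    def test_slope_recovery(self, rng):
        x = rng.normal(0, 1, 1000)
        y = 2.0 * x + rng.normal(0, 0.1, 1000)
        fit = fit_linear(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
        assert 1.9 <= fit.params["x"] <= 2.1

    def test_self_comparison_zero(self, rng):
        df = pd.DataFrame({"x": rng.normal(0, 1, 100), "y": rng.normal(0, 1, 100)})
        fit = fit_linear(df, "y", ["x"])
        assert compare(fit, fit).delta_aic == 0.0

    def test_delta_aic_equals_loglik_identity(self, rng):
        # oracle: independent Gaussian log-likelihood computation
        n = 300
        x1 = rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        y = 1.0 + 0.5 * x1 - 0.7 * x2 + rng.normal(0, 1, n)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        base = fit_linear(df, "y", ["x1"])
        aug = fit_linear(df, "y", ["x1", "x2"])

        def loglik(fit, cols):
            X = np.column_stack([np.ones(n)] + [df[c] for c in cols])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            s2 = resid @ resid / n
            return -n / 2 * (np.log(2 * np.pi * s2) + 1)

        d_oracle = 2 * (loglik(aug, ["x1", "x2"]) - loglik(base, ["x1"])) - 2 * (3 - 2)
        assert compare(base, aug).delta_aic == pytest.approx(d_oracle, abs=1e-8)

    def test_delta_aic_convention_invariance(self, rng):
        # AIC with and without the 2*pi additive constant gives the same delta
        n = 200
        x = rng.normal(0, 1, n)
        z = rng.normal(0, 1, n)
        y = x + rng.normal(0, 1, n)
        df = pd.DataFrame({"x": x, "z": z, "y": y})
        base = fit_linear(df, "y", ["x"])
        aug = fit_linear(df, "y", ["x", "z"])

        def rss_aic(fit):
            rss = float(fit.result.ssr)
            k = len(fit.predictors) + 1
            return n * np.log(rss / n) + 2 * k  # drops the constant terms

        assert compare(base, aug).delta_aic == pytest.approx(
            rss_aic(base) - rss_aic(aug), abs=1e-8
        )

    def test_interaction_requires_main_effects(self, rng):
        df = pd.DataFrame(
            {"a": rng.normal(size=50), "b": rng.normal(size=50), "y": rng.normal(size=50)}
        )
        with pytest.raises(ValueError, match="main effect"):
            fit_linear(df, "y", ["a"], interactions=[("a", "b")])

    def test_rank_deficient_names_aliased(self, rng):
        x = rng.normal(0, 1, 60)
        df = pd.DataFrame({"x": x, "x2": 2 * x, "y": rng.normal(0, 1, 60)})
        with pytest.raises(ValueError, match="aliased"):
            fit_linear(df, "y", ["x", "x2"])

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"x": [1.0, np.nan, 2.0], "y": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="missing"):
            fit_linear(df, "y", ["x"])

    def test_comparison_requires_nesting(self, rng):
        df = pd.DataFrame(
            {"a": rng.normal(size=50), "b": rng.normal(size=50), "y": rng.normal(size=50)}
        )
        fa = fit_linear(df, "y", ["a"])
        fb = fit_linear(df, "y", ["b"])
        with pytest.raises(ValueError, match="subset"):
            compare(fa, fb)


class TestNestedSuite:
    def test_ladder_structure(self, analysis_table):
        comps = run_nested_suite(analysis_table, iconicity_column=None)
        assert set(comps) == {"pnd_x_snd", "te", "ld", "snd_x_ld"}
        for comp in comps.values():
            assert comp.base.n == comp.augmented.n
            assert set(comp.base.predictors) <= set(comp.augmented.predictors)

    def test_injected_ld_effect_detected_with_negative_sign(self, analysis_table):
        comps = run_nested_suite(analysis_table)
        assert comps["ld"].delta_aic > 10
        assert comps["ld"].augmented.params["fsc_ld"] < 0

    def test_iconicity_branch(self, analysis_table):
        table = analysis_table.copy()
        rng = np.random.default_rng(0)
        table["iconicity"] = rng.normal(0, 1, len(table))
        table.loc[: len(table) // 3, "iconicity"] = np.nan
        comps = run_nested_suite(table, iconicity_column="iconicity")
        icon = comps["icon_ld"]
        assert icon.base.n == table["iconicity"].notna().sum()
        assert "iconicity" in icon.base.predictors

    def test_missing_iconicity_column_raises(self, analysis_table):
        with pytest.raises(ValueError, match="iconic"):
            run_nested_suite(
                analysis_table.drop(columns=["iconicity"], errors="ignore"),
                iconicity_column="iconicity",
            )


class TestSimpleSlopes:
    def _fit(self, b_int, rng):
        n = 400
        snd = rng.normal(0, 1, n)
        psc = rng.normal(0, 1, n)
        y = -0.7 * psc + b_int * snd * psc + rng.normal(0, 0.01, n)
        df = pd.DataFrame({"snd": snd, "psc": psc, "y": y})
        return fit_linear(df, "y", ["snd", "psc"], interactions=[("snd", "psc")]), df

    def test_no_moderation_equal_slopes(self, rng):
        fit, df = self._fit(0.0, rng)
        slopes = simple_slopes(fit, df, "psc", "snd")
        assert slopes["slope"].max() - slopes["slope"].min() < 0.02

    def test_hand_formula(self):
        # beta_psc=-0.7, beta_int=0.165, snd_q=1.6 -> -0.436
        assert -0.7 + 0.165 * 1.6 == pytest.approx(-0.436)

    def test_slopes_affine_in_moderator_quantile(self, rng):
        fit, df = self._fit(0.165, rng)
        slopes = simple_slopes(fit, df, "psc", "snd", quantiles=(0.05, 0.5, 0.95))
        b_main = fit.params["psc"]
        b_int = fit.params["snd:psc"]
        for _, row in slopes.iterrows():
            assert row["slope"] == pytest.approx(
                b_main + b_int * row["moderator_value"], abs=1e-12
            )

    def test_interaction_absent_raises(self, rng):
        df = pd.DataFrame(
            {"snd": rng.normal(size=50), "psc": rng.normal(size=50), "y": rng.normal(size=50)}
        )
        fit = fit_linear(df, "y", ["snd", "psc"])
        with pytest.raises(ValueError, match="interaction"):
            simple_slopes(fit, df, "psc", "snd")


class TestRandomForest:
    def _informative_table(self, rng, n=500):
        X = rng.normal(0, 1, (n, 5))
        y = 2.0 * X[:, 2] + rng.normal(0, 0.5, n)
        cols = [f"x{i}" for i in range(5)]
        df = pd.DataFrame(X, columns=cols)
        df["y"] = y
        return df, cols

    def test_informative_predictor_ranked_top(self, rng):
        df, cols = self._informative_table(rng)
        fit = rf_regression(df, "y", cols, n_trees=150, seed=0)
        assert fit.importances.idxmax() == "x2"
        assert fit.max_features == 1  # third of 5, floored, min 1

    def test_oob_close_to_test_split(self, rng):
        df, cols = self._informative_table(rng, n=1500)
        fit = rf_regression(df, "y", cols, n_trees=200, seed=1)
        assert abs(fit.oob_r2 - fit.test_r2) < 0.1

    def test_pure_noise_low_r2(self, rng):
        n = 800
        df = pd.DataFrame(rng.normal(0, 1, (n, 4)), columns=list("abcd"))
        df["y"] = rng.normal(0, 1, n)
        fit = rf_regression(df, "y", list("abcd"), n_trees=150, seed=2)
        assert fit.oob_r2 <= 0.05

    def test_no_predictors_rejected(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=10)})
        with pytest.raises(ValueError):
            rf_regression(df, "y", [])

    def test_impurity_mode(self, rng):
        df, cols = self._informative_table(rng, n=300)
        fit = rf_regression(df, "y", cols, n_trees=80, seed=0, importance="impurity")
        assert fit.importances.idxmax() == "x2"


def power_iteration_eig(corr, n_components, iters=10_000, tol=1e-14):
    """Deflated power iteration: independent eigendecomposition oracle."""
    a = corr.copy()
    vals, vecs = [], []
    rng = np.random.default_rng(0)
    for _ in range(n_components):
        v = rng.standard_normal(a.shape[0])
        v /= np.linalg.norm(v)
        for _ in range(iters):
            nv = a @ v
            nv /= np.linalg.norm(nv)
            if np.linalg.norm(nv - v) < tol or np.linalg.norm(nv + v) < tol:
                v = nv
                break
            v = nv
        lam = float(v @ a @ v)
        vals.append(lam)
        vecs.append(v)
        a = a - lam * np.outer(v, v)
    return np.array(vals), np.column_stack(vecs)


class TestPCA:
    def _table(self, rng, correlated=True, n=600):
        a = rng.normal(0, 1, n)
        if correlated:
            b = 0.6 * a + 0.8 * rng.normal(0, 1, n)
            c = -0.4 * a + rng.normal(0, 1, n)
        else:
            b = rng.normal(0, 1, n)
            c = rng.normal(0, 1, n)
        df = pd.DataFrame({"pnd": a, "snd": b, "fsc_ld": c})
        df["aoa"] = rng.normal(8, 1, n)
        return df

    def test_explained_variance_sums_to_inputs(self, rng):
        result, _ = pca_disentangle(self._table(rng))
        assert result.explained_variance.sum() == pytest.approx(3.0, abs=1e-10)

    def test_isotropic_shares(self, rng):
        result, _ = pca_disentangle(self._table(rng, correlated=False, n=5000))
        np.testing.assert_allclose(result.explained_shares, 1 / 3, atol=0.05)

    def test_loadings_match_power_iteration_oracle(self, rng):
        df = self._table(rng)
        result, _ = pca_disentangle(df)
        Z = df[["pnd", "snd", "fsc_ld"]].to_numpy()
        Z = (Z - Z.mean(0)) / Z.std(0)
        corr = np.corrcoef(Z, rowvar=False)
        vals, vecs = power_iteration_eig(corr, 3)
        np.testing.assert_allclose(result.explained_variance, vals, atol=1e-8)
        for j in range(3):
            v = vecs[:, j]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(result.loadings[:, j], v, atol=1e-6)

    def test_components_orthonormal(self, rng):
        result, _ = pca_disentangle(self._table(rng))
        np.testing.assert_allclose(
            result.loadings.T @ result.loadings, np.eye(3), atol=1e-10
        )

    def test_scores_and_fit_returned(self, rng):
        df = self._table(rng)
        result, fit = pca_disentangle(df, controls=())
        assert list(result.scores.columns) == ["pc1", "pc2", "pc3"]
        assert set(fit.predictors) == {"pc1", "pc2", "pc3"}


class TestCorrelationReport:
    def test_perfect_relations(self, rng):
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame({"x": x, "same": x, "neg": -x})
        rep = correlation_report(df, ["x", "same", "neg"])
        rx = rep.set_index(["var1", "var2"])
        assert rx.loc[("x", "same"), "r"] == pytest.approx(1.0)
        assert rx.loc[("x", "neg"), "r"] == pytest.approx(-1.0)

    def test_t_statistic_formula_at_reported_scale(self):
        # r = -.059 with n = 1771 -> t ~= -2.49 on 1769 df
        r, n = -0.059, 1771
        t = r * np.sqrt((n - 2) / (1 - r * r))
        assert t == pytest.approx(-2.49, abs=0.01)
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, n)
        noise = rng.normal(0, 1, n)
        y = r * x + np.sqrt(1 - r * r) * noise
        rep = correlation_report(pd.DataFrame({"x": x, "y": y}), ["x", "y"])
        row = rep.iloc[0]
        assert row["df"] == n - 2
        expected_t = row["r"] * np.sqrt(row["df"] / (1 - row["r"] ** 2))
        assert row["t"] == pytest.approx(expected_t, abs=1e-10)

    def test_fisher_ci_close_to_bootstrap(self, rng):
        n = 500
        x = rng.normal(0, 1, n)
        y = 0.4 * x + rng.normal(0, 1, n)
        rep = correlation_report(pd.DataFrame({"x": x, "y": y}), ["x", "y"]).iloc[0]
        # bootstrap oracle, vectorised
        idx = rng.integers(0, n, (10_000, n))
        xs, ys = x[idx], y[idx]
        xm = xs - xs.mean(1, keepdims=True)
        ym = ys - ys.mean(1, keepdims=True)
        rs = (xm * ym).sum(1) / np.sqrt((xm**2).sum(1) * (ym**2).sum(1))
        lo, hi = np.percentile(rs, [2.5, 97.5])
        assert abs(rep["ci_low"] - lo) < 0.02
        assert abs(rep["ci_high"] - hi) < 0.02

    def test_small_n_flagged_not_dropped(self):
        df = pd.DataFrame({"x": [1.0, 2.0, np.nan], "y": [1.0, np.nan, 2.0]})
        rep = correlation_report(df, ["x", "y"])
        assert len(rep) == 1
        assert not rep.iloc[0]["ok"]
        assert np.isnan(rep.iloc[0]["r"])
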