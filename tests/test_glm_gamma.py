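"""Gamma/log GLM fitting and marginal standardization.

Closed forms (intercept-only and saturated two-group fits), an independent
statsmodels fit, and a hand-rolled per-row prediction loop serve as oracles
for the IRLS solver and the recycled-predictions code.
"""

import numpy as np
import pandas as pd
import pytest

from costdecomp.errors import FitError, ValidationError
from costdecomp.glm_gamma import (
    ModelSpec,
    Term,
    apply_zero_rule,
    build_design,
    fit,
    marginal_means,
)


def simulate_gamma_frame(n, seed, beta=(7.0, 0.5, 0.3, -0.2), shape=0.8):
    rng = np.random.default_rng(seed)
    exposure = (rng.random(n) < 0.3).astype(float)
    x1 = rng.normal(size=n)
    x2 = rng.uniform(-1, 1, size=n)
    eta = beta[0] + beta[1] * exposure + beta[2] * x1 + beta[3] * x2
    y = rng.gamma(shape, np.exp(eta) / shape)
    return pd.DataFrame({"y": y, "exposure": exposure, "x1": x1, "x2": x2})


SPEC = ModelSpec("y", "exposure", (Term("x1"), Term("x2")))


class TestFit:
    def test_intercept_only_mle_is_the_sample_mean(self):
        # gamma/log intercept-only MLE: exp(intercept) = mean(y) = 4
        from costdecomp.glm_gamma import irls_gamma_log

        y = np.array([2.0, 4.0, 6.0])
        X = np.ones((3, 1))
        beta, _, _, converged = irls_gamma_log(X, y)
        assert converged
        assert np.exp(beta[0]) == pytest.approx(4.0, rel=1e-8)

    def test_two_group_saturated_fit_reproduces_group_means(self):
        df = pd.DataFrame(
            {"y": [2.0, 4.0, 6.0, 10.0, 14.0], "exposure": [0, 0, 0, 1, 1]}
        )
        res = fit(ModelSpec("y", "exposure"), df)
        m0, m1 = 4.0, 12.0
        b = res.coefficients
        assert np.exp(b[0]) == pytest.approx(m0, rel=1e-8)
        assert b[1] == pytest.approx(np.log(m1 / m0), rel=1e-8)
        mm = marginal_means(res, ModelSpec("y", "exposure"), df)
        assert mm.mean_unexposed == pytest.approx(m0, rel=1e-8)
        assert mm.mean_exposed == pytest.approx(m1, rel=1e-8)

    def test_zero_outcome_with_handling_disabled_errors(self):
        df = pd.DataFrame({"y": [0.0, 2.0, 3.0], "exposure": [0, 1, 0]})
        with pytest.raises(ValidationError):
            fit(ModelSpec("y", "exposure"), df, zero_rule="error")

    def test_zero_rules(self):
        y = np.array([0.0, 2.0, 3.0])
        y1, keep, n = apply_zero_rule(y, "replace_one")
        assert n == 1 and y1[0] == 1.0 and keep.all()
        y2, keep2, _ = apply_zero_rule(y, "exclude")
        assert keep2.tolist() == [False, True, True]

    def test_rank_deficient_design_names_aliased_columns(self):
        df = simulate_gamma_frame(100, 1)
        df["x_dup"] = df["x1"]
        spec = ModelSpec("y", "exposure", (Term("x1"), Term("x_dup")))
        with pytest.raises(FitError, match="aliased"):
            fit(spec, df)

    def test_matches_statsmodels(self):
        """Independent cross-check: statsmodels GLM, Gamma family, log link."""
        import statsmodels.api as sm

        df = simulate_gamma_frame(800, 7)
        res = fit(SPEC, df)
        X = sm.add_constant(df[["exposure", "x1", "x2"]])
        ref = sm.GLM(
            df["y"], X, family=sm.families.Gamma(link=sm.families.links.Log())
        ).fit()
        assert res.coefficients == pytest.approx(ref.params.to_numpy(), abs=1e-6)
        assert res.dispersion == pytest.approx(ref.scale, rel=1e-4)

    def test_mean_calibration(self):
        """Average fitted mean tracks the sample mean of the outcome."""
        df = simulate_gamma_frame(4000, 3)
        res = fit(SPEC, df)
        design = build_design(SPEC, df)
        fitted = np.exp(design.X @ res.coefficients)
        assert fitted.mean() == pytest.approx(df["y"].mean(), rel=0.005)


class TestMarginalMeans:
    def brute_force(self, res, df, covariates):
        """Per-row recycled predictions computed from the coefficient names,
        independently of the design-matrix machinery."""
        coef = dict(zip(res.columns, res.coefficients))
        out = {0: [], 1: []}
        for _, row in df.iterrows():
            for ex in (0, 1):
                eta = coef["intercept"] + coef["exposure"] * ex
                for name in covariates:
                    val = row[name]
                    if isinstance(val, str):
                        eta += coef.get(f"{name}[{val}]", 0.0)
                    else:
                        eta += coef[name] * val
                out[ex].append(np.exp(eta))
        return float(np.mean(out[1])), float(np.mean(out[0]))

    def test_null_exposure_effect_gives_zero_incremental(self):
        df = simulate_gamma_frame(500, 5)
        res = fit(SPEC, df)
        res.coefficients[1] = 0.0
        mm = marginal_means(res, SPEC, df)
        assert mm.incremental == 0.0

    def test_agrees_with_per_row_oracle(self):
        rng = np.random.default_rng(21)
        df = simulate_gamma_frame(400, 9)
        df["group"] = rng.choice(["a", "b", "c"], size=len(df))
        spec = ModelSpec("y", "exposure", (Term("x1"), Term("group", "categorical")))
        res = fit(spec, df)
        mm = marginal_means(res, spec, df)
        exp_or, unexp_or = self.brute_force(res, df, ["x1", "group"])
        assert mm.mean_exposed == pytest.approx(exp_or, rel=1e-10)
        assert mm.mean_unexposed == pytest.approx(unexp_or, rel=1e-10)
        assert mm.incremental == mm.mean_exposed - mm.mean_unexposed

    def test_outcome_scaling_scales_means_linearly(self):
        df = simulate_gamma_frame(600, 13)
        mm1 = marginal_means(fit(SPEC, df), SPEC, df)
        df2 = df.assign(y=df["y"] * 3.0)
        mm2 = marginal_means(fit(SPEC, df2), SPEC, df2)
        assert mm2.mean_exposed == pytest.approx(3 * mm1.mean_exposed, rel=1e-6)
        assert mm2.incremental == pytest.approx(3 * mm1.incremental, rel=1e-6)

    def test_nonbinary_exposure_rejected(self):
        df = simulate_gamma_frame(100, 2)
        df["exposure"] = df["exposure"] + 0.5
        with pytest.raises(ValidationError):
            fit(SPEC, df)
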