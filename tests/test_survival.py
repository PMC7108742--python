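import numpy as np
import pandas as pd
import pytest
from scipy import stats

from markerpipe.io_meta import ValidationError
from markerpipe.survival import (assumption_checks, cox_fit, linearity_test,
                                 natural_spline_basis, ph_test,
                                 schoenfeld_residuals, survival_screen)
from markerpipe.synthetic import synth_survival


class TestCoxFit:
    def test_analytic_toy_solution(self):
        # score equation reduces to u^2 = 6 in u = exp(beta)
        t = np.array([0.5, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 1, 0])
        x = np.array([0.0, 1.0, 0.0, 0.0])
        fit = cox_fit(t, e, x)
        assert fit.beta[0] == pytest.approx(np.log(np.sqrt(6.0)), abs=1e-6)
        assert fit.score_norm <= 1e-6
        assert fit.converged

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            cox_fit(np.array([1.0, 2, 3]), np.array([1, 1, 1]),
                    np.array([2.0, 2.0, 2.0]))

    def test_time_rescaling_invariance(self, rng):
        n = 80
        x = rng.normal(size=n)
        rec = synth_survival(x, 0.7, censoring_fraction=0.2, seed=3)
        f1 = cox_fit(rec["time"].to_numpy(), rec["event"].to_numpy(), x)
        f2 = cox_fit(37.0 * rec["time"].to_numpy(), rec["event"].to_numpy(), x)
        assert np.allclose(f1.beta, f2.beta, atol=1e-8)

    def test_recovers_true_loghr(self, rng):
        ests = []
        for s in range(5):
            x = np.random.default_rng(s).normal(size=500)
            rec = synth_survival(x, 0.7, censoring_fraction=0.2, seed=s)
            fit = cox_fit(rec["time"].to_numpy(), rec["event"].to_numpy(), x)
            ests.append(fit.beta[0])
        assert abs(np.mean(ests) - 0.7) <= 0.1

    def test_matches_lifelines_oracle(self, rng):
        from lifelines import CoxPHFitter
        n = 120
        Z = rng.normal(size=(n, 2))
        rec = synth_survival(Z, np.array([0.5, -0.3]), censoring_fraction=0.25,
                             seed=8)
        fit = cox_fit(rec["time"].to_numpy(), rec["event"].to_numpy(), Z)
        df = pd.DataFrame({"t": rec["time"], "e": rec["event"],
                           "x1": Z[:, 0], "x2": Z[:, 1]})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert np.allclose(fit.beta, cph.params_[["x1", "x2"]].to_numpy(),
                           atol=1e-4)
        assert np.allclose(np.sqrt(np.diag(fit.cov)),
                           cph.standard_errors_[["x1", "x2"]].to_numpy(),
                           atol=1e-4)

    def test_separation_flagged_not_raised(self):
        t = np.array([1.0, 2, 3, 4, 5, 6.0])
        e = np.array([1, 1, 1, 1, 1, 1])
        x = np.array([1.0, 1, 1, 0, 0, 0])   # early deaths all exposed
        with pytest.warns(UserWarning, match="non-estimable"):
            fit = cox_fit(t, e, x)
        assert not fit.estimable

    def test_ci_coverage_near_nominal(self):
        # 95% Wald intervals around the true logHR
        true = 0.5
        covered = 0
        n_sim = 300
        for s in range(n_sim):
            gen = np.random.default_rng(1000 + s)
            x = gen.normal(size=300)
            rec = synth_survival(x, true, censoring_fraction=0.2, seed=2000 + s)
            fit = cox_fit(rec["time"].to_numpy(), rec["event"].to_numpy(), x)
            se = np.sqrt(fit.cov[0, 0])
            if abs(fit.beta[0] - true) <= 1.96 * se:
                covered += 1
        assert 0.93 <= covered / n_sim <= 0.97


class TestAssumptionChecks:
    def test_ph_violation_detected(self):
        # effect reverses sign at the median time: textbook PH violation
        rejections = 0
        n_sim = 40
        for s in range(n_sim):
            gen = np.random.default_rng(s)
            n = 300
            x = gen.normal(size=n)
            lam0 = 0.2
            m = np.log(2) / lam0          # median of the baseline
            u = gen.random(n)
            lam1 = lam0 * np.exp(1.0 * x)
            lam2 = lam0 * np.exp(-1.0 * x)
            t = -np.log(u) / lam1
            late = t > m
            t[late] = m + (-np.log(u[late]) - lam1[late] * m) / lam2[late]
            e = np.ones(n)
            fit = cox_fit(t, e, x)
            if ph_test(t, e, x, fit)[0] < 0.05:
                rejections += 1
        assert rejections / n_sim >= 0.8

    def test_quadratic_effect_fails_linearity(self):
        gen = np.random.default_rng(5)
        n = 300
        x = gen.normal(size=n)
        rec = synth_survival(np.column_stack([x ** 2]), 1.0,
                             censoring_fraction=0.1, seed=5)
        p = linearity_test(rec["time"].to_numpy(), rec["event"].to_numpy(),
                           x.reshape(-1, 1), 0)
        assert p < 0.01

    def test_categorical_covariate_linearity_not_applicable(self, rng):
        n = 100
        z = np.column_stack([rng.integers(0, 2, n).astype(float),
                             rng.normal(size=n)])
        rec = synth_survival(z, np.array([0.3, 0.2]), censoring_fraction=0.2,
                             seed=1)
        fit = cox_fit(rec["time"].to_numpy(), rec["event"].to_numpy(), z)
        chk = assumption_checks(rec["time"].to_numpy(), rec["event"].to_numpy(),
                                z, fit)
        assert np.isnan(chk["linearity_p"].iloc[0])
        assert np.isfinite(chk["linearity_p"].iloc[1])

    def test_spline_basis_three_columns_linear_tails(self, rng):
        x = rng.normal(size=200)
        B = natural_spline_basis(x)
        assert B.shape == (200, 3)
        # natural spline: second differences vanish beyond the boundary knots
        grid = np.linspace(x.max() + 1, x.max() + 5, 50)
        Bg = natural_spline_basis(grid, knots=np.quantile(x, [0, 0.25, 0.75, 1.0]))
        second = np.diff(Bg, n=2, axis=0)
        assert np.allclose(second, 0.0, atol=1e-8)


class TestScreen:
    def test_planted_prognostic_ranks_first(self):
        gen = np.random.default_rng(10)
        n, p = 200, 20
        X = gen.normal(size=(p, n))
        rec = synth_survival(X[0], 1.0, censoring_fraction=0.2, seed=10)
        table, _ = survival_screen(X, [f"v{i}" for i in range(p)],
                                   rec["time"].to_numpy(),
                                   rec["event"].to_numpy())
        assert table.nsmallest(1, "FDR")["id"].iloc[0] == "v0"
        assert (table["ci_low"] <= table["logHR"]).all()
        assert (table["logHR"] <= table["ci_high"]).all()

    def test_nonlinear_adjustment_gets_spline(self):
        gen = np.random.default_rng(11)
        n = 300
        age = gen.uniform(-2, 2, n)
        X = gen.normal(size=(5, n))
        rec = synth_survival(np.column_stack([age ** 2]), 1.2,
                             censoring_fraction=0.1, seed=11)
        table, checks = survival_screen(
            X, [f"v{i}" for i in range(5)], rec["time"].to_numpy(),
            rec["event"].to_numpy(), adjust=age.reshape(-1, 1),
            adjust_names=["age"])
        assert bool(checks.loc[0, "spline"])

    def test_log2_scale_column(self):
        gen = np.random.default_rng(12)
        X = gen.normal(size=(3, 150))
        rec = synth_survival(X[0], 0.8, censoring_fraction=0.2, seed=12)
        table, _ = survival_screen(X, ["a", "b", "c"], rec["time"].to_numpy(),
                                   rec["event"].to_numpy())
        assert np.allclose(table["log2HR"], table["logHR"] / np.log(2))
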