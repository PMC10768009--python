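"""Subject-level GLM fitting: OLS, AR(2)-error ML, BIC comparison."""

import numpy as np
import pytest

from rlderiv.glm_fit import DesignMatrix, GLMFit, ar2_fit, compare_bic, ols_fit


def _ar2_noise(n, phi1, phi2, sigma, rng):
    e = sigma * rng.standard_normal(n + 200)
    u = np.zeros(n + 200)
    for t in range(2, n + 200):
        u[t] = phi1 * u[t - 1] + phi2 * u[t - 2] + e[t]
    return u[200:]


def _design(rng, n, names=("rpe", "deriv"), add_trend=False):
    cols = {name: rng.standard_normal(n) for name in names}
    return DesignMatrix.build(cols, add_trend=add_trend)


class TestDesignMatrix:
    def test_intercept_and_normalized_columns(self, rng):
        d = _design(rng, 300, add_trend=True)
        assert d.names == ["rpe", "deriv", "linear_trend"]
        assert np.all(d.X[:, 0] == 1.0)
        for j in range(1, d.n_columns):
            assert d.X[:, j].mean() == pytest.approx(0.0, abs=1e-10)
            assert d.X[:, j].std() == pytest.approx(1.0)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            DesignMatrix.build({"flat": np.ones(50)})

    def test_to_frame_serialization(self, rng):
        d = _design(rng, 30)
        frame = d.to_frame()
        assert list(frame.columns) == ["intercept", "rpe", "deriv"]
        assert frame.shape == (30, 3)

    def test_drop_column(self, rng):
        d = _design(rng, 100)
        r = d.drop("deriv")
        assert r.names == ["rpe"] and r.X.shape == (100, 2)
        assert r.X[:, 1] == pytest.approx(d.X[:, 1])


class TestOLS:
    def test_exact_fit_of_single_column(self, rng):
        d = _design(rng, 200, names=("rpe",))
        y = 3.0 * d.X[:, 1]
        fit = ols_fit(y, d)
        assert fit.beta("rpe") == pytest.approx(3.0)
        assert fit.beta("rpe") == pytest.approx(np.std(y))
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_generate_and_recover(self, rng):
        d = _design(rng, 2000)
        y = 2.0 * d.X[:, 1] + 3.0 * d.X[:, 2] + 0.01 * rng.standard_normal(2000)
        fit = ols_fit(y, d)
        assert fit.beta("rpe") == pytest.approx(2.0, abs=0.05)
        assert fit.beta("deriv") == pytest.approx(3.0, abs=0.05)

    def test_row_permutation_invariance(self, rng):
        d = _design(rng, 150)
        y = d.X @ np.array([0.5, 1.0, -2.0]) + rng.standard_normal(150)
        fit = ols_fit(y, d)
        perm = rng.permutation(150)
        d2 = DesignMatrix(names=d.names, X=d.X[perm])
        fit2 = ols_fit(y[perm], d2)
        assert fit2.betas == pytest.approx(fit.betas)
        assert fit2.loglik == pytest.approx(fit.loglik)

    def test_collinear_columns_named_in_error(self, rng):
        x = rng.standard_normal(100)
        d = DesignMatrix.build({"a": x, "b": 2.0 * x})
        with pytest.raises(np.linalg.LinAlgError, match="b"):
            ols_fit(rng.standard_normal(100), d)

    def test_t_scale_free_beta_inverse_scale(self, rng):
        cols = {"a": rng.standard_normal(400), "b": rng.standard_normal(400)}
        y = cols["a"] * 1.5 + rng.standard_normal(400)
        d1 = DesignMatrix.build(dict(cols), normalize=False)
        cols["a"] = cols["a"] * 10.0
        d2 = DesignMatrix.build(cols, normalize=False)
        f1, f2 = ols_fit(y, d1), ols_fit(y, d2)
        assert f2.tvalue("a") == pytest.approx(f1.tvalue("a"))
        assert f2.beta("a") == pytest.approx(f1.beta("a") / 10.0)


class TestAR2:
    def test_matches_sarimax_oracle(self, rng):
        """Exact-ML fit agrees with statsmodels SARIMAX (same model) on
        log-likelihood, AR coefficients and betas."""
        import statsmodels.api as sm

        n = 400
        d = _design(rng, n, add_trend=True)
        u = _ar2_noise(n, 0.5, 0.2, 0.8, rng)
        y = d.X @ np.array([0.1, 0.5, -0.2, 0.3]) + u
        fit = ar2_fit(y, d)
        ref = sm.tsa.SARIMAX(y, exog=d.X, order=(2, 0, 0), trend="n").fit(disp=0)
        assert fit.loglik == pytest.approx(ref.llf, abs=5e-3)
        assert fit.ar_coefficients == pytest.approx(ref.params[-3:-1], abs=0.02)
        assert fit.betas == pytest.approx(ref.params[:4], abs=0.02)

    def test_white_noise_agrees_with_ols(self, rng):
        diffs = []
        phis = []
        for _ in range(60):
            d = _design(rng, 500)
            y = d.X @ np.array([0.0, 1.0, -0.5]) + rng.standard_normal(500)
            f_ar = ar2_fit(y, d)
            f_ols = ols_fit(y, d)
            diffs.append(np.abs(f_ar.betas - f_ols.betas).mean())
            phis.append(f_ar.ar_coefficients)
        assert np.mean(diffs) < 0.02
        assert np.abs(np.mean(phis, axis=0)) == pytest.approx([0, 0], abs=0.02)

    def test_recovers_ar_coefficients(self, rng):
        est = []
        for _ in range(30):
            d = _design(rng, 2800)
            u = _ar2_noise(2800, 0.5, 0.2, 1.0, rng)
            y = d.X @ np.array([0.0, 1.0, 0.5]) + u
            est.append(ar2_fit(y, d).ar_coefficients)
        assert np.mean(est, axis=0) == pytest.approx([0.5, 0.2], abs=0.05)

    def test_noiseless_betas_exact(self, rng):
        d = _design(rng, 300)
        beta = np.array([0.2, 1.3, -0.7])
        fit = ar2_fit(d.X @ beta + 1e-8 * rng.standard_normal(300), d)
        assert fit.betas == pytest.approx(beta, abs=1e-4)

    def test_short_series_rejected(self, rng):
        d = _design(rng, 40)
        with pytest.raises(ValueError):
            ar2_fit(rng.standard_normal(40), d)


class TestCompareBIC:
    def _fit(self, loglik, k_named, n):
        names = ["intercept"] + [f"c{i}" for i in range(k_named)]
        k_bic = (k_named + 1) + 2 + 1
        return GLMFit(
            names=names,
            betas=np.zeros(k_named + 1),
            tvalues=np.zeros(k_named + 1),
            loglik=loglik,
            bic=-2 * loglik + k_bic * np.log(n),
            sigma2=1.0,
            nobs=n,
            ar_coefficients=np.zeros(2),
        )

    def test_pure_penalty_when_loglik_equal(self):
        n = 1400
        red, full = self._fit(-100.0, 2, n), self._fit(-100.0, 3, n)
        out = compare_bic(red, full)
        assert not out["prefers_full"]
        assert out["delta"] == pytest.approx(-np.log(n))

    def test_different_n_rejected(self):
        with pytest.raises(ValueError):
            compare_bic(self._fit(-10, 2, 100), self._fit(-10, 3, 101))

    def test_prefers_full_iff_likelihood_gain_beats_penalty(self):
        n = 700
        red = self._fit(-100.0, 2, n)
        assert compare_bic(red, self._fit(-95.0, 3, n))["prefers_full"]
        assert not compare_bic(red, self._fit(-98.0, 3, n))["prefers_full"]


class TestBICOnSimulatedRuns:
    """Directional behavior of the BIC comparison on fMRI-like runs."""

    @staticmethod
    def _preference(alpha_true, n_seeds, rng_offset=0):
        from rlderiv.bold_sim import simulate_bold_run
        from rlderiv.design_regressors import SamplingGrid
        from rlderiv.experiments import fmri_design
        from rlderiv.paradigms import ParticipantSpec, make_schedule

        grid = SamplingGrid(400)
        wins = 0
        for s in range(n_seeds):
            spec = ParticipantSpec(
                alpha=alpha_true, lam=1.25, drift=0.1, theta=0.0, snr=4.0,
                noise_exponent=1.0, hrf_scale=1.0, n_trials=400,
                seed=rng_offset + s,
            )
            r = np.random.default_rng(rng_offset + s)
            sched = make_schedule(400, spec.drift, rng=r)
            run = simulate_bold_run(spec, sched, grid, rng=r)
            design = fmri_design(sched.outcomes[:, 0], grid)
            full = ar2_fit(run.values, design)
            red = ar2_fit(run.values, design.drop("deriv"))
            wins += compare_bic(red, full)["prefers_full"]
        return wins / n_seeds

    def test_mismatched_alpha_rewards_derivative(self):
        """With a strongly mis-specified learning rate the derivative carries
        real signal, so BIC prefers the fuller model far more often than when
        the analysis alpha matches the truth."""
        mismatched = self._preference(0.7, 30)
        matched = self._preference(0.45, 30, rng_offset=500)
        assert matched < 0.10
        assert mismatched > 0.30
        assert mismatched > 3 * max(matched, 1 / 30)
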