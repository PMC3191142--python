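import numpy as np
import pytest

import dmncausal as dc
from dmncausal.synthetic import CouplingSpec, Edge
from dmncausal.var import BivariateVAR, fit_var_fos, fit_var_ols, geweke_measures


def _coupled_pair(t, coeff=0.9, lag=1, seed=0, noise=1.0):
    """y_t = coeff * x_{t-lag} + e_t with unit-variance white x, e."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=t)
    e = rng.normal(size=t) * noise
    y = e.copy()
    y[lag:] += coeff * x[:-lag]
    return x, y


class TestOlsFit:
    def test_recovers_generating_coefficients_at_tiny_noise(self):
        """A near-noiseless VAR(5) realization returns the generating lags."""
        spec = CouplingSpec(
            node_labels=("x", "y"),
            hub_labels=("x",),
            edges=(Edge("x", "y", 3, 0.5),),
            self_coefficients={"x": (0.4, 0.0, 0.0, 0.0, 0.2),
                               "y": (0.0, 0.3, 0.0, 0.0, 0.0)},
            noise_sd={"x": 1.0, "y": 1.0},
        )
        ts = dc.simulate_subject(spec, 4000, seed=2)
        x_sig, y_sig = ts.values[:, 0], ts.values[:, 1]
        rng = np.random.default_rng(3)
        x = x_sig + 1e-6 * rng.normal(size=x_sig.size)
        y = y_sig  # y keeps its own unit innovations; x gets micro-noise only
        model = fit_var_ols(x, y, 5)
        np.testing.assert_allclose(
            model.coefficients["y"]["cross"], [0, 0, 0.5, 0, 0], atol=0.05
        )
        np.testing.assert_allclose(
            model.coefficients["y"]["own"], [0, 0.3, 0, 0, 0], atol=0.05
        )

    def test_white_noise_cross_terms_near_zero(self):
        rng = np.random.default_rng(4)
        model = fit_var_ols(rng.normal(size=8000), rng.normal(size=8000), 5)
        assert np.max(np.abs(model.coefficients["y"]["cross"])) < 0.05
        assert np.max(np.abs(model.coefficients["x"]["cross"])) < 0.05

    def test_nested_variance_inequality(self, control_subject):
        for j in range(1, 4):
            m = fit_var_ols(control_subject.values[:, 0], control_subject.values[:, j], 5)
            assert m.residual_variance_full["x"] <= m.residual_variance_restricted["x"] + 1e-12
            assert m.residual_variance_full["y"] <= m.residual_variance_restricted["y"] + 1e-12

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            fit_var_ols(np.ones(100), np.arange(100.0), 5)


class TestFosFit:
    def test_threshold_zero_equals_ols(self, control_subject):
        x, y = control_subject.values[:, 2], control_subject.values[:, 5]
        ols = fit_var_ols(x, y, 5)
        fos = fit_var_fos(x, y, 5, mse_reduction_threshold=0.0)
        for eq in ("x", "y"):
            np.testing.assert_allclose(
                fos.coefficients[eq]["own"], ols.coefficients[eq]["own"], atol=1e-8
            )
            np.testing.assert_allclose(
                fos.coefficients[eq]["cross"], ols.coefficients[eq]["cross"], atol=1e-8
            )

    def test_strong_coupling_term_admitted(self):
        x, y = _coupled_pair(2000, coeff=0.9, lag=2, seed=5)
        model = fit_var_fos(x, y, 5, mse_reduction_threshold=1e-3)
        cross = model.coefficients["y"]["cross"]
        assert abs(cross[1] - 0.9) < 0.1  # lag-2 term admitted near truth

    def test_pure_noise_admits_few_cross_terms(self):
        rng = np.random.default_rng(6)
        admitted = 0
        for i in range(20):
            x = rng.normal(size=295)
            y = rng.normal(size=295)
            m = fit_var_fos(x, y, 5, mse_reduction_threshold=0.05)
            admitted += np.count_nonzero(m.coefficients["y"]["cross"])
        # threshold 0.05 demands a 5% RSS reduction per term: essentially
        # nothing qualifies under independence (100 candidate admissions)
        assert admitted <= 5


class TestGewekeMeasures:
    def test_analytic_limit_of_unidirectional_coupling(self):
        """y_t = 0.9 x_{t-1} + e_t: F_x->y -> ln(1.81), F_y->x -> 0."""
        x, y = _coupled_pair(10000, coeff=0.9, seed=7)
        gc = geweke_measures(x, y, 5, fitter="ols")
        assert abs(gc.f_x_to_y - np.log(1.81)) < 0.05
        assert gc.f_y_to_x < 0.02

    def test_independent_noise_null(self):
        rng = np.random.default_rng(8)
        gc = geweke_measures(rng.normal(size=10000), rng.normal(size=10000), 5, "ols")
        assert gc.f_x_to_y < 0.01 and gc.f_y_to_x < 0.01

    def test_affine_invariance(self, control_subject):
        x, y = control_subject.values[:, 1], control_subject.values[:, 0]
        base = geweke_measures(x, y, 5, "ols")
        moved = geweke_measures(10.0 * x + 100.0, -2.5 * y + 3.0, 5, "ols")
        assert moved.f_x_to_y == pytest.approx(base.f_x_to_y, abs=1e-8)
        assert moved.f_y_to_x == pytest.approx(base.f_y_to_x, abs=1e-8)
        assert moved.f_instantaneous == pytest.approx(base.f_instantaneous, abs=1e-8)

    def test_nonnegative_on_simulated_data(self, control_spec):
        ts = dc.simulate_subject(control_spec, 295, seed=3)
        for fitter in ("ols", "fos"):
            gc = geweke_measures(ts.values[:, 3], ts.values[:, 1], 5, fitter)
            assert gc.f_x_to_y >= 0 and gc.f_y_to_x >= 0 and gc.f_instantaneous >= 0

    def test_perfectly_predictable_input_reported(self):
        t = np.arange(200.0)
        x = np.sin(0.3 * t)
        y = np.cos(0.3 * t)  # both perfectly predictable from 2 lags
        with pytest.raises(ValueError, match="predictable|rank"):
            geweke_measures(x, y, 5, "ols")


class TestModelObjects:
    def test_fit_consistency_with_functions(self, control_subject):
        x, y = control_subject.values[:, 1], control_subject.values[:, 0]
        res = BivariateVAR(x, y, 5).fit(method="ols")
        gc = geweke_measures(x, y, 5, "ols")
        assert res.f_x_to_y == gc.f_x_to_y
        assert res.f_y_to_x == gc.f_y_to_x

    def test_summary_reports_key_quantities(self, control_subject):
        x, y = control_subject.values[:, 1], control_subject.values[:, 0]
        text = BivariateVAR(x, y, 5).fit().summary()
        assert "F_x->y" in text and "order: 5" in text and "fos" in text
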