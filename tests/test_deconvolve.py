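"""Constrained Laguerre deconvolution and the per-point features."""

import numpy as np
import pytest
from scipy.linalg import cho_solve, solve_triangular

from flimcore._qp import nnls_wide, nnls_wide_ref
from flimcore.deconvolve import (
    DeconvolutionOperator,
    average_lifetime,
    average_pulses,
    deconvolve,
    extract_features,
)
from flimcore.errors import DegenerateInputError, InvalidParameterError, ShapeError
from flimcore.laguerre import build_laguerre_basis, convolve_irf
from flimcore.simulate import WaveformScan


class TestAverageLifetime:
    def test_sampled_exponential(self):
        """Center of mass of a sampled exponential equals its time constant
        (bin-centered axis, window much longer than tau)."""
        dt, tau = 0.4, 3.0
        t = np.arange(200) * dt  # 80 ns window ~ 27 tau
        h = np.exp(-t / tau)
        assert average_lifetime(h, dt) == pytest.approx(tau, rel=0.01)

    def test_delta_on_grid_convention(self):
        h = np.zeros(100)
        h[17] = 2.5
        assert average_lifetime(h, 0.4, bin_centering=False) == pytest.approx(17 * 0.4)
        assert average_lifetime(h, 0.4) == pytest.approx(17.5 * 0.4)

    def test_scale_invariance(self, rng):
        h = rng.random(500)
        lt = average_lifetime(h, 0.4)
        assert average_lifetime(123.4 * h, 0.4) == pytest.approx(lt, rel=1e-12)

    def test_degenerate(self):
        with pytest.raises(DegenerateInputError):
            average_lifetime(np.zeros(10), 0.4)

    def test_support_fraction_ignores_tiny_tail(self):
        dt = 0.4
        t = np.arange(500) * dt
        h = np.exp(-t / 2.0)
        h[400:] += 1e-4  # spurious tail bump
        full = average_lifetime(h, dt)
        guarded = average_lifetime(h, dt, support_fraction=1e-3)
        assert guarded < full
        assert guarded == pytest.approx(2.0, rel=0.02)


class TestAveragePulses:
    def test_identical_pulses(self):
        p = np.tile(np.arange(16.0), (8, 1))
        out = average_pulses(p, 4)
        assert out.shape == (2, 16)
        np.testing.assert_array_equal(out[0], out[1])
        np.testing.assert_array_equal(out[0], np.arange(16.0))

    def test_factor_one_identity(self, rng):
        p = rng.normal(size=(5, 10))
        np.testing.assert_array_equal(average_pulses(p, 1), p)

    def test_noise_reduction_sqrt_law(self, rng):
        p = rng.normal(0, 1.0, size=(4000, 50))
        out = average_pulses(p, 4)
        assert out.std() == pytest.approx(0.5, rel=0.05)

    def test_remainder_dropped_with_warning(self, caplog):
        p = np.ones((7, 4))
        with caplog.at_level("WARNING"):
            out = average_pulses(p, 4)
        assert out.shape == (1, 4)
        assert "trailing" in caplog.text

    def test_invalid_factor(self):
        with pytest.raises(InvalidParameterError):
            average_pulses(np.ones((4, 4)), 0)


@pytest.fixture(scope="module")
def small_setup():
    n = 300
    dt = 0.4
    basis = build_laguerre_basis(0.8, 12, n)
    t = np.arange(n) * dt
    sigma = 1.5 / 2.355
    irf = np.exp(-0.5 * ((t - 8.0) / sigma) ** 2)
    irf /= irf.sum()
    return {"n": n, "dt": dt, "basis": basis, "t": t, "irf": irf}


class TestDeconvolve:
    def test_forward_model_roundtrip(self, small_setup):
        """A noise-free waveform built from valid coefficients is recovered
        to high precision."""
        s = small_setup
        h_true = 0.6 * np.exp(-s["t"] / 4.0) + 0.4 * np.exp(-s["t"] / 1.5)
        op = DeconvolutionOperator(
            s["irf"], s["basis"], s["dt"], background_fraction=0.0, fit_offset=False
        )
        # two-stage construction: fitting once yields coefficients whose
        # decay satisfies the constraints, i.e. a valid generator
        c0 = op.fit(convolve_irf(h_true, s["irf"], s["n"])).coeffs
        y = convolve_irf(s["basis"].matrix @ c0, s["irf"], s["n"])
        fit = op.fit(y)
        np.testing.assert_allclose(fit.coeffs, c0, atol=1e-6)

    def test_qp_equals_unconstrained_ls_when_feasible(self, small_setup):
        """On a noise-free constraint-satisfying fixture the QP returns the
        plain least-squares solution."""
        s = small_setup
        h_true = np.exp(-s["t"] / 3.0)
        c0 = s["basis"].matrix.T @ h_true
        y = convolve_irf(s["basis"].matrix @ c0, s["irf"], s["n"])
        op = DeconvolutionOperator(
            s["irf"], s["basis"], s["dt"], background_fraction=0.0, fit_offset=False
        )
        fit = op.fit(y)
        c_ls = cho_solve(op._cho, op.A.T @ y)
        assert not fit.constrained or np.allclose(fit.coeffs, c_ls, atol=1e-8)
        np.testing.assert_allclose(fit.coeffs, c_ls, atol=1e-8)

    def test_monoexponential_lifetime(self, small_setup):
        """tau = 4 ns with a delta IRF, no noise -> lifetime within 2%."""
        s = small_setup
        delta = np.zeros(s["n"])
        delta[0] = 1.0
        y = np.exp(-s["t"] / 4.0)
        fit = deconvolve(y, delta, s["basis"], s["dt"])
        assert fit.avg_lifetime_ns == pytest.approx(4.0, rel=0.02)

    def test_zero_lifetime_limit(self, small_setup):
        """waveform == IRF: the decay collapses toward a delta.

        The fastest representable decay is bounded by the basis scale, so
        the limit is probed with a fast basis (alpha = 0.35 at 0.4 ns
        sampling resolves sub-sample decays)."""
        s = small_setup
        fast = build_laguerre_basis(0.35, 12, s["n"])
        fit = deconvolve(s["irf"], s["irf"], fast, s["dt"])
        assert fit.avg_lifetime_ns < 2 * s["dt"]

    def test_all_zero_waveform(self, small_setup):
        s = small_setup
        op = DeconvolutionOperator(s["irf"], s["basis"], s["dt"])
        with pytest.raises(DegenerateInputError):
            op.fit(np.zeros(s["n"]))

    def test_wrong_length(self, small_setup):
        s = small_setup
        op = DeconvolutionOperator(s["irf"], s["basis"], s["dt"])
        with pytest.raises(ShapeError):
            op.fit(np.zeros(s["n"] + 1))

    def test_amplitude_scale_invariance(self, small_setup, rng):
        s = small_setup
        h = np.exp(-s["t"] / 2.5)
        y = convolve_irf(h, s["irf"], s["n"]) + rng.normal(0, 0.005, s["n"])
        op = DeconvolutionOperator(s["irf"], s["basis"], s["dt"])
        lt1 = op.fit(y).avg_lifetime_ns
        lt2 = op.fit(7.7 * y).avg_lifetime_ns
        assert lt2 == pytest.approx(lt1, rel=1e-8)

    def test_constraints_hold_under_noise(self, small_setup, rng):
        s = small_setup
        h = 0.5 * np.exp(-s["t"] / 4.0) + 0.5 * np.exp(-s["t"] / 1.5)
        y0 = convolve_irf(h, s["irf"], s["n"])
        y0 /= y0.max()
        op = DeconvolutionOperator(s["irf"], s["basis"], s["dt"])
        for _ in range(10):
            fit = op.fit(y0 + rng.normal(0, 0.01, s["n"]))
            scale = np.abs(fit.fitted_decay).max()
            assert fit.fitted_decay.min() >= -1e-8 * scale
            assert np.diff(fit.fitted_decay).max() <= 1e-8 * scale

    def test_dual_solver_matches_scipy_oracle(self, small_setup, rng):
        """The JIT active-set NNLS agrees with scipy's reference NNLS on
        actively constrained problems."""
        s = small_setup
        h = 0.5 * np.exp(-s["t"] / 4.0) + 0.5 * np.exp(-s["t"] / 1.5)
        y0 = convolve_irf(h, s["irf"], s["n"])
        y0 /= y0.max()
        op = DeconvolutionOperator(s["irf"], s["basis"], s["dt"])
        for _ in range(5):
            y = y0 + rng.normal(0, 0.01, s["n"])
            b = op.A.T @ y
            w = solve_triangular(op._L, b, lower=True)
            x_fast = nnls_wide(op._M, w)
            x_ref = nnls_wide_ref(op._M, w)
            c_fast = cho_solve(op._cho, b + op.G.T @ x_fast)
            c_ref = cho_solve(op._cho, b + op.G.T @ x_ref)
            np.testing.assert_allclose(c_fast, c_ref, atol=1e-5)


class TestExtractFeatures:
    def _toy_scan(self, small_instrument, value=1.0, npos=3):
        t = small_instrument.time_axis_ns
        irf = small_instrument.band_irf("band470")
        h = value * np.exp(-t / 3.0)
        y = np.convolve(irf, h)[: small_instrument.n_samples]
        wf = {
            b: np.tile(y, (npos, 1)) for b in small_instrument.band_names
        }
        return WaveformScan("C0", "P0", 0, np.arange(npos) * 0.022, wf)

    def test_composition_matches_direct_fit(self, small_instrument, small_basis):
        scan = self._toy_scan(small_instrument)
        df = extract_features(scan, small_instrument, small_basis)
        op = DeconvolutionOperator(
            small_instrument.band_irf("band470"), small_basis, small_instrument.dt_ns
        )
        direct = op.fit(scan.waveforms["band470"][0])
        assert df.loc[0, "band470_lt"] == pytest.approx(direct.avg_lifetime_ns)
        assert df.loc[0, "band470_int"] == pytest.approx(direct.intensity)
        np.testing.assert_allclose(
            df.loc[0, [f"band470_lag{l:02d}" for l in range(12)]].to_numpy(float),
            direct.coeffs_norm,
            atol=1e-12,  # batched and single solves differ only in rounding
        )
        assert df.shape[0] == 3
        assert df["fit_ok"].all()

    def test_56_stored_parameters(self, small_instrument, small_basis):
        df = extract_features(self._toy_scan(small_instrument), small_instrument, small_basis)
        per_band = [c for c in df.columns if c.startswith("band")]
        assert len(per_band) == 56

    def test_empty_scan(self, small_instrument, small_basis):
        scan = WaveformScan(
            "C0", "P0", 0, np.array([]),
            {b: np.zeros((0, small_instrument.n_samples))
             for b in small_instrument.band_names},
        )
        df = extract_features(scan, small_instrument, small_basis)
        assert len(df) == 0

    def test_bad_point_flagged_not_fatal(self, small_instrument, small_basis):
        scan = self._toy_scan(small_instrument, npos=2)
        for b in scan.waveforms:
            scan.waveforms[b][1] = 0.0  # dead point in every band
        df = extract_features(scan, small_instrument, small_basis)
        assert df["fit_ok"].tolist() == [True, False]
        assert np.isnan(df.loc[1, "band470_lt"])
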