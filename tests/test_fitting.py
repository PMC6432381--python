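"""Fitting-layer tests: convolution, parameter recovery on synthetic data."""

import numpy as np
import pytest
from scipy.special import erf

from nanodozer import (ConvolutionSpec, NPDEParams, extract_Do, fit_alpha,
                       fit_parabola, fit_sigma_initial, fit_speed_exponent,
                       gaussian_convolve, steady_state_ramp)
from nanodozer.fitting import FitError, _resolve_states


def grid(n=400, lo=-1.6, hi=0.4):
    x = np.linspace(lo, hi, n)
    return x, x[1] - x[0]


class TestGaussianConvolve:
    def test_zero_sigma_is_identity(self):
        x, _ = grid()
        c = np.where((x > -1.0) & (x < 0.0), 2.0, 0.0)
        out = gaussian_convolve(x, c, ConvolutionSpec(0.0))
        assert np.array_equal(out, c)

    def test_mass_preserved(self):
        x, h = grid()
        c = np.where((x > -1.0) & (x < 0.0), 2.0, 0.0)
        for spec in (ConvolutionSpec(0.03), ConvolutionSpec(0.05, 0.008)):
            out = gaussian_convolve(x, c, spec)
            assert out.sum() * h == pytest.approx(c.sum() * h, rel=1e-9)

    def test_delta_becomes_gaussian_of_requested_width(self):
        x, h = grid()
        c = np.zeros_like(x)
        c[200] = 1.0
        sigma = 0.08
        out = gaussian_convolve(x, c, ConvolutionSpec(sigma))
        mu = np.sum(x * out) / np.sum(out)
        sd = np.sqrt(np.sum(out * (x - mu) ** 2) / np.sum(out))
        assert sd == pytest.approx(sigma, rel=0.02)

    def test_step_edge_half_height(self):
        """A broadened step takes half the plateau value at the edge
        position (error-function profile)."""
        x, h = grid()
        c = np.where(x > -0.6, 1.0, 0.0)
        c[x > 0.2] = 0.0
        sigma = 0.05
        out = gaussian_convolve(x, c, ConvolutionSpec(sigma))
        at_edge = np.interp(-0.6, x, out)
        assert at_edge == pytest.approx(0.5, abs=0.03)
        # and the shape near the edge matches the closed form
        sel = (x > -0.75) & (x < -0.45)
        expected = 0.5 * (1 + erf((x[sel] + 0.6) / (np.sqrt(2) * sigma)))
        assert np.allclose(out[sel], expected, atol=0.02)

    def test_distinct_edge_sigmas(self):
        """Each edge is broadened by its own sigma."""
        x, h = grid(600)
        c = np.where((x > -1.0) & (x < 0.0), 1.0, 0.0)
        out = gaussian_convolve(x, c, ConvolutionSpec(0.10, 0.01))
        # 10-90% rise distances differ by roughly the sigma ratio
        def rise(mask):
            seg = out[mask]
            xs = x[mask]
            lo = xs[np.searchsorted(seg, 0.1)]
            hi = xs[np.searchsorted(seg, 0.9)]
            return abs(hi - lo)
        left = rise((x > -1.4) & (x < -0.6))
        seg = out[(x > -0.4) & (x < 0.4)][::-1]
        xs = x[(x > -0.4) & (x < 0.4)][::-1]
        right = abs(xs[np.searchsorted(seg, 0.9)]
                    - xs[np.searchsorted(seg, 0.1)])
        assert left > 4 * right


class TestExtractDo:
    def test_recovers_do_from_analytic_ramp(self):
        """extract_Do inverts steady_state_ramp exactly (1e-6)."""
        for Do in (0.3, 0.74, 1.5):
            p = NPDEParams(Do=Do, r0=235.0, V=2.0 * Do / 235.0, alpha=0.07)
            ramp = steady_state_ramp(p)
            got = extract_Do(ramp.grid, ramp.u, p.V, p.r0)
            assert got == pytest.approx(Do, rel=1e-6)

    def test_robust_to_edge_broadening(self):
        p = NPDEParams(Do=0.74, r0=235.0, V=3.0 * 0.74 / 235.0, alpha=0.07)
        ramp = steady_state_ramp(p, m_cells=400)
        x = np.linspace(ramp.x1 - 0.3, ramp.x2 + 0.3, 700)
        u = np.interp(x, ramp.grid, ramp.u, left=0.0, right=0.0)
        u = gaussian_convolve(x, u, ConvolutionSpec(0.01))
        got = extract_Do(x, u, p.V, p.r0)
        assert got == pytest.approx(0.74, rel=0.02)

    def test_flat_profile_raises(self):
        x = np.linspace(0, 1, 100)
        with pytest.raises(FitError):
            extract_Do(x, np.ones_like(x), 0.05, 235.0)


class TestFitSigmaInitial:
    def test_exact_box_gives_vanishing_sigma(self):
        x, h = grid()
        u = np.where((x > -1.0) & (x < 0.0), 1.0, 0.0)
        spec, _ = fit_sigma_initial(x, u, "uniform_plateau")
        assert spec.sigma_left < 2 * h
        assert spec.sigma_right < 2 * h

    def test_recovers_distinct_edge_sigmas(self):
        """Box broadened with (0.05, 0.008) r0 is recovered within 5%."""
        x, h = grid(800)
        u = np.where((x > -1.0) & (x < 0.0), 1.0, 0.0)
        u = gaussian_convolve(x, u, ConvolutionSpec(0.05, 0.008))
        spec, fit = fit_sigma_initial(x, u, "uniform_plateau")
        assert spec.sigma_left == pytest.approx(0.05, rel=0.05)
        assert spec.sigma_right == pytest.approx(0.008, rel=0.05)

    def test_recovers_ramp_sigma(self):
        p = NPDEParams(Do=0.74, r0=235.0, V=4 * 0.74 / 235.0, alpha=0.07)
        ramp = steady_state_ramp(p, m_cells=400)
        x = np.linspace(ramp.x1 - 0.4, ramp.x2 + 0.4, 700)
        u = np.interp(x, ramp.grid, ramp.u, left=0.0, right=0.0)
        u = gaussian_convolve(x, u, ConvolutionSpec(0.013))
        spec, fit = fit_sigma_initial(x, u, "ramp")
        assert spec.sigma_left == pytest.approx(0.013, rel=0.05)
        assert fit.params["slope"] == pytest.approx(4.0, rel=0.05)

    def test_degenerate_profile_raises(self):
        x, _ = grid()
        with pytest.raises(FitError):
            fit_sigma_initial(x, np.zeros_like(x), "uniform_plateau")


class TestFitAlpha:
    @pytest.mark.parametrize("mode,alpha_true", [("compression", 0.07),
                                                 ("retraction", 0.26)])
    def test_recovers_generating_alpha(self, mode, alpha_true):
        """Replacing the data by NPDE output generated at alpha* recovers
        alpha* within 1%."""
        p = NPDEParams(Do=0.74, r0=235.0, V=3.0 * 0.74 / 235.0,
                       alpha=alpha_true)
        times = np.array([0.08, 0.2, 0.4])
        states = _resolve_states(p, mode, times, m_cells=120)
        spec = ConvolutionSpec(0.02)
        data = []
        for t, st in zip(times, states):
            x = np.linspace(st.x1 - 0.3, st.x2 + 0.3, 300)
            u = np.interp(x, st.grid, st.u, left=0.0, right=0.0)
            u = gaussian_convolve(x, u, spec)
            data.append((t, x, u))
        fit = fit_alpha(data, p.with_(alpha=1.0), mode, spec, m_cells=120)
        assert fit.params["alpha"] == pytest.approx(alpha_true, rel=0.01)

    def test_objective_is_local_minimum(self):
        p = NPDEParams(Do=0.74, r0=235.0, V=3.0 * 0.74 / 235.0, alpha=0.1)
        times = np.array([0.15, 0.35])
        states = _resolve_states(p, "compression", times, m_cells=100)
        data = []
        for t, st in zip(times, states):
            x = np.linspace(st.x1 - 0.2, st.x2 + 0.2, 250)
            data.append((t, x, np.interp(x, st.grid, st.u, left=0, right=0)))
        spec = ConvolutionSpec(0.0)
        fit = fit_alpha(data, p.with_(alpha=1.0), "compression", spec,
                        m_cells=100)
        a = fit.params["alpha"]

        def sse(alpha):
            sts = _resolve_states(p.with_(alpha=alpha), "compression",
                                  times, m_cells=100)
            s = 0.0
            for (t, x, u), st in zip(data, sts):
                s += np.sum((np.interp(x, st.grid, st.u, left=0, right=0)
                             - u) ** 2)
            return s

        assert fit.objective <= sse(2 * a) + 1e-12
        assert fit.objective <= sse(a / 2) + 1e-12

    def test_no_profiles_raises(self):
        with pytest.raises(FitError):
            fit_alpha([], NPDEParams(), "compression", ConvolutionSpec(0.0))


class TestFitParabola:
    def test_exact_parabola_recovered(self):
        x = np.linspace(-1, 1, 300)
        cm, xc, w = 2.5, 0.1, 0.55
        c = np.maximum(cm * (1 - ((x - xc) / w) ** 2), 0.0)
        fit = fit_parabola(x, c, fit_sigma=False)
        assert fit.params["cmax"] == pytest.approx(cm, rel=1e-6)
        assert fit.params["center"] == pytest.approx(xc, abs=1e-6)
        assert fit.params["width"] == pytest.approx(w, rel=1e-6)

    def test_noisy_parabola_amplitude_within_3_percent(self):
        rng = np.random.default_rng(42)
        x = np.linspace(-1, 1, 300)
        cm, xc, w = 2.5, 0.0, 0.6
        c = np.maximum(cm * (1 - ((x - xc) / w) ** 2), 0.0)
        noisy = c * (1 + 0.05 * rng.standard_normal(len(c)))
        fit = fit_parabola(x, np.maximum(noisy, 0.0))
        assert fit.params["cmax"] == pytest.approx(cm, rel=0.03)

    def test_flat_profile_raises(self):
        x = np.linspace(-1, 1, 200)
        with pytest.raises(FitError):
            fit_parabola(x, np.ones_like(x))


class TestFitSpeedExponent:
    def test_exact_power_law(self):
        speeds = [0.005, 0.01, 0.02, 0.05]
        ext = {v: 3.0 * v ** -0.5 for v in speeds}
        assert fit_speed_exponent(ext) == pytest.approx(-0.5, abs=1e-12)

    def test_constant_extension(self):
        ext = {v: 7.0 for v in (0.01, 0.02, 0.05)}
        assert fit_speed_exponent(ext) == pytest.approx(0.0, abs=1e-12)

    def test_high_speed_restriction(self):
        ext = {0.01: 50.0, 0.02: 49.0, 0.04: 35.0, 0.08: 35.0 / np.sqrt(2)}
        tail = fit_speed_exponent(ext, n_high=2)
        assert tail == pytest.approx(-0.5, abs=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            fit_speed_exponent({0.01: 1.0, 0.02: 0.9})
        with pytest.raises(ValueError):
            fit_speed_exponent({0.01: 1.0, 0.012: 0.9, 0.014: 0.8})
        with pytest.raises(ValueError):
            fit_speed_exponent({0.01: -1.0, 0.02: 0.9, 0.05: 0.8})
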