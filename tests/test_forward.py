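"""Forward models: inputs, transfer functions, spectra, ERPs, integrator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microdcm import constants as K
from microdcm import cmc, forward
from microdcm.cmc import ModelError, compile_network, fixed_point, rest_network
from microdcm.forward import (NoiseModel, Stimulus, click_train,
                              gaussian_bump_input, integrate_time_domain,
                              powerlaw_input, predict_csd, simulate_erp,
                              transfer_function)


class TestInputSpectra:
    def test_bump_peaks_at_center(self):
        grid = forward.assr_grid()
        inp = gaussian_bump_input(40.0, 4.0, 1.0, grid)
        assert grid[np.argmax(inp.values)] == pytest.approx(40.0)

    def test_width_convention(self):
        grid = np.linspace(30, 50, 201)
        inp = gaussian_bump_input(40.0, 4.0, 1.0, grid)
        at = lambda f: inp.values[np.argmin(np.abs(grid - f))]
        assert at(44.0) / at(40.0) == pytest.approx(np.exp(-0.5), rel=1e-6)

    def test_wider_bump_has_more_relative_power_off_center(self):
        grid = np.linspace(30, 50, 201)
        wide = gaussian_bump_input(40.0, 4.0, 1.0, grid)
        narrow = gaussian_bump_input(40.0, 1.0, 1.0, grid)
        i44 = np.argmin(np.abs(grid - 44.0))
        i40 = np.argmin(np.abs(grid - 40.0))
        assert (wide.values[i44] / wide.values[i40]
                > narrow.values[i44] / narrow.values[i40])

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ModelError, match="width"):
            gaussian_bump_input(40.0, 0.0, 1.0, forward.assr_grid())

    def test_floor_keeps_positivity(self):
        grid = np.linspace(1, 100, 300)
        inp = gaussian_bump_input(40.0, 1.0, 1.0, grid, floor=0.01)
        assert np.all(inp.values > 0)


class TestTransferFunction:
    def test_gain_vanishes_at_high_frequency(self, rest_net):
        H = transfer_function(rest_net, np.array([1.0, 2000.0, 20000.0]))
        assert np.abs(H[1]).max() < 1e-2 * np.abs(H[0]).max()
        assert np.abs(H[2]).max() < 1e-2 * np.abs(H[1]).max()

    def test_single_population_matches_analytic_resonance(self):
        net = rest_network()
        for c in K.INTRINSIC:
            net.set_param(f"ctx.G.{c}", -30.0)
        grid = np.linspace(1, 48, 48)
        H = transfer_function(net, grid)
        kappa = 1.0 / K.T_PRIOR_MS["ss"]
        omega = 2 * np.pi * grid / 1000.0
        analytic = K.J_PRIOR["ss"] * kappa ** 2 / (1j * omega + kappa) ** 2
        np.testing.assert_allclose(H[:, 0, 0], analytic, rtol=1e-6)

    def test_delay_changes_phase_not_magnitude(self):
        grid = forward.rest_grid()
        net1 = rest_network()
        net1.set_param("D.intrinsic", -2.0)       # ~0.14 ms
        net2 = rest_network()
        net2.set_param("D.intrinsic", np.log(10.0))  # 10 ms
        # isolate one delayed path (input -> ss -> sp) and observe sp only,
        # so the magnitude has no interference between delayed paths
        for net in (net1, net2):
            for c in K.INTRINSIC:
                if c != "ss->sp":
                    net.set_param(f"ctx.G.{c}", -30.0)
            for p in ("ss", "dp"):
                net.set_param(f"ctx.J.{p}", -30.0)
        H1 = transfer_function(net1, grid)
        H2 = transfer_function(net2, grid)
        # observed via sp only
        np.testing.assert_allclose(np.abs(H1[:, 0, 0]), np.abs(H2[:, 0, 0]),
                                   rtol=1e-9)
        assert not np.allclose(np.angle(H1[:, 0, 0]),
                               np.angle(H2[:, 0, 0]), atol=1e-3)

    def test_unstable_model_raises_with_eigenvalue(self):
        net = rest_network()
        net.set_param("ctx.G.ii->ii", -2.5)
        net.set_param("ctx.G.sp->ii", 1.0)
        net.set_param("ctx.G.ii->sp", 1.0)
        with pytest.raises(forward.UnstableModelError, match="eigenvalue"):
            transfer_function(net, forward.rest_grid())


class TestPredictCsd:
    def test_zero_input_gives_exactly_the_channel_noise(self, rest_net):
        grid = forward.rest_grid()
        inp = powerlaw_input(0.0, 1.0, grid, floor=0.0)
        noise = NoiseModel(source_white=-50.0, source_pink=-50.0)
        csd = predict_csd(rest_net, inp, noise=noise)
        chan, _ = noise.spectra(grid)
        np.testing.assert_allclose(csd.diagonal[:, 0], chan, rtol=1e-6)

    def test_assr_peak_in_gamma_window(self):
        net, extras = cmc.apply_priors(cmc.assr_network(),
                                       cmc.default_priors("assr", "full"))
        grid = forward.assr_grid()
        inp = gaussian_bump_input(40.0, 4.0, 1.0, grid,
                                  floor=K.ASSR_BUMP_FLOOR)
        csd = predict_csd(net, inp, input_coherence=np.ones((2, 2)))
        peak = grid[np.argmax(csd.diagonal[:, 0])]
        assert 35.0 <= peak <= 45.0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_cross_spectra_hermitian_psd_for_random_parameters(self, seed):
        rng = np.random.default_rng(seed)
        net = cmc.assr_network()
        for a in net.areas:
            for c in ("sp->sp", "ii->ii", "sp->ii", "ii->sp"):
                net.set_param(f"{a}.G.{c}", rng.normal(0, 0.2))
        grid = forward.assr_grid()
        inp = gaussian_bump_input(40.0, 4.0, 1.0, grid, floor=0.05)
        try:
            csd = predict_csd(net, inp, noise=NoiseModel(),
                              input_coherence=np.ones((2, 2)))
        except forward.UnstableModelError:
            return
        assert csd.validate()


class TestIntegrator:
    def test_constant_at_fixed_point_with_zero_drive(self, rest_net):
        x0 = fixed_point(rest_net, 0.0)
        obs, states, xf = integrate_time_domain(
            rest_net, np.zeros((1001, 1)), dt=0.1, x0=x0, store_states=True)
        np.testing.assert_allclose(xf, x0, atol=1e-12)
        assert np.ptp(obs) < 1e-12

    def test_bitwise_deterministic(self, rest_net):
        rng = np.random.default_rng(3)
        drive = rng.standard_normal((2001, 1)) * 0.01
        o1, _, _ = integrate_time_domain(rest_net, drive, dt=0.1)
        o2, _, _ = integrate_time_domain(rest_net, drive, dt=0.1)
        assert np.array_equal(o1, o2)

    def test_divergence_reports_time(self):
        # a step size far beyond the stability limit blows the scheme up
        net = rest_network()
        drive = np.full((2001, 1), 1.0)
        with pytest.raises(forward.DivergenceError, match="ms"):
            integrate_time_domain(net, drive, dt=50.0)

    def test_small_sinusoid_gain_matches_transfer_function(self, rest_net):
        f0 = 40.0
        amp = 1e-4
        dt = 0.05
        t = np.arange(0, 3000 + dt / 2, dt)
        drive = (amp * np.sin(2 * np.pi * f0 * t / 1000.0))[:, None]
        x0 = fixed_point(rest_net, 0.0)
        obs, _, _ = integrate_time_domain(rest_net, drive, dt=dt, x0=x0)
        tail = obs[t > 1500, 0]
        est_gain = (np.max(tail) - np.min(tail)) / 2 / amp
        H = transfer_function(rest_net, np.array([f0]))
        assert est_gain == pytest.approx(abs(H[0, 0, 0]), rel=0.02)

    def test_halving_dt_changes_traces_negligibly(self, rest_net):
        stim = Stimulus()
        net = rest_network()
        net.B["only"] = {}
        a = simulate_erp(net, stim, ("only",), dt=0.2, t_end_ms=300.0)
        b = simulate_erp(net, stim, ("only",), dt=0.1, t_end_ms=300.0)
        x = np.asarray(a.traces["only"])[0]
        y = np.asarray(b.traces["only"])[0][::2]
        scale = np.max(np.abs(y))
        assert np.max(np.abs(x - y)) < 1e-3 * scale


class TestSimulateErp:
    def test_no_modulation_means_identical_conditions(self):
        net = cmc.mmn_network()
        erp = simulate_erp(net, Stimulus(), ("standard", "deviant"), dt=0.2,
                           t_end_ms=300.0)
        np.testing.assert_array_equal(erp.traces["standard"],
                                      erp.traces["deviant"])

    def test_baseline_is_zero(self):
        net = cmc.mmn_network()
        erp = simulate_erp(net, Stimulus(), ("standard",), dt=0.2,
                           t_end_ms=300.0)
        peak = np.max(np.abs(np.asarray(erp.traces["standard"])))
        pre = np.asarray(erp.traces["standard"])[:, erp.t_ms < -50]
        assert np.max(np.abs(pre)) < 1e-4 * peak

    def test_linearity_in_small_stimulus_limit(self):
        net = cmc.mmn_network()
        small = Stimulus(amplitude=1e-4)
        half = Stimulus(amplitude=5e-5)
        e1 = simulate_erp(net, small, ("standard",), dt=0.2, t_end_ms=300.0)
        e2 = simulate_erp(net, half, ("standard",), dt=0.2, t_end_ms=300.0)
        a = np.asarray(e1.traces["standard"])
        b = np.asarray(e2.traces["standard"])
        assert np.max(np.abs(a - 2 * b)) < 0.01 * np.max(np.abs(a))

    def test_click_train_entrains_forty_hz(self):
        net = rest_network()
        net.B["assr"] = {}
        train = click_train(rate_hz=40.0, n_clicks=16, amplitude=0.2)
        erp = simulate_erp(net, train, ("assr",), t_start_ms=-50.0,
                           t_end_ms=450.0, dt=0.2)
        x = np.asarray(erp.traces["assr"])[0]
        sel = (erp.t_ms > 50) & (erp.t_ms < 400)
        seg = x[sel] - x[sel].mean()
        freqs = np.fft.rfftfreq(seg.size, d=0.2e-3)
        spec = np.abs(np.fft.rfft(seg * np.hanning(seg.size))) ** 2
        band = (freqs > 5) & (freqs < 100)
        peak = freqs[band][np.argmax(spec[band])]
        assert abs(peak - 40.0) < 3.0
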