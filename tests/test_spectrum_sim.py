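import numpy as np
import pytest
from scipy.linalg import expm
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

import gluchange as g
from gluchange.spectrum_sim import find_oh_window


def _peak_positions(spectrum, min_prominence_frac=0.05):
    y = np.real(spectrum.intensity)
    peaks, _ = find_peaks(y, prominence=min_prominence_frac * y.max())
    return spectrum.axis_ppm[peaks]


class TestGenerators:
    def test_restricted_dimension_40(self, restricted_spec, params_270K, acq):
        G = g.build_extended_liouvillian(restricted_spec, params_270K, acq)
        assert G.shape == (40, 40)

    def test_single_pool_on_resonance_is_zero(self, water_only_spec, acq):
        params = g.ModelParameters(deltas=np.zeros(0), rates=np.zeros(0))
        G = g.build_extended_liouvillian(water_only_spec, params, acq)
        assert G.shape == (4, 4)
        assert np.abs(G).max() == 0.0

    def test_sq_block_is_bloch_mcconnell(self, symmetric_two_site, acq):
        """The single-quantum block of the 8x8 generator is i*Omega + K."""
        spec, params = symmetric_two_site(0.4, 150.0)
        G = g.build_extended_liouvillian(spec, params, acq)
        n = spec.n_pools
        block = G[2 * n : 3 * n, 2 * n : 3 * n]
        K = g.assemble_exchange_matrix(spec, params).K
        omega = 2 * np.pi * 0.4 * acq.spectrometer_freq_MHz
        expected = K + 1j * np.diag([omega, 0.0])
        assert np.allclose(block, expected, atol=1e-12)
        assert np.allclose(
            block, g.single_quantum_generator(spec, params, acq), atol=1e-12
        )


class TestFid:
    def test_no_exchange_pure_oscillation(self, symmetric_two_site, acq):
        spec, params = symmetric_two_site(2.0, 0.0)
        G = g.build_extended_liouvillian(spec, params, acq)
        fid = g.simulate_fid(G, spec, acq)
        omega = 2 * np.pi * 2.0 * acq.spectrometer_freq_MHz
        expected = 0.5 + 0.5 * np.exp(1j * omega * acq.times_s)
        assert np.abs(fid - expected).max() < 1e-9

    @pytest.mark.parametrize("variant", ["split_anomeric", "restricted"])
    def test_fid_starts_at_unity(self, variant, acq):
        spec = g.build_model(variant)
        rng = np.random.default_rng(2)
        params = g.ModelParameters(
            deltas=rng.uniform(0.7, 2.9, len(spec.non_water_labels)),
            rates=rng.uniform(50, 500, spec.n_rate_groups),
        )
        fid = g.simulate_fid(g.build_extended_liouvillian(spec, params, acq), spec, acq)
        assert abs(fid[0] - 1.0) < 1e-12

    def test_full_vs_reduced_propagation(self, restricted_spec, params_270K, acq):
        """Extended-Liouville FID equals stepwise transverse Bloch-McConnell."""
        G = g.build_extended_liouvillian(restricted_spec, params_270K, acq)
        fid = g.simulate_fid(G, restricted_spec, acq)
        A = g.single_quantum_generator(restricted_spec, params_270K, acq)
        P = expm(A * acq.dwell_s)
        M = restricted_spec.fractions.astype(complex)
        oracle = np.empty(acq.td, dtype=complex)
        for i in range(acq.td):
            oracle[i] = M.sum()
            M = P @ M
        assert np.abs(fid - oracle).max() / np.abs(oracle).max() < 1e-9

    def test_non_finite_generator_rejected(self, symmetric_two_site, acq):
        spec, params = symmetric_two_site(1.0, 100.0)
        G = g.build_extended_liouvillian(spec, params, acq)
        G[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite|overflow"):
            g.simulate_fid(G, spec, acq)


class TestProcessing:
    def test_linewidth_equals_line_broadening(self, symmetric_two_site, acq):
        """A pure line apodized with LB = 1 Hz acquires FWHM 1.0 Hz (+-2%)."""
        spec, params = symmetric_two_site(2.0, 0.0)
        fid = g.simulate_fid(g.build_extended_liouvillian(spec, params, acq), spec, acq)
        spectrum = g.process_fid(fid, acq)
        hz = spectrum.axis_ppm * acq.spectrometer_freq_MHz
        sel = (hz > 985) & (hz < 1015)  # the 2 ppm = 1000 Hz line
        x, y = hz[sel], np.real(spectrum.intensity[sel])

        def lorentzian(x, amp, x0, fwhm, c):
            return amp / (1.0 + ((x - x0) / (fwhm / 2.0)) ** 2) + c

        popt, _ = curve_fit(
            lorentzian, x, y, p0=[y.max(), 1000.0, 1.0, 0.0]
        )
        assert popt[2] == pytest.approx(1.0, rel=0.02)

    def test_axis_and_spacing(self, acq):
        axis = acq.axis_ppm
        assert np.all(np.diff(axis) > 0)
        assert np.allclose(np.diff(axis), acq.sweep_width_ppm / acq.td)

    def test_wrong_fid_length_rejected(self, acq):
        with pytest.raises(ValueError, match="td"):
            g.process_fid(np.ones(10), acq)

    def test_slow_and_fast_exchange_limits(self, symmetric_two_site, acq):
        spec_slow, p_slow = symmetric_two_site(0.4, 1e-6)  # two lines 200 Hz apart
        fid = g.simulate_fid(
            g.build_extended_liouvillian(spec_slow, p_slow, acq), spec_slow, acq
        )
        pos = _peak_positions(g.process_fid(fid, acq))
        assert len(pos) == 2
        assert pos.min() == pytest.approx(0.0, abs=0.02)
        assert pos.max() == pytest.approx(0.4, abs=0.02)
        spec_fast, p_fast = symmetric_two_site(0.4, 1e6)
        fid = g.simulate_fid(
            g.build_extended_liouvillian(spec_fast, p_fast, acq), spec_fast, acq
        )
        pos = _peak_positions(g.process_fid(fid, acq))
        # single line at the population-weighted mean shift (0.5 * 0.4 ppm)
        assert len(pos) == 1
        assert pos[0] == pytest.approx(0.2, abs=0.02)

    def test_two_site_lineshape_matches_closed_form(self, symmetric_two_site, acq):
        """Pointwise match to the symmetric two-site exchange lineshape.

        Oracle: resolvent of the 2x2 transverse system evaluated analytically,
        S(nu) = Re[0.5 (x1 + x2 + 4k) / (x1 x2 + k (x1 + x2))] with
        x_j = i 2 pi (nu - nu_j) + pi LB, times the dwell-normalized scale.
        """
        delta = 0.4  # 200 Hz at 500 MHz
        k = 500.0
        spec, params = symmetric_two_site(delta, k)
        fid = g.simulate_fid(g.build_extended_liouvillian(spec, params, acq), spec, acq)
        spectrum = g.process_fid(fid, acq)
        hz = spectrum.axis_ppm * acq.spectrometer_freq_MHz
        sel = (hz > -300) & (hz < 500)
        nu = hz[sel]
        x1 = 1j * 2 * np.pi * (nu - 0.0) + np.pi * acq.lb_Hz
        x2 = 1j * 2 * np.pi * (nu - delta * acq.spectrometer_freq_MHz) + np.pi * acq.lb_Hz
        oracle = np.real(0.5 * (x1 + x2 + 4 * k) / (x1 * x2 + k * (x1 + x2)))
        oracle /= acq.dwell_s  # continuous FT -> DFT sum scale
        y = np.real(spectrum.intensity[sel])
        assert np.abs(y - oracle).max() < 0.01 * np.abs(y).max()

    def test_coalescence_threshold(self, symmetric_two_site, acq):
        """Peaks merge at k ~ pi * delta_nu / sqrt(2) (+-10%), by brute force."""
        dnu = 200.0
        expected = np.pi * dnu / np.sqrt(2.0)
        merged_at = None
        for k in np.arange(300.0, 620.0, 10.0):
            spec, params = symmetric_two_site(dnu / acq.spectrometer_freq_MHz, k)
            fid = g.simulate_fid(
                g.build_extended_liouvillian(spec, params, acq), spec, acq
            )
            if len(_peak_positions(g.process_fid(fid, acq), 1e-4)) == 1:
                merged_at = k
                break
        assert merged_at is not None
        assert merged_at == pytest.approx(expected, rel=0.10)

    def test_spectrum_integral_conserved_under_exchange(
        self, restricted_spec, params_270K, acq
    ):
        """Exchange conserves total magnetization; no relaxation is modelled."""
        def total(params):
            fid = g.simulate_fid(
                g.build_extended_liouvillian(restricted_spec, params, acq),
                restricted_spec, acq,
            )
            sp = g.process_fid(fid, acq)
            return np.trapezoid(sp.intensity, sp.axis_ppm)

        fast = g.ModelParameters(
            deltas=params_270K.deltas, rates=5.0 * params_270K.rates
        )
        assert total(fast) == pytest.approx(total(params_270K), rel=1e-3)


@pytest.fixture(scope="module")
def paper_like_spectrum(restricted_spec, params_270K, acq):
    fid = g.simulate_fid(
        g.build_extended_liouvillian(restricted_spec, params_270K, acq),
        restricted_spec, acq,
    )
    return g.process_fid(fid, acq)


class TestExtraction:
    def test_window_has_about_3800_points(self, paper_like_spectrum, acq):
        a, b = find_oh_window(paper_like_spectrum, acq)
        assert 3800 * 0.9 <= b - a <= 3800 * 1.1

    def test_unit_integral_before_scale(self, paper_like_spectrum, acq):
        seg = g.apply_baseline_and_extract(paper_like_spectrum, np.zeros(3), 1.0, acq)
        assert np.trapezoid(seg.intensity, seg.axis_ppm) == pytest.approx(1.0, abs=1e-9)

    def test_baseline_additivity(self, paper_like_spectrum, acq):
        window = find_oh_window(paper_like_spectrum, acq)
        poly = np.array([0.05, -0.01, 0.002])
        with_poly = g.apply_baseline_and_extract(
            paper_like_spectrum, poly, 1.1, acq, window
        )
        without = g.apply_baseline_and_extract(
            paper_like_spectrum, np.zeros(3), 1.0, acq, window
        )
        from numpy.polynomial import polynomial as npoly

        residual = with_poly.intensity - npoly.polyval(with_poly.axis_ppm, poly)
        assert np.allclose(residual, 1.1 * without.intensity, atol=1e-12)

    def test_coalesced_spectrum_rejected(self, symmetric_two_site, acq):
        spec, params = symmetric_two_site(0.05, 1e6)  # single line on water
        fid = g.simulate_fid(g.build_extended_liouvillian(spec, params, acq), spec, acq)
        with pytest.raises(ValueError, match="minimum"):
            find_oh_window(g.process_fid(fid, acq), acq)


class TestForwardModel:
    def test_deterministic(self, restricted_spec, params_270K, acq):
        s1 = g.forward_model(params_270K, restricted_spec, acq)
        s2 = g.forward_model(params_270K, restricted_spec, acq)
        assert np.array_equal(s1.intensity, s2.intensity)

    def test_window_path_equals_full_path(self, restricted_spec, params_270K, acq):
        full = g.forward_model(params_270K, restricted_spec, acq)
        fast = g.forward_model(
            params_270K, restricted_spec, acq, window=full.window
        )
        ext = g.forward_model(
            params_270K, restricted_spec, acq, window=full.window, engine="extended"
        )
        scale = np.abs(full.intensity).max()
        assert np.abs(fast.intensity - full.intensity).max() < 1e-9 * scale
        assert np.abs(ext.intensity - fast.intensity).max() < 1e-9 * scale

    def test_c1_features_near_published_shifts(
        self, restricted_spec, params_270K, acq
    ):
        """The two resolved downfield features sit at the anomeric shifts."""
        seg = g.forward_model(params_270K, restricted_spec, acq)
        peaks, _ = find_peaks(seg.intensity, prominence=0.02 * seg.intensity.max())
        pos = seg.axis_ppm[peaks]
        assert np.min(np.abs(pos - 2.116)) < 0.03
        assert np.min(np.abs(pos - 2.835)) < 0.03

    def test_extreme_fast_exchange_flattens_oh_region(
        self, restricted_spec, params_270K, acq
    ):
        slow = g.forward_model(params_270K, restricted_spec, acq)
        a, b = slow.window
        fast_params = g.ModelParameters(
            deltas=params_270K.deltas, rates=1e6 * params_270K.rates
        )
        fid = g.simulate_fid(
            g.build_extended_liouvillian(restricted_spec, fast_params, acq),
            restricted_spec, acq,
        )
        raw_fast = np.real(g.process_fid(fid, acq).intensity[a:b])
        fid0 = g.simulate_fid(
            g.build_extended_liouvillian(restricted_spec, params_270K, acq),
            restricted_spec, acq,
        )
        raw_slow = np.real(g.process_fid(fid0, acq).intensity[a:b])
        axis = acq.axis_ppm[a:b]
        oh = axis >= 0.7  # the -OH region proper (C6 is the first feature)
        smooth = np.polyval(np.polyfit(axis[oh], raw_fast[oh], 2), axis[oh])
        assert np.abs(raw_fast[oh] - smooth).max() < 0.01 * raw_slow.max()

    def test_unknown_engine_rejected(self, restricted_spec, params_270K, acq):
        with pytest.raises(ValueError, match="engine"):
            g.forward_model(params_270K, restricted_spec, acq, engine="magic")
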