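"""Fourier and TV-regularized reconstruction: oracles and round trips."""

import numpy as np
import pytest

from holopollen import (
    ComplexField,
    Hologram,
    OptimConfig,
    ReferenceWave,
    cost_terms,
    estimate_reference,
    forward_hologram,
    fourier_reconstruct,
    gradients,
    make_phantom,
    make_reference,
    sparse_reconstruct,
    wrap_phase,
)
from holopollen.reconstruct import OptimizationError, ReferenceEstimationError


class TestEstimateReference:
    def test_round_trip_recovers_tilt(self):
        ref = ReferenceWave(tilt=(0.0, 0.125), amplitude=1.0)
        holo = forward_hologram(np.zeros((256, 256)), 0.5, ref)
        est = estimate_reference(holo)
        assert est.tilt[0] == pytest.approx(0.0, abs=0.002)
        assert est.tilt[1] == pytest.approx(0.125, abs=0.002)

    def test_zero_tilt_raises(self):
        ref = ReferenceWave(tilt=(0.0, 0.0), amplitude=1.0)
        holo = forward_hologram(np.zeros((128, 128)), 1.0, ref)
        with pytest.raises(ReferenceEstimationError):
            estimate_reference(holo)

    def test_half_plane_convention(self):
        # carrier (1/8, -1/8) and its conjugate map to the positive-row choice
        ref = ReferenceWave(tilt=(0.125, -0.125), amplitude=1.0)
        holo = forward_hologram(np.zeros((128, 128)), 0.5, ref)
        est = estimate_reference(holo)
        assert est.tilt[0] == pytest.approx(0.125, abs=0.002)
        assert est.tilt[1] == pytest.approx(-0.125, abs=0.002)

    def test_amplitude_estimate_on_transparent_background(self, reference):
        phantom = make_phantom("viable", (256, 256), (128, 128), 40, 4.0)
        holo = forward_hologram(phantom.true_phase, 1.0, reference)
        est = estimate_reference(holo)
        assert est.amplitude == pytest.approx(1.0, rel=0.05)


class TestFourierReconstruct:
    def test_constant_object_amplitude_recovered(self):
        ref = ReferenceWave(tilt=(0.0, 0.125), amplitude=1.0)
        holo = forward_hologram(np.zeros((256, 256)), 0.8, ref)
        fld = fourier_reconstruct(holo, ref, 1.0 / 16.0)
        central = np.abs(fld.values[64:192, 64:192])
        assert np.all(np.abs(central - 0.8) < 0.02 * 0.8)

    def test_smooth_gaussian_phase_round_trip(self, reference):
        r = np.hypot(*(np.indices((256, 256)) - 128.0))
        phi = 2.0 * np.exp(-(r**2) / (2 * 20.0**2))
        holo = forward_hologram(phi, 1.0, reference)
        fld = fourier_reconstruct(holo, reference, 1.0 / 16.0)
        w = wrap_phase(fld).values
        rmse = np.sqrt(np.mean((w - phi)[64:192, 64:192] ** 2))
        assert rmse < 0.05

    def test_zero_hologram_gives_zero_field(self, reference):
        holo = Hologram(np.zeros((64, 64)))
        fld = fourier_reconstruct(holo, reference, 1.0 / 16.0)
        assert np.allclose(fld.values, 0.0)

    def test_sideband_dc_overlap_rejected(self, reference):
        holo = Hologram(np.ones((64, 64)))
        with pytest.raises(ValueError):
            fourier_reconstruct(holo, reference, filter_radius=0.3)

    def test_conjugate_reference_gives_conjugate_field(self, reference):
        phantom = make_phantom("viable", (128, 128), (64, 64), 20, 2.0)
        holo = forward_hologram(phantom.true_phase, 1.0, reference)
        conj_ref = ReferenceWave(
            tilt=(-reference.tilt[0], -reference.tilt[1]), amplitude=reference.amplitude
        )
        fld = fourier_reconstruct(holo, reference, 1.0 / 16.0)
        fld_c = fourier_reconstruct(holo, conj_ref, 1.0 / 16.0)
        assert np.allclose(fld_c.values, np.conj(fld.values), atol=1e-10)


class TestCostTerms:
    def test_consistent_object_zeroes_data_term(self, reference):
        phantom = make_phantom("viable", (64, 64), (32, 32), 15, 3.0)
        holo = forward_hologram(phantom.true_phase, 1.0, reference)
        O = np.exp(1j * phantom.true_phase)
        ct = cost_terms(O, reference, holo, epsilon=0.0)
        assert ct.data_term == pytest.approx(0.0, abs=1e-18)

    def test_constant_object_has_zero_tv(self, reference):
        holo = Hologram(np.ones((16, 16)))
        ct = cost_terms(np.full((16, 16), 2.0 + 1.0j), reference, holo, epsilon=0.0)
        assert ct.tv_term == pytest.approx(0.0, abs=1e-15)

    def test_step_image_tv_equals_image_height(self, reference):
        # one unit step per row: TV = N for an N x N half-and-half image
        N = 12
        step = np.zeros((N, N), dtype=complex)
        step[:, N // 2 :] = 1.0
        ct = cost_terms(step, reference, Hologram(np.zeros((N, N))), epsilon=0.0)
        assert ct.tv_term == pytest.approx(N)

    def test_shape_mismatch_rejected(self, reference):
        with pytest.raises(ValueError):
            cost_terms(np.ones((8, 8), complex), reference, Hologram(np.zeros((16, 16))))


class TestGradients:
    def test_consistent_object_zeroes_data_gradient(self, reference):
        phantom = make_phantom("viable", (32, 32), (16, 16), 8, 2.0)
        holo = forward_hologram(phantom.true_phase, 1.0, reference)
        g_data, _ = gradients(np.exp(1j * phantom.true_phase), reference, holo, 1e-6)
        assert np.allclose(g_data, 0.0, atol=1e-12)

    def test_constant_object_zeroes_tv_gradient(self, reference):
        holo = Hologram(np.ones((16, 16)))
        _, g_tv = gradients(np.full((16, 16), 1.5 - 0.5j), reference, holo, 1e-6)
        assert np.allclose(g_tv, 0.0, atol=1e-12)

    def test_nonpositive_epsilon_rejected(self, reference):
        with pytest.raises(ValueError):
            gradients(np.ones((8, 8), complex), reference, Hologram(np.ones((8, 8))), 0.0)

    def test_wirtinger_gradients_match_finite_differences(self, rng):
        # real-cost convention: d cost / d Re(O_q) = 2 Re(grad_q),
        #                       d cost / d Im(O_q) = 2 Im(grad_q)
        shape = (16, 16)
        holo = Hologram(rng.uniform(0, 4, shape))
        ref = ReferenceWave(tilt=(0.125, -0.0625), amplitude=1.3)
        O = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        eps = 1e-3
        g_data, g_tv = gradients(O, ref, holo, eps)
        h = 1e-6
        worst = 0.0
        for _ in range(30):
            i, j = rng.integers(16), rng.integers(16)
            for comp in (1.0, 1j):
                Op, Om = O.copy(), O.copy()
                Op[i, j] += h * comp
                Om[i, j] -= h * comp
                cp = cost_terms(Op, ref, holo, eps)
                cm = cost_terms(Om, ref, holo, eps)
                for term, g in (("data", g_data), ("tv", g_tv)):
                    fp = cp.data_term if term == "data" else cp.tv_term
                    fm = cm.data_term if term == "data" else cm.tv_term
                    fd = (fp - fm) / (2 * h)
                    an = 2 * (g[i, j].real if comp == 1.0 else g[i, j].imag)
                    worst = max(worst, abs(fd - an) / max(abs(fd), 1e-8))
        assert worst < 1e-5


class TestSparseReconstruct:
    def test_fixed_point_at_exact_solution(self, reference):
        phantom = make_phantom("viable", (64, 64), (32, 32), 15, 3.0)
        holo = forward_hologram(phantom.true_phase, 1.0, reference)
        O_true = np.exp(1j * phantom.true_phase)
        cfg = OptimConfig(max_iters=1)
        fld, trace = sparse_reconstruct(holo, reference, cfg, init=O_true)
        rel = np.linalg.norm(fld.values - O_true) / np.linalg.norm(O_true)
        assert rel < cfg.rel_change_tol

    def test_data_term_monotone_and_phase_recovered(self, reference):
        phantom = make_phantom("viable", (128, 128), (64, 64), 30, 3.0)
        holo = forward_hologram(phantom.true_phase, 1.0, reference)
        fld, trace = sparse_reconstruct(holo, reference, OptimConfig(max_iters=60))
        d = [t.data_term for t in trace]
        assert all(d[k + 1] <= d[k] + 1e-9 for k in range(len(d) - 1))
        assert all(t.tv_term >= 0 and np.isfinite(t.tv_term) for t in trace)
        werr = np.angle(fld.values * np.exp(-1j * phantom.true_phase))
        from scipy.ndimage import binary_erosion

        mask = binary_erosion(phantom.true_mask, iterations=2)
        assert np.sqrt(np.mean(werr[mask] ** 2)) < 0.1

    def test_sharp_edge_beats_fourier_baseline(self, reference):
        # cylindrical (sharp-edged) phase profile: the low-pass Fourier
        # method blurs the edge, the TV reconstruction preserves it
        from scipy.ndimage import binary_erosion

        from holopollen import remove_background, unwrap_tie

        r = np.hypot(*(np.indices((128, 128)) - 64.0))
        cyl = np.where(r <= 25, 2.0, 0.0)
        holo = forward_hologram(cyl, 1.0, reference)
        mask = binary_erosion(r <= 25, iterations=2)
        fld_s, _ = sparse_reconstruct(holo, reference, OptimConfig(max_iters=150))
        fld_f = fourier_reconstruct(holo, reference, 1.0 / 16.0)
        err_s = remove_background(unwrap_tie(wrap_phase(fld_s))).values - cyl
        err_f = remove_background(unwrap_tie(wrap_phase(fld_f))).values - cyl
        rmse_s = np.sqrt(np.mean(err_s[mask] ** 2))
        rmse_f = np.sqrt(np.mean(err_f[mask] ** 2))
        assert rmse_s <= rmse_f

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            OptimConfig(max_iters=0)
        with pytest.raises(ValueError):
            OptimConfig(epsilon=0.0)
        with pytest.raises(ValueError):
            OptimConfig(balance_ratio=1.5)
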