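"""Phantom geometry, reference waves, hologram formation, populations."""

import numpy as np
import pytest

from holopollen import (
    Hologram,
    PollenClass,
    ReferenceWave,
    forward_hologram,
    generate_population,
    make_phantom,
    make_reference,
)


class TestMakePhantom:
    def test_hemisphere_profile_endpoints(self):
        ph = make_phantom("viable", (128, 128), (64, 64), 20, 9.0)
        assert ph.true_phase[64, 64] == pytest.approx(9.0)
        assert ph.true_phase[64, 84] == pytest.approx(0.0, abs=1e-12)
        assert not ph.true_phase[~ph.true_mask].any()

    def test_hemisphere_mask_mean_is_two_thirds_peak(self):
        # area mean of sqrt(1-rho^2) over the unit disk = int_0^1 2r*sqrt(1-r^2) dr = 2/3
        peak = 7.5
        ph = make_phantom("viable", (256, 256), (128, 128), 40, peak)
        assert ph.mask_mean_phase == pytest.approx(2.0 / 3.0 * peak, rel=0.01)

    def test_nonviable_interior_plateau_bounded_by_rim(self):
        ph = make_phantom("nonviable", (128, 128), (64, 64), 20, 1.0)
        r = np.hypot(*(np.indices((128, 128)) - 64.0))
        interior = r < 0.7 * 20
        assert ph.true_phase[interior].max() <= 1.0 + 1e-12
        assert ph.rim_phase == 1.0

    def test_edge_softening_preserves_mask_mean(self):
        ph = make_phantom("viable", (256, 256), (128, 128), 60, 9.0, edge_sigma_px=1.0)
        assert ph.mask_mean_phase == pytest.approx(6.0, rel=0.01)
        assert not ph.true_phase[~ph.true_mask].any()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(center=(5, 64), radius=20),  # disk outside bounds
            dict(center=(64, 64), radius=2),  # radius too small
            dict(center=(64, 64), radius=20, peak_phase=-1.0),
        ],
    )
    def test_invalid_geometry_raises(self, kwargs):
        args = dict(label="viable", shape=(128, 128), center=(64, 64), radius=20, peak_phase=5.0)
        args.update(kwargs)
        with pytest.raises(ValueError):
            make_phantom(**args)


class TestMakeReference:
    def test_zero_tilt_is_unity(self):
        fld = make_reference((8, 8), (0.0, 0.0), 1.0)
        assert np.allclose(fld.values, 1.0 + 0.0j)

    def test_half_period_phase_is_pi(self):
        fld = make_reference((8, 8), (0.0, 1.0 / 8.0), 1.0)
        assert fld.values[0, 4] == pytest.approx(-1.0 + 0.0j, abs=1e-12)

    def test_modulus_equals_amplitude(self, rng):
        tilt = tuple(rng.uniform(-0.4, 0.4, 2))
        fld = make_reference((32, 32), tilt, 2.7)
        assert np.allclose(np.abs(fld.values), 2.7)

    def test_nyquist_tilt_rejected(self):
        with pytest.raises(ValueError):
            make_reference((8, 8), (0.5, 0.0), 1.0)


class TestForwardHologram:
    def test_zero_object_gives_constant_reference_intensity(self, reference):
        holo = forward_hologram(np.zeros((32, 32)), 0.0, reference)
        assert np.allclose(holo.values, reference.amplitude**2)

    def test_unit_object_unit_reference_gives_four(self):
        ref = ReferenceWave(tilt=(0.0, 0.0), amplitude=1.0)
        holo = forward_hologram(np.zeros((16, 16)), 1.0, ref)
        assert np.allclose(holo.values, 4.0)

    def test_carrier_fringes_have_expected_profile(self):
        # |1 + exp(i 2π col/8)|^2 = 2 + 2 cos(2π col/8): period 8, min 0, max 4
        ref = ReferenceWave(tilt=(0.0, 1.0 / 8.0), amplitude=1.0)
        holo = forward_hologram(np.zeros((8, 32)), 1.0, ref)
        row = holo.values[0]
        cols = np.arange(32)
        assert np.allclose(row, 2 + 2 * np.cos(2 * np.pi * cols / 8), atol=1e-12)
        assert row.min() == pytest.approx(0.0, abs=1e-12)
        assert row.max() == pytest.approx(4.0, abs=1e-12)

    def test_noiseless_hologram_nonnegative_for_random_fields(self, rng):
        for _ in range(10):
            tilt = tuple(rng.uniform(-0.4, 0.4, 2))
            ref = ReferenceWave(tilt=tilt, amplitude=float(rng.uniform(0.2, 3)))
            phase = rng.uniform(-np.pi, np.pi, (24, 24))
            amp = rng.uniform(0, 2, (24, 24))
            holo = forward_hologram(phase, amp, ref)
            assert holo.values.min() >= 0

    def test_shape_mismatch_rejected(self, reference):
        with pytest.raises(ValueError):
            forward_hologram(np.zeros((8, 8)), np.ones((4, 4))[:, :3], reference)

    def test_fringe_bending_inside_grain(self, hemisphere_hologram, reference):
        # demodulated local fringe phase differs inside the phantom footprint
        holo, phantom = hemisphere_hologram
        from holopollen import fourier_reconstruct, wrap_phase

        fld = fourier_reconstruct(holo, reference, 1.0 / 16.0)
        w = wrap_phase(fld).values
        inside = np.abs(w[phantom.true_mask]).mean()
        outside = np.abs(w[~phantom.true_mask]).mean()
        assert inside > 10 * outside


class TestGeneratePopulation:
    def test_pure_viable_population_hits_target_mean(self):
        pop = generate_population(
            n=10, viable_fraction=1.0, mean_phase_sd=0.0, image_shape=(128, 128),
            radius_range=(80.0, 100.0), seed=3,
        )
        for _, phantom in pop:
            assert phantom.label is PollenClass.VIABLE
            assert phantom.mask_mean_phase == pytest.approx(8.72, rel=0.01)

    def test_same_seed_bitwise_identical(self):
        kw = dict(n=4, image_shape=(64, 64), radius_range=(40, 48), noise_sd=0.1, seed=11)
        a = generate_population(**kw)
        b = generate_population(**kw)
        for (ha, pa), (hb, pb) in zip(a, b):
            assert np.array_equal(ha.values, hb.values)
            assert np.array_equal(pa.true_phase, pb.true_phase)

    def test_class_counts_within_binomial_interval(self):
        pop = generate_population(n=200, viable_fraction=0.5, image_shape=(64, 64),
                                  radius_range=(40, 48), seed=5)
        n_viable = sum(p.label is PollenClass.VIABLE for _, p in pop)
        # central 99% binomial interval for n=200, p=0.5: 100 ± 2.58*sqrt(50)
        assert 82 <= n_viable <= 118

    def test_class_centers_converge(self):
        pop = generate_population(n=150, viable_fraction=0.5, mean_phase_sd=0.4,
                                  image_shape=(64, 64), radius_range=(40, 48), seed=9)
        v = [p.mask_mean_phase for _, p in pop if p.label is PollenClass.VIABLE]
        nv = [p.mask_mean_phase for _, p in pop if p.label is PollenClass.NONVIABLE]
        tol_v = 3 * 0.4 / np.sqrt(len(v))
        tol_nv = 3 * 0.4 / np.sqrt(len(nv))
        assert abs(np.mean(v) - 8.72) < tol_v + 0.05
        assert abs(np.mean(nv) - 4.26) < tol_nv + 0.05

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            generate_population(n=0)
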