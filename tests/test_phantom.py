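"""Digital phantom, k-space simulation, reconstruction and PSF tests."""

import numpy as np
import pytest
import scipy.ndimage as ndi
from dataclasses import replace

from b1sandwich import get_preset, prep_lookup, simulate_acquisition
from b1sandwich.epg import TissueParams
from b1sandwich.mapping import t1_spread
from b1sandwich.phantom import (
    DigitalPhantom,
    end_to_end_map,
    make_phantom,
    psf_fwhm,
    reconstruct,
    resize_fourier,
    simulate_kspace,
)
from conftest import ideal_sattfl


class TestMakePhantom:
    def test_uniform_sphere_structure(self):
        ph = make_phantom("uniform_sphere", (32, 24), seed=0)
        inside = ph.pd_map > 0
        assert inside.any() and not inside.all()
        assert np.unique(ph.t1_map[inside]).size == 1

    def test_deterministic_under_seed(self):
        a = make_phantom("brain_like", (32, 24), seed=5)
        b = make_phantom("brain_like", (32, 24), seed=5)
        assert np.array_equal(a.pd_map, b.pd_map)
        assert np.array_equal(a.b1_field, b.b1_field)

    def test_brain_like_has_long_t1_compartment(self):
        ph = make_phantom("brain_like", (48, 36), seed=0)
        assert np.any(ph.t1_map > 3.5)  # CSF-like ventricles

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            make_phantom("banana", (32, 32))

    def test_eight_channel_fields(self):
        ph = make_phantom("uniform_sphere", (24, 24), seed=1, n_channels=8)
        assert ph.b1_field.shape == (8, 24, 24)
        assert ph.combined_b1().shape == (24, 24)


class TestSimulateKSpace:
    def test_single_voxel_kspace_equals_echo_train(self):
        """Delta-object identity: k-line amplitudes are the echoes directly."""
        nx, ny = 16, 16
        pd = np.zeros((nx, ny))
        pd[nx // 2, ny // 2] = 1.0
        ph = DigitalPhantom(pd, np.full((nx, ny), 2.0), np.full((nx, ny), 0.05),
                            np.ones((nx, ny), dtype=complex), (100.0, 100.0))
        proto = replace(get_preset("2d-sandwich"), n_segments=4, tr_fill_s=None)
        kp = simulate_kspace(ph, proto)
        trains = simulate_acquisition(
            replace(proto, n_lines_per_shot=4, tr_fill_s=None), TissueParams(t1=2.0), 1.0
        )
        order = trains.segment_order
        for s in range(4):
            for e in range(4):
                line = kp.s0_k[:, order[s, e]]
                assert np.allclose(line, trains.s0_echoes[s, e], atol=1e-9)

    def test_prep_disabled_sattfl_pair_identical(self):
        ph = make_phantom("uniform_sphere", (16, 16), seed=0)
        proto = replace(ideal_sattfl(16), alpha_nom_deg=0.0)
        kp = simulate_kspace(ph, proto)
        # the k-space scale is set by the object sum; compare relative to it
        assert np.allclose(kp.s1_k, kp.s0_k, atol=1e-4 * np.abs(kp.s0_k).max())

    def test_partial_fourier_lines_zeroed(self):
        ph = make_phantom("uniform_sphere", (16, 16), seed=0)
        kp = simulate_kspace(ph, replace(get_preset("2d-sandwich"), tr_fill_s=None),
                             partial_fourier=0.75)
        assert (~kp.sampling_mask).sum() == 4
        assert np.all(kp.s0_k[:, ~kp.sampling_mask] == 0)


class TestReconstruct:
    def test_all_ones_kspace_is_delta(self):
        img = reconstruct(np.ones((16, 16), dtype=complex), (16, 16), hanning=False)
        peak = np.unravel_index(np.argmax(np.abs(img)), img.shape)
        assert peak == (8, 8)
        off_peak = np.abs(img).ravel()
        assert np.sum(off_peak > 1e-9) == 1

    def test_linearity(self):
        rng = np.random.default_rng(0)
        k1 = rng.normal(size=(12, 10)) + 1j * rng.normal(size=(12, 10))
        k2 = rng.normal(size=(12, 10)) + 1j * rng.normal(size=(12, 10))
        a, b = 1.7, -0.4 + 0.2j
        lhs = reconstruct(a * k1 + b * k2, (16, 16))
        rhs = a * reconstruct(k1, (16, 16)) + b * reconstruct(k2, (16, 16))
        assert np.max(np.abs(lhs - rhs)) < 1e-10

    def test_pad_smaller_than_matrix_rejected(self):
        with pytest.raises(ValueError):
            reconstruct(np.ones((16, 16), dtype=complex), (8, 8))

    def test_uniform_phantom_round_trip_flat_inside(self):
        ph = make_phantom("uniform_sphere", (32, 32), seed=0)
        obj = ph.pd_map.astype(complex)
        k = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(obj)))
        img = np.abs(reconstruct(k, (32, 32), hanning=False))
        inside = ndi.binary_erosion(ph.pd_map > 0, iterations=2)
        assert np.ptp(img[inside]) / np.mean(img[inside]) < 0.01


class TestPSF:
    def test_hanning_baseline_two_pixels(self):
        """A flat train with the Hanning window gives the ~2 px window PSF."""
        flat = replace(get_preset("2d-sandwich"), alpha_nom_deg=0.0, beta_nom_deg=0.5)
        fwhm = psf_fwhm(flat, TissueParams(t1=100.0, t2=0.05))
        assert fwhm == pytest.approx(2.0, abs=0.1)

    def test_sandwich_blurring_low_at_short_t1(self):
        flat = replace(get_preset("2d-sandwich"), alpha_nom_deg=0.0, beta_nom_deg=0.5)
        base = psf_fwhm(flat, TissueParams(t1=100.0, t2=0.05))
        fwhm = psf_fwhm(get_preset("2d-sandwich"), TissueParams(t1=0.5))
        assert abs(fwhm - base) / base < 0.25

    def test_longer_train_blurs_at_least_as_much(self):
        short = psf_fwhm(get_preset("2d-sandwich"), TissueParams(t1=0.5))
        long_ = psf_fwhm(get_preset("2d-ptx-sandwich"), TissueParams(t1=0.5))
        assert long_ >= short - 0.01


class TestEndToEnd:
    def test_ideal_sattfl_recovers_scaled_b1_field(self):
        """Noise-free uniform phantom: the map is the B1 field times alpha."""
        ph = make_phantom("uniform_sphere", (48, 36), seed=1)
        fmap = end_to_end_map(ph, ideal_sattfl(36))
        ref = np.abs(resize_fourier(np.abs(ph.combined_b1()) * 90.0 * (ph.pd_map > 0), (64, 64)))
        inner = ndi.binary_erosion(fmap.mask, iterations=4)
        err = np.abs(fmap.values - ref)[inner]
        assert np.nanmedian(err) < 1.0
        assert np.nanpercentile(err, 95) < 4.0  # Gibbs ringing near the rim

    def test_prep_disabled_map_is_zero(self):
        ph = make_phantom("uniform_sphere", (32, 24), seed=0)
        proto = replace(ideal_sattfl(24), alpha_nom_deg=0.0)
        fmap = end_to_end_map(ph, proto, zero_pad_to=(32, 32))
        assert np.nanmedian(np.abs(fmap.values[fmap.mask])) < 1.0

    def test_sandwich_agrees_with_sattfl_brain(self):
        """Noise-free scheme agreement: voxel-wise RMSE below 3 degrees."""
        ph = make_phantom("brain_like", (48, 36), seed=3)
        m_sw = end_to_end_map(ph, get_preset("2d-sandwich"))
        m_st = end_to_end_map(ph, get_preset("2d-sattfl"))
        both = m_sw.mask & m_st.mask & ndi.binary_erosion(m_sw.mask, iterations=2)
        rmse = np.sqrt(np.nanmean((m_sw.values[both] - m_st.values[both]) ** 2))
        assert rmse < 3.0

    def test_amplitude_linearity_sattfl(self):
        """Maps at 0.5/1.0/1.5x amplitude rescale onto each other (2 deg)."""
        maps = {}
        for s in (0.5, 1.0, 1.5):
            ph = make_phantom("uniform_sphere", (48, 36), seed=1)
            ph.b1_field[:] = ph.b1_field * s
            maps[s] = end_to_end_map(ph, get_preset("2d-sattfl"))
        inner = ndi.binary_erosion(maps[1.0].mask, iterations=4)
        ref = maps[1.0].values
        for s in (0.5, 1.5):
            scaled = maps[s].values / s
            ok = inner & (maps[s].values > 20) & (maps[s].values < 140) & (ref > 20) & (ref < 140)
            assert np.nanmax(np.abs(scaled - ref)[ok]) < 2.0

    def test_two_compartment_errors_match_t1_spread_prediction(self):
        """Voxel-wise T1 dependence reproduces the forward-simulation spread."""
        ph = make_phantom("two_compartment", (48, 36), seed=0)
        # uniform transmit so every voxel sits at the same nominal flip
        ph.b1_field[:] = 1.0
        proto = get_preset("2d-shorttr")  # the T1-sensitive scheme
        fmap = end_to_end_map(ph, proto)
        inner = ndi.binary_erosion(fmap.mask, iterations=4)
        t1_up = resize_fourier(ph.t1_map, (64, 64)).real > 2.0
        short_t1 = np.nanmedian(fmap.values[inner & ~t1_up])
        long_t1 = np.nanmedian(fmap.values[inner & t1_up])
        lut = prep_lookup(proto)
        from b1sandwich.mapping import forward_curve

        pred = [
            forward_curve(proto, TissueParams(t1=t1), [90.0], lut)[0] for t1 in (0.5, 3.0)
        ]
        assert abs((short_t1 - long_t1) - (pred[0] - pred[1])) < 1.0

    def test_noise_seed_reproducibility(self):
        ph = make_phantom("uniform_sphere", (32, 24), seed=0)
        proto = replace(get_preset("2d-sandwich"), tr_fill_s=None)
        a = end_to_end_map(ph, proto, noise_sd=0.003, seed=12, zero_pad_to=(32, 32))
        b = end_to_end_map(ph, proto, noise_sd=0.003, seed=12, zero_pad_to=(32, 32))
        c = end_to_end_map(ph, proto, noise_sd=0.003, seed=13, zero_pad_to=(32, 32))
        assert np.array_equal(a.values, b.values, equal_nan=True)
        assert not np.array_equal(a.values, c.values, equal_nan=True)
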