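"""Flip-angle extraction, accuracy metrics and pTx combination tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from b1sandwich import (
    FlipAngleMap,
    combine_ptx_maps,
    correct_with_lookup,
    dynamic_range,
    flip_from_ratio,
    forward_curve,
    get_preset,
    mean_cov_reduction,
    prep_lookup,
    simulate_acquisition,
    t1_spread,
    measure_flip,
)
from b1sandwich.epg import TissueParams
from b1sandwich.mapping import accuracy_report
from b1sandwich.pulses import simulate_pulse_response
from conftest import ideal_sattfl


class TestFlipFromRatio:
    @pytest.mark.parametrize(
        "s0,s1,expected",
        [(1.0, 0.5, 60.0), (1.0, 0.0, 90.0), (2.0, -1.0, 120.0)],
    )
    def test_known_ratios(self, s0, s1, expected):
        assert flip_from_ratio(s0, s1) == pytest.approx(expected, abs=1e-9)

    @given(flip=st.floats(0.0, 180.0))
    def test_arccos_cos_identity(self, flip):
        s1 = np.cos(np.deg2rad(flip))
        assert flip_from_ratio(1.0, s1) == pytest.approx(flip, abs=1e-9)

    def test_vanishing_s0_masked_as_nan(self):
        out = flip_from_ratio(np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        assert out[0] == pytest.approx(60.0)
        assert np.isnan(out[1])

    def test_complex_phase_cancels(self):
        ph = np.exp(1j * 1.2)
        assert flip_from_ratio(2.0 * ph, -1.0 * ph) == pytest.approx(120.0, abs=1e-9)


class TestLookupCorrection:
    def test_rect_lookup_equals_arccos(self, rect_lookup):
        for s0, s1 in [(1.0, 0.7), (1.0, -0.4), (0.5, 0.1)]:
            assert correct_with_lookup(s0, s1, rect_lookup) == pytest.approx(
                flip_from_ratio(s0, s1), abs=0.1
            )

    def test_unit_ratio_is_zero_flip(self, rect_lookup, hs8_lookup):
        assert correct_with_lookup(1.0, 1.0, rect_lookup) == pytest.approx(0.0, abs=0.1)
        assert correct_with_lookup(1.0, 1.0, hs8_lookup) == pytest.approx(0.0, abs=0.1)

    def test_hs8_forward_then_invert_round_trip(self, hs8_pulse, hs8_lookup):
        """The nominal flip whose simulated Mz we observe is recovered, and it
        exceeds the naive arccos value in the sub-linear regime."""
        nominal = 170.0
        mz = simulate_pulse_response(hs8_pulse, [nominal / 130.0], [0.0]).mz[0, 0]
        recovered = correct_with_lookup(1.0, mz, hs8_lookup)
        assert recovered == pytest.approx(nominal, abs=0.5)
        assert recovered > flip_from_ratio(1.0, mz)


class TestForwardCurves:
    def test_accurate_at_90_degrees_all_presets(self):
        """K-center measurement is exact mid-range for every 2D scheme."""
        tissue = TissueParams(t1=2.0)
        for name in ["2d-sattfl", "2d-shorttr", "2d-sandwich", "2d-ref-sattfl"]:
            m = forward_curve(get_preset(name), tissue, [90.0], method="kcenter")[0]
            assert m == pytest.approx(90.0, abs=1.0), name

    def test_t1_spread_ordering_at_120(self):
        """Sandwich < satTFL < short-TR in T1 sensitivity at a 120 deg prep."""
        t1s = np.arange(0.5, 3.01, 0.5)
        spreads = {
            name: t1_spread(get_preset(name), 120.0, t1s)
            for name in ["2d-sandwich", "2d-sattfl", "2d-shorttr"]
        }
        assert spreads["2d-sandwich"] < spreads["2d-sattfl"] < spreads["2d-shorttr"]
        assert spreads["2d-sandwich"] < 2.0

    def test_ideal_sattfl_spread_vanishes(self):
        assert t1_spread(ideal_sattfl(), 120.0, [0.5, 1.5, 3.0], method="kcenter") < 0.2

    def test_dynamic_range_ideal_curve(self):
        alphas = np.arange(0.0, 181.0, 2.0)
        assert dynamic_range(alphas, alphas.copy()) == 180.0

    def test_dynamic_range_spacing_guard(self):
        with pytest.raises(ValueError):
            dynamic_range(np.arange(0, 181, 5.0), np.arange(0, 181, 5.0))

    def test_dynamic_range_sandwich_vs_sattfl(self):
        tissue = TissueParams(t1=2.0)
        alphas = np.arange(2.0, 181.0, 2.0)
        dr = {}
        for name in ["2d-sandwich", "2d-sattfl"]:
            m = forward_curve(get_preset(name), tissue, alphas)
            dr[name] = dynamic_range(alphas, m)
        assert 150.0 <= dr["2d-sandwich"] <= 170.0
        assert dr["2d-sattfl"] >= 170.0
        assert dr["2d-sandwich"] < dr["2d-sattfl"]


class TestCoV:
    def test_identical_protocols_zero_reduction(self):
        p = get_preset("2d-shorttr")
        grid = np.array([0.5, 1.5, 3.0])
        alphas = np.array([60.0, 90.0])
        assert mean_cov_reduction(p, p, grid, alphas) == pytest.approx(0.0, abs=1e-9)

    def test_t1_grid_step_invariance(self):
        """The reduction is stable once the T1 grid is <= 0.25 s."""
        ref, new = get_preset("2d-sattfl"), get_preset("2d-sandwich")
        alphas = np.arange(60.0, 121.0, 20.0)
        r1 = mean_cov_reduction(ref, new, np.arange(0.5, 3.01, 0.25), alphas)
        r2 = mean_cov_reduction(ref, new, np.arange(0.5, 3.01, 0.125), alphas)
        assert abs(r1 - r2) < 2.0


class TestAccuracyReport:
    def test_report_shapes_and_csv(self, tmp_path):
        rep = accuracy_report(
            get_preset("2d-sandwich"), [60.0, 90.0], t1_grid_s=[1.0, 2.0]
        )
        assert rep.measured_deg.shape == (2, 2)
        assert np.all(rep.spread_deg >= 0) and np.all(rep.cov >= 0)
        path = tmp_path / "report.csv"
        rep.to_csv(path)
        import pandas as pd

        frame = pd.read_csv(path)
        assert set(frame.columns) == {"alpha_nom_deg", "t1_s", "measured_deg", "bias_deg"}
        assert len(frame) == 4


class TestCombinePtx:
    def test_single_channel_identity(self):
        mag = np.random.default_rng(0).uniform(10, 120, (1, 6, 5))
        rel = np.exp(1j * np.linspace(0, 1, 30).reshape(1, 6, 5))
        assert np.allclose(combine_ptx_maps(mag, rel), mag[0])

    def test_eight_equal_channels_add(self):
        mag = np.full((8, 4, 4), 10.0)
        rel = np.ones((8, 4, 4), dtype=complex)
        assert np.allclose(combine_ptx_maps(mag, rel), 80.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_ptx_maps(np.ones((8, 4, 4)), np.ones((7, 4, 4), dtype=complex))

    def test_matches_map_of_summed_field(self):
        """Combining per-channel maps equals mapping the combined field."""
        from b1sandwich.phantom import make_phantom

        ph = make_phantom("uniform_sphere", (16, 16), seed=2, n_channels=8)
        proto = ideal_sattfl()
        lut = prep_lookup(proto)
        tissue = TissueParams(t1=2.0)
        pts = [(8, 8), (5, 9), (10, 6)]
        for ix, iy in pts:
            chans = ph.b1_field[:, ix, iy]

            def measure(scale):
                tr = simulate_acquisition(proto, tissue, float(scale), lut)
                return measure_flip(tr, lut, "kcenter")

            abs_maps = np.array([measure(abs(c)) for c in chans])
            combined = combine_ptx_maps(abs_maps[:, None], chans[:, None])[0]
            direct = measure(abs(np.sum(chans)))
            assert combined == pytest.approx(direct, abs=1.0)


class TestFlipAngleMapIO:
    def test_nifti_round_trip(self, tmp_path):
        values = np.linspace(0, 120, 20).reshape(4, 5).astype(float)
        mask = values > 30
        fmap = FlipAngleMap(values, mask, nominal_ref_deg=90.0, meta={"scheme": "sandwich"})
        path = tmp_path / "map.nii.gz"
        fmap.to_nifti(path)
        back = FlipAngleMap.from_nifti(path)
        assert np.allclose(back.values, values, atol=1e-5)
        assert np.array_equal(back.mask, mask)
        assert back.nominal_ref_deg == 90.0
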