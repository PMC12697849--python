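"""2-D spectral encodings: hand-computed matrices and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acidmap.encode import encode, gadf, gasf, recurrence_plot, rescale_unit

finite_seqs = st.lists(
    st.floats(min_value=-1e4, max_value=1e4, allow_nan=False),
    min_size=2,
    max_size=40,
).filter(lambda xs: max(xs) - min(xs) > 1e-6)


class TestRescaleUnit:
    def test_endpoints_map_to_unit_interval(self):
        scaled, record, flag = rescale_unit([0.0, 5.0, 10.0])
        np.testing.assert_allclose(scaled, [-1.0, 0.0, 1.0])
        assert record == (0.0, 10.0)
        assert not flag

    def test_full_range_input_unchanged(self):
        x = np.array([-1.0, 0.25, 1.0])
        scaled, _, _ = rescale_unit(x)
        np.testing.assert_allclose(scaled, x)

    def test_constant_sequence_falls_back_to_zeros(self):
        scaled, _, flag = rescale_unit([3.0, 3.0, 3.0])
        assert flag
        np.testing.assert_array_equal(scaled, np.zeros(3))

    @given(finite_seqs)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_invariance(self, xs):
        base, _, _ = rescale_unit(np.array(xs))
        shifted, _, _ = rescale_unit(2.5 * np.array(xs) + 17.0)
        np.testing.assert_allclose(base, shifted, atol=1e-6)


class TestGasf:
    def test_hand_computed_three_point_matrix(self):
        expected = np.array([[1, 0, -1], [0, -1, 0], [-1, 0, 1]], dtype=float)
        np.testing.assert_allclose(gasf([-1.0, 0.0, 1.0]), expected, atol=1e-12)

    def test_all_ones_input_gives_all_ones(self):
        np.testing.assert_allclose(gasf(np.ones(5)), np.ones((5, 5)), atol=1e-12)

    def test_out_of_range_entry_rejected(self):
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            gasf([0.0, 1.5])

    @given(st.lists(st.floats(-1, 1), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_bounds_and_diagonal(self, xs):
        x = np.array(xs)
        g = gasf(x)
        assert np.max(np.abs(g - g.T)) < 1e-9
        assert g.min() >= -1 - 1e-12 and g.max() <= 1 + 1e-12
        np.testing.assert_allclose(np.diag(g), 2 * x**2 - 1, atol=1e-12)


class TestGadf:
    def test_hand_computed_three_point_matrix(self):
        # phi = (pi, pi/2, 0): D_01 = sin(pi - pi/2) = 1, D_02 = sin(pi) = 0,
        # D_12 = sin(pi/2 - 0) = 1; lower triangle by antisymmetry.
        expected = np.array([[0, 1, 0], [-1, 0, 1], [0, -1, 0]], dtype=float)
        np.testing.assert_allclose(
            gadf([-1.0, 0.0, 1.0]), expected, atol=1e-12
        )

    def test_constant_input_gives_zero_matrix(self):
        np.testing.assert_allclose(gadf(np.full(4, 0.3)), np.zeros((4, 4)), atol=1e-12)

    @given(st.lists(st.floats(-1, 1), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry_and_zero_diagonal(self, xs):
        d = gadf(np.array(xs))
        np.testing.assert_allclose(d, -d.T, atol=0)
        np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-12)
        assert np.abs(d).max() <= 1 + 1e-12


class TestRecurrencePlot:
    def test_two_point_matrix(self):
        r, flag = recurrence_plot([0.0, 1.0])
        np.testing.assert_allclose(r, [[1, 0], [0, 1]])
        assert not flag

    def test_hand_computed_three_point_matrix(self):
        r, _ = recurrence_plot([0.0, 1.0, 2.0])
        expected = np.array([[1, 0.5, 0], [0.5, 1, 0.5], [0, 0.5, 1]])
        np.testing.assert_allclose(r, expected)

    def test_constant_sequence_all_ones_with_flag(self):
        r, flag = recurrence_plot(np.full(4, 2.0))
        assert flag
        np.testing.assert_array_equal(r, np.ones((4, 4)))

    @given(finite_seqs)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_unit_diagonal_symmetry_and_bounds(self, xs):
        r, _ = recurrence_plot(np.array(xs))
        np.testing.assert_allclose(np.diag(r), 1.0, atol=0)
        np.testing.assert_allclose(r, r.T, atol=0)
        assert r.min() >= 0.0 and r.max() <= 1.0


class TestEncode:
    def test_channel_order_and_invariants(self, clean_spectrum_ph7):
        img = encode(clean_spectrum_ph7, side=32)
        assert img.channels.shape == (3, 32, 32)
        rp, ga, gd = img.rp, img.gasf, img.gadf
        assert np.allclose(np.diag(rp), 1.0)
        assert np.max(np.abs(ga - ga.T)) < 1e-9
        assert np.max(np.abs(gd + gd.T)) < 1e-12

    def test_no_resampling_when_side_matches(self):
        seq = np.sin(np.linspace(0, 3, 16))
        img = encode(
            np.asarray(seq), side=16
        )
        scaled, _, _ = rescale_unit(seq)
        np.testing.assert_allclose(img.gasf, gasf(scaled), atol=1e-12)

    def test_determinism(self, clean_spectrum_ph7):
        a = encode(clean_spectrum_ph7, side=24)
        b = encode(clean_spectrum_ph7, side=24)
        assert np.array_equal(a.channels, b.channels)

    def test_affine_invariance_of_all_channels(self, clean_spectrum_ph7):
        doubled = clean_spectrum_ph7.copy_with(2.0 * clean_spectrum_ph7.intensities)
        a = encode(clean_spectrum_ph7, side=24)
        b = encode(doubled, side=24)
        np.testing.assert_allclose(a.channels, b.channels, atol=1e-9)

    def test_side_too_small_rejected(self, clean_spectrum_ph7):
        with pytest.raises(ValueError, match="too small"):
            encode(clean_spectrum_ph7, side=4)

    def test_save_load_roundtrip_with_png_dump(self, tmp_path, clean_spectrum_ph7):
        from acidmap.encode import load_image, save_image

        img = encode(clean_spectrum_ph7, side=16, source_id="ph7")
        save_image(img, tmp_path / "img", png_dump=True)
        back = load_image(tmp_path / "img")
        np.testing.assert_array_equal(back.channels, img.channels)
        assert back.source_id == "ph7"
        assert back.rescale_record == img.rescale_record
        for name in ("rp", "gasf", "gadf"):
            assert (tmp_path / "img" / f"{name}.png").exists()
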