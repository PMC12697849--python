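"""Synthetic-spectrum generator: calibration-line fidelity, internal
reference invariance, and specimen-grid statistics."""

import numpy as np
import pytest

from acidmap.simulate import (
    SpecimenSimConfig,
    SpectrumModelParams,
    draw_class_ph,
    generate_dataset,
    generate_specimen,
    generate_spectrum,
)

class TestGenerateSpectrum:
    @pytest.mark.parametrize(
        "ph,expected",
        [(7.0, 2.4565), (2.0, 4.5570), (9.0, 1.6163)],
    )
    def test_noise_free_ratio_matches_calibration_line(
        self, ph, expected, noise_free_params, measured_ratio
    ):
        spec = generate_spectrum(ph, noise_free_params)
        assert measured_ratio(spec) == pytest.approx(expected, abs=1e-3)

    def test_ratio_larger_at_acidic_end(self, noise_free_params, measured_ratio):
        r_acid = measured_ratio(generate_spectrum(2.0, noise_free_params))
        r_base = measured_ratio(generate_spectrum(9.0, noise_free_params))
        assert r_acid > r_base

    def test_reference_band_equals_amplitude_without_baseline(self):
        params = SpectrumModelParams(noise_sd=0.0, baseline_params=())
        spec = generate_spectrum(5.0, params)
        assert spec.intensity_at(520.0) == pytest.approx(1000.0, abs=1e-9)

    def test_reference_band_invariant_across_ph(self, noise_free_params):
        values = [
            generate_spectrum(ph, noise_free_params).intensity_at(520.0)
            for ph in (2.0, 4.5, 7.0, 9.0)
        ]
        assert np.ptp(values) < 1e-9

    def test_measured_ratio_strictly_decreases_with_ph(
        self, noise_free_params, measured_ratio
    ):
        ratios = [
            measured_ratio(generate_spectrum(ph, noise_free_params))
            for ph in np.linspace(2.0, 9.0, 8)
        ]
        assert np.all(np.diff(ratios) < 0)

    def test_out_of_range_ph_warns(self, noise_free_params):
        with pytest.warns(UserWarning, match="outside the calibrated range"):
            generate_spectrum(9.5, noise_free_params)

    def test_ph_beyond_zero_crossing_errors(self, noise_free_params):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="admit pH"):
                generate_spectrum(13.5, noise_free_params)

    def test_true_ph_recorded(self, noise_free_params):
        assert generate_spectrum(6.2, noise_free_params).true_ph == 6.2


class TestGenerateDataset:
    def test_seeded_determinism_bit_for_bit(self, default_params):
        a = generate_dataset(5, "uniform", default_params, seed=42)
        b = generate_dataset(5, "uniform", default_params, seed=42)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.intensities, sb.intensities)
            assert sa.true_ph == sb.true_ph

    def test_uniform_support_respected(self, noise_free_params):
        phs = [
            s.true_ph
            for s in generate_dataset(200, "uniform", noise_free_params, seed=0)
        ]
        assert min(phs) >= 2.0 and max(phs) <= 9.0

    def test_noise_free_points_recover_generating_line(
        self, noise_free_params, measured_ratio
    ):
        """An OLS fit through noise-free spectra returns the generating
        slope to tight tolerance (the points lie on the line)."""
        spectra = generate_dataset(
            40, {"kind": "grid", "values": [2, 3, 4, 5, 6, 7, 8, 9]},
            noise_free_params, seed=0,
        )
        phs = np.array([s.true_ph for s in spectra])
        ratios = np.array([measured_ratio(s) for s in spectra])
        slope, intercept = np.polyfit(phs, ratios, 1)
        assert slope == pytest.approx(-0.4201, abs=1e-6)
        assert intercept == pytest.approx(5.3972, abs=1e-6)

    def test_unsupported_sampling_spec_errors(self, noise_free_params):
        with pytest.raises(ValueError, match="unsupported"):
            generate_dataset(3, {"kind": "cauchy"}, noise_free_params, seed=0)
        with pytest.raises(ValueError, match="n must be"):
            generate_dataset(0, "uniform", noise_free_params, seed=0)


class TestGenerateSpecimen:
    def test_grid_geometry(self):
        cfg = SpecimenSimConfig(grid_rows=6, grid_cols=6, pitch_mm=3.0, seed=1)
        specimen = generate_specimen(cfg, with_spectra=False)
        assert len(specimen.points) == 36
        xs = [p.x_mm for p in specimen.points]
        ys = [p.y_mm for p in specimen.points]
        assert max(xs) - min(xs) == pytest.approx(15.0)
        assert max(ys) - min(ys) == pytest.approx(15.0)

    def test_empty_tumor_region_all_para(self):
        cfg = SpecimenSimConfig(grid_rows=3, grid_cols=3, seed=2)
        specimen = generate_specimen(cfg, with_spectra=False)
        assert all(p.label == "para" for p in specimen.points)

    def test_tumor_cells_labelled(self):
        cfg = SpecimenSimConfig(
            grid_rows=3, grid_cols=3, tumor_region=frozenset({(0, 0)}), seed=3
        )
        specimen = generate_specimen(cfg, with_spectra=False)
        labels = {(p.row, p.col): p.label for p in specimen.points}
        assert labels[(0, 0)] == "tumor"
        assert sum(v == "tumor" for v in labels.values()) == 1

    def test_points_carry_spectra_at_their_ph(self, noise_free_params):
        cfg = SpecimenSimConfig(grid_rows=2, grid_cols=2, seed=4)
        specimen = generate_specimen(cfg, params=noise_free_params)
        for p in specimen.points:
            assert p.spectrum is not None
            assert p.spectrum.true_ph == pytest.approx(p.true_ph)

    def test_seeded_reproducibility(self):
        cfg = SpecimenSimConfig(grid_rows=4, grid_cols=4, seed=7)
        a = generate_specimen(cfg, with_spectra=False)
        b = generate_specimen(cfg, with_spectra=False)
        assert [p.true_ph for p in a.points] == [p.true_ph for p in b.points]

    def test_invalid_tumor_cell_rejected(self):
        with pytest.raises(ValueError, match="outside the grid"):
            SpecimenSimConfig(grid_rows=2, grid_cols=2,
                              tumor_region=frozenset({(5, 0)}))

    def test_class_distribution_recovery(self):
        """Large draws recover the configured truncated-normal means
        (tolerance 3 standard errors; truncation to [2, 9] barely moves
        the tumor mean)."""
        cfg = SpecimenSimConfig()
        tumor = draw_class_ph("tumor", 10_000, cfg, rng=11)
        para = draw_class_ph("para", 10_000, cfg, rng=12)
        assert tumor.mean() == pytest.approx(7.056, abs=0.02)
        se = para.std() / np.sqrt(para.size)
        # para-tumor mean shifts slightly upward under truncation at 2.0
        assert abs(para.mean() - 6.046) < max(3 * se, 0.03)
        assert tumor.min() >= 2.0 and tumor.max() <= 9.0
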