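"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import pytest

from acidmap.preprocess import PreprocessOptions, extract_ratio, preprocess
from acidmap.simulate import SpectrumModelParams, generate_spectrum


@pytest.fixture(scope="session")
def noise_free_params() -> SpectrumModelParams:
    return SpectrumModelParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def default_params() -> SpectrumModelParams:
    return SpectrumModelParams()


@pytest.fixture(scope="session")
def clean_spectrum_ph7(noise_free_params):
    """Noise-free synthetic spectrum at pH 7.0 (baseline included)."""
    return generate_spectrum(7.0, noise_free_params)


@pytest.fixture(scope="session")
def measured_ratio():
    """Measured peak ratio through the standard pipeline."""

    def _measure(spectrum, options: PreprocessOptions | None = None) -> float:
        return extract_ratio(preprocess(spectrum, options)).ratio

    return _measure


def line_ratio(ph: float) -> float:
    """The generating calibration line (ratio as a function of pH)."""
    return -0.4201 * ph + 5.3972
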