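"""Synthetic SERS spectra and virtual specimen grids.

The generator emulates the empirical behaviour of a ratiometric pH-sensing
SERS microarray: a pH-responsive Lorentzian band near 303 cm^-1, a
pH-invariant internal-reference band near 520 cm^-1, a smooth
fluorescence-like additive baseline, and i.i.d. Gaussian intensity noise.
Band amplitudes are solved so that the ratio measured by the package's own
default preprocessing + windowed-maximum extraction equals the calibration
line ``ratio = calib_slope * pH + calib_intercept`` exactly at zero noise —
the generator targets the measurement, not an idealised continuous profile,
so sampling-grid and smoothing effects cannot bias the calibration.

Virtual specimens draw per-point pH from truncated normal class
distributions (tumor 7.056 +/- 0.4138, para-tumor 6.046 +/- 0.8352 by
default) on a rectangular grid at 3.0 mm pitch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.stats import truncnorm

from .preprocess import PreprocessOptions, extract_ratio, preprocess
from .spectrum import RamanSpectrum

__all__ = [
    "SpectrumModelParams",
    "SpecimenSimConfig",
    "SpecimenPoint",
    "Specimen",
    "generate_spectrum",
    "generate_specimen",
    "generate_dataset",
    "CALIB_SLOPE",
    "CALIB_INTERCEPT",
    "TUMOR_PH_MEAN",
    "TUMOR_PH_SD",
    "PARATUMOR_PH_MEAN",
    "PARATUMOR_PH_SD",
]

#: Calibration line of the ratiometric sensor: ratio = slope * pH + intercept.
CALIB_SLOPE = -0.4201
CALIB_INTERCEPT = 5.3972

#: Class-conditional pH distributions observed on resected specimens.
TUMOR_PH_MEAN = 7.056
TUMOR_PH_SD = 0.4138
PARATUMOR_PH_MEAN = 6.046
PARATUMOR_PH_SD = 0.8352

PH_BOUNDS = (2.0, 9.0)


@dataclass(frozen=True)
class SpectrumModelParams:
    """Forward model of one synthetic spectrum.

    The spectral axis (200-1800 cm^-1 at 2 cm^-1) covers both reporter
    bands; Lorentzian profiles with 15 cm^-1 FWHM are typical of SERS bands.
    ``noise_sd`` is additive zero-mean Gaussian intensity noise; the default
    yields a ratiometric pH scatter of roughly 0.1 pH units at mid-range.
    """

    axis_min: float = 200.0
    axis_max: float = 1800.0
    axis_step: float = 2.0
    peak1_center: float = 303.0
    peak2_center: float = 520.0
    peak_fwhm: float = 15.0
    peak2_amplitude: float = 1000.0
    baseline_params: tuple[float, ...] = (80.0, -60.0, 40.0)
    noise_sd: float = 5.5
    calib_slope: float = CALIB_SLOPE
    calib_intercept: float = CALIB_INTERCEPT

    def __post_init__(self) -> None:
        if not (self.axis_min < self.peak1_center < self.peak2_center < self.axis_max):
            raise ValueError(
                "require axis_min < peak1_center < peak2_center < axis_max"
            )
        if self.axis_step <= 0:
            raise ValueError("axis_step must be > 0")
        if self.peak_fwhm <= 0:
            raise ValueError("peak_fwhm must be > 0")
        if self.peak2_amplitude <= 0:
            raise ValueError("peak2_amplitude must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.calib_slope >= 0:
            raise ValueError("calib_slope must be negative (ratio falls with pH)")

    @property
    def wavenumbers(self) -> np.ndarray:
        n = int(np.floor((self.axis_max - self.axis_min) / self.axis_step)) + 1
        return self.axis_min + self.axis_step * np.arange(n)

    def target_ratio(self, ph: float) -> float:
        return self.calib_slope * ph + self.calib_intercept

    @property
    def ph_upper_limit(self) -> float:
        """pH at which the calibration line crosses zero ratio."""
        return -self.calib_intercept / self.calib_slope

    def baseline(self, wavenumbers: np.ndarray) -> np.ndarray:
        u = (wavenumbers - self.axis_min) / (self.axis_max - self.axis_min)
        out = np.zeros_like(u)
        for k, coef in enumerate(self.baseline_params):
            out += coef * u**k
        return out


def _lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    hwhm_sq = (fwhm / 2.0) ** 2
    return hwhm_sq / ((x - center) ** 2 + hwhm_sq)


def _clean_profile(
    params: SpectrumModelParams, a1: float, a2: float
) -> np.ndarray:
    wn = params.wavenumbers
    return (
        params.baseline(wn)
        + a1 * _lorentzian(wn, params.peak1_center, params.peak_fwhm)
        + a2 * _lorentzian(wn, params.peak2_center, params.peak_fwhm)
    )


def _reference_amplitude(params: SpectrumModelParams, a1: float) -> float:
    """Peak-2 amplitude keeping the raw intensity at the reference band's
    nearest axis position exactly ``peak2_amplitude``, independent of pH."""
    wn = params.wavenumbers
    g2 = wn[np.argmin(np.abs(wn - params.peak2_center))]
    tail1 = float(_lorentzian(np.array([g2]), params.peak1_center, params.peak_fwhm)[0])
    self2 = float(_lorentzian(np.array([g2]), params.peak2_center, params.peak_fwhm)[0])
    return (params.peak2_amplitude - a1 * tail1) / self2


def _measured_ratio(
    params: SpectrumModelParams, a1: float, options: PreprocessOptions
) -> float:
    a2 = _reference_amplitude(params, a1)
    spec = RamanSpectrum(params.wavenumbers, _clean_profile(params, a1, a2))
    return extract_ratio(preprocess(spec, options)).ratio


def _solve_amplitudes(
    params: SpectrumModelParams, ph: float, options: PreprocessOptions
) -> tuple[float, float]:
    """Solve the responsive-band amplitude so the pipeline-measured ratio
    equals the calibration line at ``ph`` (multiplicative fixed point; the
    measured ratio is almost exactly inversely proportional to a1)."""
    r = params.target_ratio(ph)
    if r <= 0:
        raise ValueError(
            f"target ratio {r:.4f} is non-positive at pH {ph:g}; the chosen "
            f"calibration coefficients admit pH < {params.ph_upper_limit:.3f}"
        )
    a1 = params.peak2_amplitude / r
    for _ in range(20):
        measured = _measured_ratio(params, a1, options)
        if abs(measured - r) <= 1e-10 * r:
            break
        a1 *= measured / r
    return a1, _reference_amplitude(params, a1)


def generate_spectrum(
    ph: float,
    params: SpectrumModelParams | None = None,
    seed: int | np.random.Generator = 0,
    options: PreprocessOptions | None = None,
) -> RamanSpectrum:
    """Generate one synthetic spectrum whose measured peak ratio follows the
    calibration line at ``ph`` (up to additive noise).

    ``options`` selects the preprocessing recipe the amplitude calibration
    targets; by default the package's standard recipe.
    """
    params = params or SpectrumModelParams()
    options = options or PreprocessOptions()
    lo, hi = PH_BOUNDS
    if not (lo <= ph <= hi):
        warnings.warn(
            f"pH {ph:g} is outside the calibrated range [{lo}, {hi}]",
            stacklevel=2,
        )
    a1, a2 = _solve_amplitudes(params, ph, options)
    intensities = _clean_profile(params, a1, a2)
    if params.noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        intensities = intensities + rng.normal(0.0, params.noise_sd, intensities.size)
    return RamanSpectrum(
        wavenumbers=params.wavenumbers,
        intensities=intensities,
        meta={"laser_nm": 785, "acquisition_ms": 500, "synthetic": True},
        true_ph=float(ph),
    )


# ---------------------------------------------------------------------------
# Virtual specimens
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpecimenSimConfig:
    """Virtual specimen: grid geometry, tumor region and pH distributions."""

    grid_rows: int = 6
    grid_cols: int = 6
    pitch_mm: float = 3.0
    tumor_region: frozenset[tuple[int, int]] = frozenset()
    tumor_ph_mean: float = TUMOR_PH_MEAN
    tumor_ph_sd: float = TUMOR_PH_SD
    paratumor_ph_mean: float = PARATUMOR_PH_MEAN
    paratumor_ph_sd: float = PARATUMOR_PH_SD
    ph_bounds: tuple[float, float] = PH_BOUNDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows * self.grid_cols < 1:
            raise ValueError("grid must contain at least one cell")
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be > 0")
        for r, c in self.tumor_region:
            if not (0 <= r < self.grid_rows and 0 <= c < self.grid_cols):
                raise ValueError(f"tumor cell ({r}, {c}) is outside the grid")
        lo, hi = self.ph_bounds
        for name, mean in (
            ("tumor_ph_mean", self.tumor_ph_mean),
            ("paratumor_ph_mean", self.paratumor_ph_mean),
        ):
            if not (lo <= mean <= hi):
                raise ValueError(f"{name}={mean} outside ph_bounds {self.ph_bounds}")
        if self.tumor_ph_sd <= 0 or self.paratumor_ph_sd <= 0:
            raise ValueError("pH standard deviations must be > 0")


@dataclass
class SpecimenPoint:
    """One grid measurement point of a virtual specimen."""

    row: int
    col: int
    x_mm: float
    y_mm: float
    true_ph: float
    label: str  # "tumor" | "para"
    spectrum: RamanSpectrum | None = None


@dataclass
class Specimen:
    """A complete virtual specimen: one labelled point per grid cell."""

    points: list[SpecimenPoint]
    grid_rows: int
    grid_cols: int
    pitch_mm: float
    specimen_id: str = "specimen-0"

    def ph_array(self) -> np.ndarray:
        arr = np.full((self.grid_rows, self.grid_cols), np.nan)
        for p in self.points:
            arr[p.row, p.col] = p.true_ph
        return arr


def _truncated_normal(
    mean: float,
    sd: float,
    bounds: tuple[float, float],
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    a = (bounds[0] - mean) / sd
    b = (bounds[1] - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def draw_class_ph(
    label: str,
    size: int,
    config: SpecimenSimConfig | None = None,
    rng: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw pH values from one class-conditional truncated normal."""
    config = config or SpecimenSimConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if label == "tumor":
        return _truncated_normal(
            config.tumor_ph_mean, config.tumor_ph_sd, config.ph_bounds, size, rng
        )
    if label == "para":
        return _truncated_normal(
            config.paratumor_ph_mean, config.paratumor_ph_sd, config.ph_bounds, size, rng
        )
    raise ValueError(f"unknown class label {label!r}")


def generate_specimen(
    config: SpecimenSimConfig | None = None,
    params: SpectrumModelParams | None = None,
    with_spectra: bool = True,
    specimen_id: str = "specimen-0",
) -> Specimen:
    """Generate a virtual specimen: one pH draw (and optionally one
    spectrum) per grid cell.

    Tumor cells draw from the tumor distribution, all other cells from the
    para-tumor distribution; both truncated to ``ph_bounds``. Ground-truth
    pH attaches to the point, not to any particular noise realisation of
    its spectrum.
    """
    config = config or SpecimenSimConfig()
    params = params or SpectrumModelParams()
    rng = np.random.default_rng(config.seed)
    n = config.grid_rows * config.grid_cols
    if n < 1:
        raise ValueError("empty grid")
    tumor = np.zeros((config.grid_rows, config.grid_cols), dtype=bool)
    for r, c in config.tumor_region:
        tumor[r, c] = True
    # One vectorised draw per class keeps the stream reproducible and cheap.
    n_tumor = int(tumor.sum())
    tumor_ph = _truncated_normal(
        config.tumor_ph_mean, config.tumor_ph_sd, config.ph_bounds, n_tumor, rng
    )
    para_ph = _truncated_normal(
        config.paratumor_ph_mean,
        config.paratumor_ph_sd,
        config.ph_bounds,
        n - n_tumor,
        rng,
    )
    points: list[SpecimenPoint] = []
    it, ip = 0, 0
    for r in range(config.grid_rows):
        for c in range(config.grid_cols):
            if tumor[r, c]:
                ph, label = float(tumor_ph[it]), "tumor"
                it += 1
            else:
                ph, label = float(para_ph[ip]), "para"
                ip += 1
            spec = None
            if with_spectra:
                spec = generate_spectrum(ph, params, seed=rng)
            points.append(
                SpecimenPoint(
                    row=r,
                    col=c,
                    x_mm=c * config.pitch_mm,
                    y_mm=r * config.pitch_mm,
                    true_ph=ph,
                    label=label,
                    spectrum=spec,
                )
            )
    return Specimen(
        points=points,
        grid_rows=config.grid_rows,
        grid_cols=config.grid_cols,
        pitch_mm=config.pitch_mm,
        specimen_id=specimen_id,
    )


def _sample_ph(
    spec: str | dict[str, Any], n: int, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = PH_BOUNDS
    if isinstance(spec, str):
        spec = {"kind": spec}
    if not isinstance(spec, dict) or "kind" not in spec:
        raise ValueError(f"unsupported pH sampling spec: {spec!r}")
    kind = spec["kind"]
    if kind == "uniform":
        low = float(spec.get("low", lo))
        high = float(spec.get("high", hi))
        if not (lo <= low < high <= hi):
            raise ValueError(f"uniform bounds [{low}, {high}] outside [{lo}, {hi}]")
        return rng.uniform(low, high, n)
    if kind == "normal":
        return _truncated_normal(
            float(spec["mean"]), float(spec["sd"]), (lo, hi), n, rng
        )
    if kind == "grid":
        values = np.asarray(spec["values"], dtype=float)
        if values.size == 0:
            raise ValueError("grid sampling spec needs at least one value")
        return values[np.arange(n) % values.size]
    raise ValueError(f"unsupported pH sampling kind: {kind!r}")


def generate_dataset(
    n: int,
    ph_sampling: str | dict[str, Any] = "uniform",
    params: SpectrumModelParams | None = None,
    seed: int = 0,
) -> list[RamanSpectrum]:
    """Generate ``n`` pH-labelled spectra with pH drawn from a sampling spec.

    Supported specs: ``"uniform"`` (optionally with ``low``/``high``),
    ``{"kind": "normal", "mean": m, "sd": s}`` (truncated to [2, 9]) and
    ``{"kind": "grid", "values": [...]}`` (cycled). Deterministic under a
    fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or SpectrumModelParams()
    rng = np.random.default_rng(seed)
    phs = _sample_ph(ph_sampling, n, rng)
    return [generate_spectrum(float(ph), params, seed=rng) for ph in phs]
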