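"""Core spectral container.

A :class:`RamanSpectrum` is the unit of data flowing through the whole
package: a strictly increasing wavenumber axis (cm^-1), one intensity per
axis position, free-form acquisition metadata and — for synthetic spectra —
the ground-truth pH the spectrum was generated at.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["RamanSpectrum", "resample"]


@dataclass
class RamanSpectrum:
    """One sampled Raman spectrum.

    Parameters
    ----------
    wavenumbers : array-like
        Raman shift axis in cm^-1, strictly increasing.
    intensities : array-like
        Intensity at each axis position (arbitrary units); same length as
        the axis and finite everywhere.
    meta : dict
        Acquisition descriptors (e.g. laser wavelength, integration time).
        Purely informational.
    true_ph : float or None
        Ground-truth pH for synthetic spectra; ``None`` for measured data.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)
    true_ph: float | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise ValueError(
                f"axis length {self.wavenumbers.size} != intensity length "
                f"{self.intensities.size}"
            )
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def copy_with(self, intensities: np.ndarray) -> "RamanSpectrum":
        """Return a new spectrum on the same axis with replaced intensities."""
        return RamanSpectrum(
            wavenumbers=self.wavenumbers.copy(),
            intensities=np.asarray(intensities, dtype=float),
            meta=dict(self.meta),
            true_ph=self.true_ph,
        )

    def intensity_at(self, wavenumber: float) -> float:
        """Intensity at the axis position nearest ``wavenumber``."""
        idx = int(np.argmin(np.abs(self.wavenumbers - wavenumber)))
        return float(self.intensities[idx])


def resample(values: np.ndarray, length: int) -> np.ndarray:
    """Linearly interpolate a sequence onto ``length`` evenly spaced positions.

    Used both by the 2-D encoder (to square the image side) and by the
    network's 1-D branch (fixed input width).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D sequence of length >= 2")
    if length < 2:
        raise ValueError("target length must be >= 2")
    if length == values.size:
        return values.copy()
    old = np.linspace(0.0, 1.0, values.size)
    new = np.linspace(0.0, 1.0, length)
    return np.interp(new, old, values)
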