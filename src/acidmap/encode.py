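"""Imaging a 1-D spectrum as a 3-channel 2-D field.

A spectrum's intensity sequence is turned into three square matrices that
expose its self-similarity structure to a convolutional backbone:

* recurrence plot (RP) — unthresholded, globally normalised pairwise
  similarity ``R_ij = 1 - |x_i - x_j| / max |x_a - x_b|``;
* Gramian angular summation field (GASF) — ``cos(phi_i + phi_j)`` with
  ``phi = arccos`` of the sequence rescaled into [-1, 1];
* Gramian angular difference field (GADF) — ``sin(phi_i - phi_j)``.

All three are invariant to positive affine transforms of the intensities,
so detector gain and offset cannot leak into the image representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .spectrum import RamanSpectrum, resample

__all__ = [
    "SpectralImage",
    "rescale_unit",
    "gasf",
    "gadf",
    "recurrence_plot",
    "encode",
    "save_image",
    "load_image",
]

_CLIP_TOL = 1e-9


@dataclass
class SpectralImage:
    """3-channel square image of one spectrum (channels: RP, GASF, GADF)."""

    channels: np.ndarray  # (3, L, L)
    source_id: str = ""
    rescale_record: tuple[float, float] | None = None  # (min, max) of raw seq
    flags: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ValueError("channels must have shape (3, L, L)")
        if self.channels.shape[1] != self.channels.shape[2]:
            raise ValueError("channel matrices must be square")

    @property
    def side(self) -> int:
        return int(self.channels.shape[1])

    @property
    def rp(self) -> np.ndarray:
        return self.channels[0]

    @property
    def gasf(self) -> np.ndarray:
        return self.channels[1]

    @property
    def gadf(self) -> np.ndarray:
        return self.channels[2]


def rescale_unit(x) -> tuple[np.ndarray, tuple[float, float], bool]:
    """Affine map of ``[min(x), max(x)]`` onto ``[-1, 1]``.

    Returns ``(rescaled, (min, max), constant_flag)``. A constant sequence
    has no span to map; the defined fallback is all zeros with the flag set.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sequence of length >= 2")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x), (lo, hi), True
    scaled = 2.0 * (x - lo) / (hi - lo) - 1.0
    return scaled, (lo, hi), False


def _angles(x_scaled: np.ndarray) -> np.ndarray:
    x = np.asarray(x_scaled, dtype=float)
    if np.any(np.abs(x) > 1.0 + _CLIP_TOL):
        worst = float(np.max(np.abs(x)))
        raise ValueError(
            f"rescaled values must lie in [-1, 1]; found magnitude {worst}"
        )
    return np.arccos(np.clip(x, -1.0, 1.0))


def gasf(x_scaled) -> np.ndarray:
    """Gramian angular summation field ``cos(phi_i + phi_j)``.

    The diagonal equals ``2 x_i^2 - 1`` (double-angle identity) and the
    matrix is symmetric with entries in [-1, 1].
    """
    phi = _angles(x_scaled)
    return np.cos(phi[:, None] + phi[None, :])


def gadf(x_scaled) -> np.ndarray:
    """Gramian angular difference field ``sin(phi_i - phi_j)``:
    antisymmetric with a zero diagonal."""
    phi = _angles(x_scaled)
    return np.sin(phi[:, None] - phi[None, :])


def recurrence_plot(x) -> tuple[np.ndarray, bool]:
    """Unthresholded recurrence matrix of pairwise similarity.

    ``R_ij = 1 - |x_i - x_j| / max_ab |x_a - x_b|``: symmetric, unit
    diagonal, entries in [0, 1]. No embedding, no threshold — the globally
    normalised similarity form has no free parameters. A constant sequence
    yields the all-ones matrix with the degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sequence of length >= 2")
    dist = np.abs(x[:, None] - x[None, :])
    dmax = float(dist.max())
    if dmax == 0.0:
        return np.ones((x.size, x.size)), True
    return 1.0 - dist / dmax, False


def encode(
    spectrum: RamanSpectrum | np.ndarray,
    side: int = 224,
    source_id: str = "",
) -> SpectralImage:
    """Encode a spectrum as an ``(3, side, side)`` image.

    The intensity sequence is linearly resampled to ``side`` positions,
    then the RP, GASF and GADF matrices are stacked as channels (in that
    order). Fully deterministic.
    """
    if side < 8:
        raise ValueError(f"image side {side} too small; need >= 8")
    values = (
        spectrum.intensities
        if isinstance(spectrum, RamanSpectrum)
        else np.asarray(spectrum, dtype=float)
    )
    seq = resample(values, side)
    scaled, record, constant = rescale_unit(seq)
    rp, rp_degenerate = recurrence_plot(seq)
    image = np.stack([rp, gasf(scaled), gadf(scaled)])
    return SpectralImage(
        channels=image,
        source_id=source_id,
        rescale_record=record,
        flags={"constant_input": constant or rp_degenerate},
    )


def save_image(
    image: SpectralImage, directory, png_dump: bool = False
) -> None:
    """Persist an encoding: channels as an ``.npy`` array with a JSON
    sidecar; optionally one 8-bit PNG per channel for visual inspection
    (channels linearly mapped onto 0-255)."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "channels.npy", image.channels)
    meta = {
        "source_id": image.source_id,
        "rescale_record": list(image.rescale_record)
        if image.rescale_record
        else None,
        "flags": image.flags,
        "channel_order": ["rp", "gasf", "gadf"],
        "side": image.side,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    if png_dump:
        from PIL import Image as PILImage

        for name, chan in zip(("rp", "gasf", "gadf"), image.channels):
            lo, hi = float(chan.min()), float(chan.max())
            span = hi - lo if hi > lo else 1.0
            arr = np.round(255 * (chan - lo) / span).astype(np.uint8)
            PILImage.fromarray(arr, mode="L").save(directory / f"{name}.png")


def load_image(directory) -> SpectralImage:
    import json
    from pathlib import Path

    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    record = meta.get("rescale_record")
    return SpectralImage(
        channels=np.load(directory / "channels.npy"),
        source_id=meta.get("source_id", ""),
        rescale_record=tuple(record) if record else None,
        flags=meta.get("flags", {}),
    )
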