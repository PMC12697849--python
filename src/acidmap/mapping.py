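"""pH topographic maps of specimens.

Per-point pH predictions on a rectangular sampling grid (3.0 mm pitch by
default) are assembled into a validated map, thresholded into
tumor-suspect / non-suspect regions, and rendered as a color overlay:
green-family cells for faintly acidic (pH at or above the diagnostic
threshold, the tumor-suspect side) and red-family cells for strongly
acidic mucosa.

Grid convention: 0-based (row, col); x grows rightward with column, y grows
downward with row, both from the specimen's top-left; a point's nominal
position is (col * pitch, row * pitch).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw
from scipy import ndimage

__all__ = [
    "PHPoint",
    "PHMap",
    "DiagnosticThreshold",
    "RegionSet",
    "build_map",
    "classify_map",
    "render_map",
    "THRESHOLD_PRESETS",
]

#: Published diagnostic thresholds by provenance.
THRESHOLD_PRESETS = {
    "animal": 6.735,
    "clinical-classical": 6.855,
    "clinical-ai": 6.845,
}


@dataclass(frozen=True)
class DiagnosticThreshold:
    """A pH cutoff with its provenance (a preset name or "fitted")."""

    value: float
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        if not (2.0 <= self.value <= 9.0):
            raise ValueError(f"threshold {self.value} outside plausible pH range")

    @classmethod
    def preset(cls, name: str) -> "DiagnosticThreshold":
        if name not in THRESHOLD_PRESETS:
            raise KeyError(
                f"unknown preset {name!r}; choose from {sorted(THRESHOLD_PRESETS)}"
            )
        return cls(value=THRESHOLD_PRESETS[name], provenance=name)


@dataclass(frozen=True)
class PHPoint:
    """One measured/predicted point of a specimen map."""

    row: int
    col: int
    ph: float
    source: str = "ratiometric"  # "ratiometric" | "model"
    label: str | None = None  # optional ground truth: "tumor" | "para"

    def __post_init__(self) -> None:
        if not np.isfinite(self.ph):
            raise ValueError("pH must be finite")
        if self.row < 0 or self.col < 0:
            raise ValueError("grid indices are 0-based and nonnegative")


class PHMap:
    """A complete rectangular grid of pH points."""

    def __init__(
        self,
        points: Sequence[PHPoint],
        pitch_mm: float,
        specimen_id: str = "specimen-0",
    ):
        if pitch_mm <= 0:
            raise ValueError("pitch must be > 0")
        if not points:
            raise ValueError("a map needs at least one point")
        rows = max(p.row for p in points) + 1
        cols = max(p.col for p in points) + 1
        seen: dict[tuple[int, int], PHPoint] = {}
        duplicates = []
        for p in points:
            if (p.row, p.col) in seen:
                duplicates.append((p.row, p.col))
            seen[(p.row, p.col)] = p
        missing = [
            (r, c)
            for r in range(rows)
            for c in range(cols)
            if (r, c) not in seen
        ]
        if duplicates or missing:
            raise ValueError(
                f"grid is not a complete {rows}x{cols} rectangle: "
                f"duplicate cells {duplicates or 'none'}, "
                f"missing cells {missing or 'none'}"
            )
        self.points = sorted(points, key=lambda p: (p.row, p.col))
        self.rows = rows
        self.cols = cols
        self.pitch_mm = float(pitch_mm)
        self.specimen_id = specimen_id
        self.threshold_applied: DiagnosticThreshold | None = None

    def __len__(self) -> int:
        return len(self.points)

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(width, height) spanned by cell centers plus one pitch margin."""
        return (self.cols * self.pitch_mm, self.rows * self.pitch_mm)

    def ph_grid(self) -> np.ndarray:
        grid = np.empty((self.rows, self.cols))
        for p in self.points:
            grid[p.row, p.col] = p.ph
        return grid

    def labels_grid(self) -> np.ndarray:
        grid = np.full((self.rows, self.cols), None, dtype=object)
        for p in self.points:
            grid[p.row, p.col] = p.label
        return grid

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            rows.append(
                {
                    "row": p.row,
                    "col": p.col,
                    "x_mm": p.col * self.pitch_mm,
                    "y_mm": p.row * self.pitch_mm,
                    "ph": p.ph,
                    "source": p.source,
                    "label": p.label,
                }
            )
        return pd.DataFrame(rows)


def build_map(
    points: Iterable[PHPoint], pitch_mm: float, specimen_id: str = "specimen-0"
) -> PHMap:
    """Validate a collection of points into a complete rectangular map."""
    return PHMap(list(points), pitch_mm, specimen_id)


@dataclass
class RegionSet:
    """Connected tumor-suspect regions of a classified map."""

    mask: np.ndarray  # boolean (rows, cols): True = suspect
    labels: np.ndarray  # integer region id per cell (0 = background)
    n_regions: int
    areas_mm2: dict[int, float]

    @property
    def total_area_mm2(self) -> float:
        return float(sum(self.areas_mm2.values()))


def classify_map(
    ph_map: PHMap,
    threshold: DiagnosticThreshold | float,
    connectivity: int = 4,
) -> RegionSet:
    """Threshold a map into tumor-suspect cells and group them into regions.

    A cell is tumor-suspect when its pH is **at or above** the threshold
    (tumor mucosa has compromised acidity, i.e. higher pH). Suspect cells
    are grouped by 4-connectivity into regions with areas in mm^2
    (8-connectivity available via ``connectivity=8``).
    """
    if not isinstance(threshold, DiagnosticThreshold):
        threshold = DiagnosticThreshold(float(threshold))
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    grid = ph_map.ph_grid()
    mask = grid >= threshold.value
    structure = (
        ndimage.generate_binary_structure(2, 1)
        if connectivity == 4
        else ndimage.generate_binary_structure(2, 2)
    )
    labels, n_regions = ndimage.label(mask, structure=structure)
    cell_area = ph_map.pitch_mm**2
    areas = {
        int(region): float(np.sum(labels == region) * cell_area)
        for region in range(1, n_regions + 1)
    }
    ph_map.threshold_applied = threshold
    return RegionSet(mask=mask, labels=labels, n_regions=n_regions, areas_mm2=areas)


def _cell_colors(grid: np.ndarray, thr: float) -> np.ndarray:
    """Per-cell RGB: red family below the threshold (strongly acidic),
    green family at/above it, shaded continuously with pH within each side."""
    lo, hi = 2.0, 9.0
    rgb = np.zeros((*grid.shape, 3), dtype=np.uint8)
    below = grid < thr
    # Red side: deeper red for more acidic; green side: deeper green for
    # higher pH. Shade 0.35-1.0 keeps every cell visibly colored.
    span_lo = max(thr - lo, 1e-9)
    span_hi = max(hi - thr, 1e-9)
    depth_red = np.clip((thr - grid) / span_lo, 0.0, 1.0)
    depth_green = np.clip((grid - thr) / span_hi, 0.0, 1.0)
    shade_red = (0.35 + 0.65 * depth_red) * 255
    shade_green = (0.35 + 0.65 * depth_green) * 255
    rgb[..., 0] = np.where(below, shade_red.astype(np.uint8), 0)
    rgb[..., 1] = np.where(~below, shade_green.astype(np.uint8), 0)
    return rgb


def render_map(
    ph_map: PHMap,
    threshold: DiagnosticThreshold | float,
    background: Image.Image | None = None,
    cell_px: int = 24,
    alpha: float = 0.6,
    out_path: str | Path | None = None,
) -> Image.Image:
    """Render a map as a raster overlay (deterministic for fixed inputs).

    Green cells mark faintly acidic (tumor-suspect) mucosa, red cells
    strongly acidic mucosa; shading within each side follows pH. An
    optional background photograph (at least as large as the map raster)
    is blended under the overlay. A legend bar with the threshold value is
    appended below the map.
    """
    if not isinstance(threshold, DiagnosticThreshold):
        threshold = DiagnosticThreshold(float(threshold))
    grid = ph_map.ph_grid()
    rgb = _cell_colors(grid, threshold.value)
    raster = np.repeat(np.repeat(rgb, cell_px, axis=0), cell_px, axis=1)
    overlay = Image.fromarray(raster, mode="RGB")
    if background is not None:
        if (
            background.size[0] < overlay.size[0]
            or background.size[1] < overlay.size[1]
        ):
            raise ValueError(
                f"background {background.size} smaller than map raster "
                f"{overlay.size}"
            )
        base = background.convert("RGB").crop((0, 0, *overlay.size))
        overlay = Image.blend(base, overlay, alpha)
    legend_h = 28
    canvas = Image.new(
        "RGB", (overlay.size[0], overlay.size[1] + legend_h), (255, 255, 255)
    )
    canvas.paste(overlay, (0, 0))
    draw = ImageDraw.Draw(canvas)
    draw.rectangle(
        [4, overlay.size[1] + 6, 14, overlay.size[1] + 16], fill=(0, 160, 0)
    )
    draw.rectangle(
        [64, overlay.size[1] + 6, 74, overlay.size[1] + 16], fill=(200, 0, 0)
    )
    draw.text(
        (18, overlay.size[1] + 6),
        f">= {threshold.value:.3f}",
        fill=(0, 0, 0),
    )
    draw.text((78, overlay.size[1] + 6), "acidic", fill=(0, 0, 0))
    if out_path is not None:
        canvas.save(out_path, format="PNG")
    return canvas
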