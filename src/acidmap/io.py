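"""File formats: spectra (CSV, JCAMP-DX), specimen tables, map tables.

CSV dialect: UTF-8, '.' decimal, ``# key: value`` comment headers followed
by a ``wavenumber_cm-1,intensity`` header row. JCAMP-DX: XYPOINTS is
written; both XYPOINTS and X++(Y..Y) (with XFACTOR/YFACTOR) are read.
Round-trips preserve the axis and intensities to full float precision
(values are printed with repr-faithful formatting).
"""

from __future__ import annotations

from pathlib import Path
import numpy as np
import pandas as pd

from .mapping import PHMap, PHPoint
from .simulate import Specimen
from .spectrum import RamanSpectrum

__all__ = [
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_spectrum_jcamp",
    "read_spectrum_jcamp",
    "read_spectrum",
    "write_spectrum",
    "write_specimen_table",
    "read_specimen_table",
    "write_map_table",
    "read_map_table",
]

_META_FLOAT_KEYS = {"true_ph"}


def write_spectrum_csv(path: str | Path, spectrum: RamanSpectrum) -> None:
    lines = []
    meta = dict(spectrum.meta)
    if spectrum.true_ph is not None:
        meta["true_ph"] = spectrum.true_ph
    for key, value in sorted(meta.items()):
        lines.append(f"# {key}: {value}")
    lines.append("wavenumber_cm-1,intensity")
    for x, y in zip(spectrum.wavenumbers, spectrum.intensities):
        lines.append(f"{float(x)!r},{float(y)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum_csv(path: str | Path) -> RamanSpectrum:
    meta: dict = {}
    xs: list[float] = []
    ys: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        if not header_seen and line.lower().startswith("wavenumber"):
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {lineno}: expected two columns")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    if not xs:
        raise ValueError(f"{path}: no data rows")
    true_ph = None
    if "true_ph" in meta:
        true_ph = float(meta.pop("true_ph"))
    return RamanSpectrum(np.array(xs), np.array(ys), meta=meta, true_ph=true_ph)


def write_spectrum_jcamp(
    path: str | Path, spectrum: RamanSpectrum, title: str = "synthetic SERS spectrum"
) -> None:
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=RAMAN SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ARBITRARY UNITS",
        f"##NPOINTS={len(spectrum)}",
        f"##FIRSTX={float(spectrum.wavenumbers[0])!r}",
        f"##LASTX={float(spectrum.wavenumbers[-1])!r}",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
    ]
    if spectrum.true_ph is not None:
        lines.append(f"##$TRUEPH={float(spectrum.true_ph)!r}")
    for key, value in sorted(spectrum.meta.items()):
        token = str(key).upper().replace(" ", "")
        lines.append(f"##${token}={value}")
    lines.append("##XYPOINTS=(XY..XY)")
    for x, y in zip(spectrum.wavenumbers, spectrum.intensities):
        lines.append(f"{float(x)!r}, {float(y)!r}")
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum_jcamp(path: str | Path) -> RamanSpectrum:
    text = Path(path).read_text().splitlines()
    meta: dict = {}
    xfactor = yfactor = 1.0
    deltax = None
    firstx = None
    mode = None  # None | "xypoints" | "xydata"
    xs: list[float] = []
    ys: list[float] = []
    true_ph = None
    for lineno, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.strip().upper().replace(" ", "")
            value = value.strip()
            if label == "END":
                break
            if label == "XFACTOR":
                xfactor = float(value)
            elif label == "YFACTOR":
                yfactor = float(value)
            elif label == "DELTAX":
                deltax = float(value)
            elif label == "FIRSTX":
                firstx = float(value)
            elif label == "$TRUEPH":
                true_ph = float(value)
            elif label == "XYPOINTS":
                mode = "xypoints"
            elif label == "XYDATA":
                mode = "xydata"
            elif label.startswith("$"):
                meta[label[1:].lower()] = value
            continue
        if mode == "xypoints":
            for pair in line.replace(";", " ").split():
                pass  # fall through to comma parsing below
            parts = [p for p in line.replace(";", ",").split(",") if p.strip()]
            if len(parts) % 2 != 0:
                raise ValueError(f"{path}: line {lineno}: odd token count")
            for i in range(0, len(parts), 2):
                xs.append(float(parts[i]) * xfactor)
                ys.append(float(parts[i + 1]) * yfactor)
        elif mode == "xydata":
            tokens = line.replace(",", " ").split()
            if not tokens:
                continue
            try:
                x0 = float(tokens[0]) * xfactor
                yvals = [float(t) * yfactor for t in tokens[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if deltax is None:
                raise ValueError(f"{path}: XYDATA requires ##DELTAX")
            for i, y in enumerate(yvals):
                xs.append(x0 + i * deltax * xfactor)
                ys.append(y)
    if not xs:
        raise ValueError(f"{path}: no data rows")
    return RamanSpectrum(np.array(xs), np.array(ys), meta=meta, true_ph=true_ph)


def write_spectrum(path: str | Path, spectrum: RamanSpectrum) -> None:
    """Dispatch on extension: .csv or .jdx/.dx."""
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        write_spectrum_csv(path, spectrum)
    elif suffix in (".jdx", ".dx", ".jcamp"):
        write_spectrum_jcamp(path, spectrum)
    else:
        raise ValueError(f"unsupported spectrum format {suffix!r}")


def read_spectrum(path: str | Path) -> RamanSpectrum:
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return read_spectrum_csv(path)
    if suffix in (".jdx", ".dx", ".jcamp"):
        return read_spectrum_jcamp(path)
    raise ValueError(f"unsupported spectrum format {suffix!r}")


# ---------------------------------------------------------------------------
# Specimen and map tables
# ---------------------------------------------------------------------------


def write_specimen_table(
    path: str | Path,
    specimen: Specimen,
    spectrum_dir: str | Path | None = None,
    fmt: str = "csv",
) -> pd.DataFrame:
    """Write the specimen point table (TSV) and optionally its spectra.

    Columns: row, col, x_mm, y_mm, true_ph, label, spectrum_path. Spectrum
    paths are stored relative to the table's directory so a run directory
    can be moved or compared wholesale.
    """
    rows = []
    table_dir = Path(path).resolve().parent
    spectrum_dir = Path(spectrum_dir) if spectrum_dir is not None else None
    if spectrum_dir is not None:
        spectrum_dir.mkdir(parents=True, exist_ok=True)
    for p in specimen.points:
        spec_path = ""
        if spectrum_dir is not None and p.spectrum is not None:
            target = spectrum_dir / f"{specimen.specimen_id}_r{p.row}c{p.col}.{fmt}"
            write_spectrum(target, p.spectrum)
            try:
                spec_path = str(target.resolve().relative_to(table_dir))
            except ValueError:
                spec_path = str(target.resolve())
        rows.append(
            {
                "row": p.row,
                "col": p.col,
                "x_mm": p.x_mm,
                "y_mm": p.y_mm,
                "true_ph": p.true_ph,
                "label": p.label,
                "spectrum_path": spec_path,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def read_specimen_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = {"row", "col", "true_ph", "label"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "spectrum_path" in frame.columns:
        base = Path(path).resolve().parent
        frame["spectrum_path"] = [
            p if not p or Path(p).is_absolute() else str(base / p)
            for p in frame["spectrum_path"].fillna("")
        ]
    return frame


def write_map_table(path: str | Path, ph_map: PHMap, suspect_mask=None) -> None:
    """Map TSV: row, col, x_mm, y_mm, ph, source, suspect{0,1}."""
    frame = ph_map.to_frame()
    if suspect_mask is not None:
        frame["suspect"] = [
            int(suspect_mask[p.row, p.col]) for p in ph_map.points
        ]
    frame.to_csv(path, sep="\t", index=False)


def read_map_table(path: str | Path, pitch_mm: float | None = None) -> PHMap:
    frame = pd.read_csv(path, sep="\t")
    points = [
        PHPoint(
            row=int(r.row),
            col=int(r.col),
            ph=float(r.ph),
            source=getattr(r, "source", "ratiometric"),
            label=getattr(r, "label", None),
        )
        for r in frame.itertuples()
    ]
    if pitch_mm is None:
        with_coords = frame[frame["col"] > 0]
        if len(with_coords) and "x_mm" in frame.columns:
            first = with_coords.iloc[0]
            pitch_mm = float(first["x_mm"] / first["col"])
        else:
            pitch_mm = 3.0
    return PHMap(points, pitch_mm=pitch_mm)
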