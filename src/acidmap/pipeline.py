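"""End-to-end pipeline: simulate -> calibrate -> predict -> map -> evaluate.

A single YAML (or dict) configuration drives every stage; unknown keys are
rejected so typos fail loudly. Each run writes its artifacts plus a
resolved-config snapshot and a manifest listing every file with its SHA-256
checksum; rerunning with the same seed reproduces the checksums of all
deterministic stages. One master seed is fanned out to the stages by fixed
offsets so stages stay independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as amio
from .calibration import RatiometricCalibration, load_calibration
from .diagnostics import confusion, metric_report, roc_curve, youden_threshold
from .mapping import DiagnosticThreshold, PHPoint, build_map, classify_map, render_map
from .phnet import PHNet, PHNetConfig, SpectrumDataset
from .preprocess import PreprocessOptions, extract_ratio, preprocess
from .simulate import SpecimenSimConfig, SpectrumModelParams, generate_dataset, generate_specimen

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("acidmap")

_SEED_OFFSETS = {"simulate": 11, "calibrate": 23, "model": 37}

_SECTION_KEYS = {
    "simulate": {
        "n_specimens", "grid_rows", "grid_cols", "pitch_mm", "tumor_block",
        "noise_sd", "calibration_levels", "calibration_replicates",
    },
    "preprocess": {
        "despike_window", "spike_nsigma", "baseline", "als_lam", "als_p",
        "als_niter", "smooth", "savgol_window", "savgol_order",
    },
    "predict": {"method"},
    "model": {
        "image_side", "seq_len", "d_1d", "d_attn", "n_heads", "conv_widths",
        "head_hidden", "learning_rate", "weight_decay", "epochs", "batch_size",
        "patience", "split", "loss",
    },
    "map": {"threshold", "cell_px"},
    "evaluate": {"threshold"},
}
_TOP_KEYS = {"seed", "out_dir", "log_level", "stages"} | set(_SECTION_KEYS)
_ALL_STAGES = ("simulate", "calibrate", "predict", "map", "evaluate")


def _check_keys(mapping: dict, allowed: set[str], section: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(
            f"unknown configuration key(s) {sorted(unknown)} in {section}; "
            f"allowed: {sorted(allowed)}"
        )


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with per-section dictionaries."""

    seed: int = 0
    out_dir: str = "acidmap-run"
    log_level: str = "INFO"
    stages: tuple[str, ...] = _ALL_STAGES
    simulate: dict[str, Any] = field(default_factory=dict)
    preprocess: dict[str, Any] = field(default_factory=dict)
    predict: dict[str, Any] = field(default_factory=dict)
    model: dict[str, Any] = field(default_factory=dict)
    map: dict[str, Any] = field(default_factory=dict)
    evaluate: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("simulate", "preprocess", "predict", "model", "map", "evaluate"):
            _check_keys(getattr(self, name), _SECTION_KEYS[name], f"section '{name}'")
        bad = [s for s in self.stages if s not in _ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stage(s) {bad}; valid: {list(_ALL_STAGES)}")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        _check_keys(data, _TOP_KEYS, "top level")
        kwargs = dict(data)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def resolved(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
            "stages": list(self.stages),
            "simulate": self.simulate,
            "preprocess": self.preprocess,
            "predict": self.predict,
            "model": self.model,
            "map": self.map,
            "evaluate": self.evaluate,
        }

    def preprocess_options(self) -> PreprocessOptions:
        return PreprocessOptions(**self.preprocess)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.root = Path(config.out_dir)
        self.root.mkdir(parents=True, exist_ok=True)
        self.artifacts: list[dict[str, str]] = []

    def record(self, path: Path, stage: str) -> None:
        self.artifacts.append(
            {
                "path": str(path.relative_to(self.root)),
                "stage": stage,
                "sha256": _sha256(path),
            }
        )

    def require(self, path: Path, stage: str, produced_by: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs {path}, produced by stage "
                f"'{produced_by}' — run it first"
            )
        return path


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the requested stages in order; returns the run directory."""
    logging.basicConfig(level=config.log_level)
    run = _Run(config)
    root = run.root
    options = config.preprocess_options()

    snapshot = root / "config.resolved.yaml"
    snapshot.write_text(yaml.safe_dump(config.resolved(), sort_keys=True))
    run.record(snapshot, "config")

    sim = config.simulate
    n_specimens = int(sim.get("n_specimens", 4))
    rows = int(sim.get("grid_rows", 6))
    cols = int(sim.get("grid_cols", 6))
    pitch = float(sim.get("pitch_mm", 3.0))
    block = sim.get("tumor_block", [1, 1, 2, 2])
    params = SpectrumModelParams(
        noise_sd=float(sim.get("noise_sd", SpectrumModelParams().noise_sd))
    )

    if "simulate" in config.stages:
        logger.info("stage: simulate (%d specimens)", n_specimens)
        spectra_dir = root / "spectra"
        tumor = frozenset(
            (r, c)
            for r in range(block[0], block[2] + 1)
            for c in range(block[1], block[3] + 1)
        )
        for k in range(n_specimens):
            cfg = SpecimenSimConfig(
                grid_rows=rows,
                grid_cols=cols,
                pitch_mm=pitch,
                tumor_region=tumor,
                seed=config.seed + _SEED_OFFSETS["simulate"] + k,
            )
            specimen = generate_specimen(
                cfg, params, specimen_id=f"specimen-{k}"
            )
            table = root / f"specimen-{k}.tsv"
            amio.write_specimen_table(table, specimen, spectrum_dir=spectra_dir)
            run.record(table, "simulate")
        for spec_file in sorted(spectra_dir.glob("*.csv")):
            run.record(spec_file, "simulate")
        # Calibration standards: replicate spectra at fixed pH levels.
        levels = sim.get("calibration_levels", [2, 3, 4, 5, 6, 7, 8, 9])
        reps = int(sim.get("calibration_replicates", 3))
        calib_dir = root / "calibration_spectra"
        calib_dir.mkdir(exist_ok=True)
        cal_spectra = generate_dataset(
            len(levels) * reps,
            {"kind": "grid", "values": levels},
            params,
            seed=config.seed + _SEED_OFFSETS["calibrate"],
        )
        for i, spec in enumerate(cal_spectra):
            path = calib_dir / f"standard_{i:03d}.csv"
            amio.write_spectrum_csv(path, spec)
            run.record(path, "simulate")

    if "calibrate" in config.stages:
        logger.info("stage: calibrate")
        calib_dir = run.require(
            root / "calibration_spectra", "calibrate", "simulate"
        )
        points = []
        for path in sorted(calib_dir.glob("*.csv")):
            spec = amio.read_spectrum_csv(path)
            ratio = extract_ratio(preprocess(spec, options)).ratio
            points.append((spec.true_ph, ratio))
        pts = np.asarray(points)
        results = RatiometricCalibration(pts[:, 0], pts[:, 1]).fit()
        results.preprocessing_options = options.to_dict()
        calib_path = root / "calib.json"
        payload = results.to_dict()
        payload.pop("created", None)  # keep reruns byte-identical
        calib_path.write_text(json.dumps(payload, indent=2))
        run.record(calib_path, "calibrate")

    if "predict" in config.stages:
        logger.info("stage: predict")
        method = config.predict.get("method", "ratiometric")
        calib = load_calibration(
            run.require(root / "calib.json", "predict", "calibrate")
        )
        model_results = None
        if method == "model":
            model_results = _train_model(config, run, options, params)
        for table_path in sorted(root.glob("specimen-*.tsv")):
            frame = amio.read_specimen_table(table_path)
            points = []
            for r in frame.itertuples():
                spec = amio.read_spectrum_csv(r.spectrum_path)
                if method == "model":
                    ph = model_results.predict_ph(spec, options=options)
                else:
                    ratio = extract_ratio(preprocess(spec, options)).ratio
                    ph = float(calib.predict_ph(ratio)[0])
                points.append(
                    PHPoint(
                        row=int(r.row),
                        col=int(r.col),
                        ph=ph,
                        source="model" if method == "model" else "ratiometric",
                        label=r.label,
                    )
                )
            ph_map = build_map(points, pitch_mm=pitch,
                               specimen_id=table_path.stem)
            out = root / f"ph_{table_path.stem}.tsv"
            amio.write_map_table(out, ph_map)
            run.record(out, "predict")

    threshold = DiagnosticThreshold(
        float(config.map.get("threshold",
                             config.evaluate.get("threshold", 6.845)))
    )

    if "map" in config.stages:
        logger.info("stage: map")
        for ph_table in sorted(root.glob("ph_specimen-*.tsv")):
            ph_map = amio.read_map_table(ph_table, pitch_mm=pitch)
            regions = classify_map(ph_map, threshold)
            amio.write_map_table(ph_table, ph_map, suspect_mask=regions.mask)
            run.record(ph_table, "map")
            png = root / (ph_table.stem + ".png")
            render_map(
                ph_map,
                threshold,
                cell_px=int(config.map.get("cell_px", 24)),
                out_path=png,
            )
            run.record(png, "map")

    if "evaluate" in config.stages:
        logger.info("stage: evaluate")
        ph_tables = sorted(root.glob("ph_specimen-*.tsv"))
        if not ph_tables:
            raise FileNotFoundError(
                "stage 'evaluate' needs ph_specimen-*.tsv, produced by "
                "stage 'predict' — run it first"
            )
        labels, scores = [], []
        for ph_table in ph_tables:
            frame = amio.read_map_table(ph_table, pitch_mm=pitch).to_frame()
            labels.extend((frame["label"] == "tumor").astype(int))
            scores.extend(frame["ph"])
        labels = np.asarray(labels)
        scores = np.asarray(scores)
        roc = roc_curve(labels, scores)
        opt_thr, j = youden_threshold(roc)
        cm = confusion(labels, (scores >= threshold.value).astype(int))
        report = metric_report(cm, auc=roc.auc, optimal_threshold=opt_thr)
        report_path = root / "report.json"
        report_path.write_text(json.dumps(report.to_dict(), indent=2))
        run.record(report_path, "evaluate")
        roc_path = root / "roc.tsv"
        np.savetxt(
            roc_path,
            np.column_stack([roc.fpr, roc.tpr, roc.thresholds]),
            delimiter="\t",
            header="fpr\ttpr\tthreshold",
            comments="",
        )
        run.record(roc_path, "evaluate")

    manifest = root / "manifest.json"
    manifest.write_text(json.dumps(run.artifacts, indent=2))
    logger.info("run complete: %s (%d artifacts)", root, len(run.artifacts))
    return root


def _train_model(config, run, options, params):
    """Train the multimodal network on the simulated specimens."""
    spectra, ids = [], []
    tables = sorted(run.root.glob("specimen-*.tsv"))
    if not tables:
        raise FileNotFoundError(
            "stage 'predict' (model) needs specimen-*.tsv, produced by "
            "stage 'simulate' — run it first"
        )
    for table_path in tables:
        frame = amio.read_specimen_table(table_path)
        for r in frame.itertuples():
            spectra.append(amio.read_spectrum_csv(r.spectrum_path))
            ids.append(table_path.stem)
    model_cfg_fields = dict(config.model)
    if "conv_widths" in model_cfg_fields:
        model_cfg_fields["conv_widths"] = tuple(model_cfg_fields["conv_widths"])
    if "split" in model_cfg_fields:
        model_cfg_fields["split"] = tuple(model_cfg_fields["split"])
    cfg = PHNetConfig(
        seed=config.seed + _SEED_OFFSETS["model"], **model_cfg_fields
    )
    dataset = SpectrumDataset.from_spectra(spectra, ids, cfg, options)
    results = PHNet(dataset, cfg).fit()
    model_dir = run.root / "model"
    results.save(model_dir)
    for path in sorted(p for p in model_dir.rglob("*") if p.is_file()):
        run.record(path, "predict")
    return results
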