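"""End-to-end orchestration: simulate/load -> extract -> segment ->
normalize -> calibrate -> quantify, driven by one config.

All stage parameters default to the study's stated values (0.005 Da
extraction tolerance, spot threshold 5.6 on the log10 scale, 400 um
raster) and every run writes a manifest listing each stage, its
parameters and the checksums of its outputs, so a run is auditable and
exactly reproducible from config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import chem
from .design import CalibrationDesign
from .images import extract_ion_image, log_transform
from .imzml import read_imzml, write_imzml
from .quant import build_distribution_map, fit_calibration, normalize_ratio, summarize_roi
from .segment import annotate_rois, combine_maps, detect_spots, segment_tissue
from .simulate import default_calibration_spec, default_slide_spec, generate_slide

__all__ = ["RunConfig", "ConfigError", "PipelineError", "validate_config", "run_pipeline", "run_calibration_experiment"]


class ConfigError(ValueError):
    def __init__(self, errors: List[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Validated pipeline configuration with study defaults."""

    output_dir: str = "msiquant_run"
    input_path: Optional[str] = None        # imzML path; None -> simulate
    simulate: str = "calibration"           # "calibration" | "slide" | "none"
    design_path: Optional[str] = None       # required for real input with spots
    seed: int = 0
    tolerance_da: float = 0.005
    spot_threshold: float = 5.6
    spot_min_area_px: int = 3
    spot_max_area_px: Optional[int] = 200
    tissue_min_area_px: int = 20
    aggregation: str = "sum"
    lipid_level_for_map: float = 0.0
    treated_amount_ng: float = 5.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_TYPES = {
    "output_dir": str,
    "input_path": (str, type(None)),
    "simulate": str,
    "design_path": (str, type(None)),
    "seed": int,
    "tolerance_da": (int, float),
    "spot_threshold": (int, float),
    "spot_min_area_px": int,
    "spot_max_area_px": (int, type(None)),
    "tissue_min_area_px": int,
    "aggregation": str,
    "lipid_level_for_map": (int, float),
    "treated_amount_ng": (int, float),
}


def validate_config(source) -> RunConfig:
    """Normalize a config mapping or YAML file path into a RunConfig.

    Unknown keys and type mismatches are collected and raised together
    as a :class:`ConfigError`, each message naming the offending key.
    Normalization is idempotent: validating a validated config's
    ``to_dict()`` returns an equal config.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    elif isinstance(source, RunConfig):
        data = source.to_dict()
    else:
        data = dict(source or {})

    errors = []
    for key in data:
        if key not in _FIELD_TYPES:
            errors.append(f"unknown config key {key!r}")
    for key, typ in _FIELD_TYPES.items():
        if key in data:
            val = data[key]
            if not isinstance(val, typ) or (isinstance(val, bool) and typ is not bool):
                errors.append(f"config key {key!r}: expected {typ}, got {type(val).__name__}")
    cfg = None
    if not errors:
        cfg = RunConfig(**{k: data[k] for k in data})
        if cfg.tolerance_da <= 0:
            errors.append("config key 'tolerance_da': must be > 0")
        if cfg.simulate not in ("calibration", "slide", "none"):
            errors.append("config key 'simulate': must be 'calibration', 'slide' or 'none'")
        if cfg.simulate == "none" and not cfg.input_path:
            errors.append("config key 'input_path': required when simulate='none'")
        if cfg.aggregation not in ("sum", "max"):
            errors.append("config key 'aggregation': must be 'sum' or 'max'")
    if errors:
        raise ConfigError(errors)
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config) -> dict:
    """Run every stage; returns the manifest (also written to disk).

    On a stage failure the manifest is written with that stage marked
    ``failed`` (partial outputs retained) and :class:`PipelineError` is
    raised.
    """
    cfg = validate_config(config)
    out = cfg.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "stages": []}
    state: dict = {}

    def stage(name):
        def deco(fn):
            entry = {"stage": name, "status": "pending", "outputs": []}
            manifest["stages"].append(entry)

            def run():
                try:
                    produced = fn() or []
                    entry["outputs"] = [
                        {"path": p, "sha256": _sha256(p)} for p in produced
                    ]
                    entry["status"] = "ok"
                except Exception as exc:
                    entry["status"] = "failed"
                    entry["error"] = str(exc)
                    _write_manifest(manifest, out, failed=True)
                    raise PipelineError(name, exc) from exc
            return run
        return deco

    @stage("simulate")
    def s_input():
        if cfg.simulate == "none":
            state["grid"] = read_imzml(cfg.input_path)
            if cfg.design_path:
                state["design"] = CalibrationDesign.from_csv(cfg.design_path)
            return []
        spec = (
            default_calibration_spec(cfg.seed)
            if cfg.simulate == "calibration"
            else default_slide_spec(cfg.seed, cfg.treated_amount_ng)
        )
        grid, truth = generate_slide(spec)
        state["grid"], state["truth"], state["design"] = grid, truth, truth.design
        path = os.path.join(out, "simulated.imzML")
        write_imzml(grid, path, mode="processed", dtype="float64")
        dpath = os.path.join(out, "design.csv")
        truth.design.to_csv(dpath)
        return [path, os.path.splitext(path)[0] + ".ibd", dpath]

    @stage("extract")
    def s_extract():
        targets = chem.builtin_targets()
        imgs = {}
        for key in ("BUD-GirP", "TA-GirP", "hemeB", "tiotropium"):
            imgs[key] = extract_ion_image(
                state["grid"], targets[key].mz, cfg.tolerance_da, cfg.aggregation,
                provenance=key,
            )
        state["images"] = imgs
        produced = []
        for key, img in imgs.items():
            p = os.path.join(out, f"ion_image_{key}.csv")
            np.savetxt(p, img.values, delimiter=",", fmt="%.6g")
            produced.append(p)
        return produced

    @stage("segment")
    def s_segment():
        tissue = segment_tissue(
            log_transform(state["images"]["hemeB"]), cfg.tissue_min_area_px
        )
        spots = detect_spots(
            log_transform(state["images"]["tiotropium"]),
            cfg.spot_threshold,
            cfg.spot_min_area_px,
            cfg.spot_max_area_px,
        )
        combined = combine_maps(tissue, spots)
        if "design" in state:
            combined = annotate_rois(combined, state["design"])
        state["rois"] = combined
        p = os.path.join(out, "roi_labels.csv")
        np.savetxt(p, combined.labels, delimiter=",", fmt="%d")
        return [p]

    @stage("normalize")
    def s_normalize():
        state["ratio"] = normalize_ratio(
            state["images"]["BUD-GirP"], state["images"]["TA-GirP"]
        )
        p = os.path.join(out, "ratio_image.csv")
        np.savetxt(p, state["ratio"].values, delimiter=",", fmt="%.6g")
        return [p]

    @stage("calibrate")
    def s_calibrate():
        summaries = summarize_roi(state["ratio"], state["rois"])
        state["summaries"] = summaries
        spot_sums = [
            s for s in summaries if s.annotation.get("amount_ng") is not None
        ]
        import pandas as pd

        tab = pd.DataFrame(
            [
                {
                    "roi_id": s.roi_id,
                    "spot_id": s.annotation.get("spot_id", ""),
                    "amount_ng": s.annotation.get("amount_ng", np.nan),
                    "lipid_mg_per_g": s.annotation.get("lipid_mg_per_g", np.nan),
                    "replicate": s.annotation.get("replicate", 0),
                    "n_pixels": s.n_pixels_used,
                    "median_ratio": s.median_ratio,
                    "iqr_ratio": s.iqr_ratio,
                }
                for s in spot_sums
            ]
        )
        tpath = os.path.join(out, "calibration_table.csv")
        tab.to_csv(tpath, index=False)
        produced = [tpath]
        if spot_sums:
            fit = fit_calibration(spot_sums)
            state["fit"] = fit
            fpath = os.path.join(out, "calibration_fit.json")
            with open(fpath, "w") as fh:
                fh.write(fit.to_json(indent=2))
            produced.append(fpath)
        return produced

    @stage("quantify")
    def s_quantify():
        if "fit" not in state:
            return []
        conc_img, table = build_distribution_map(
            state["ratio"], state["rois"], state["fit"], cfg.lipid_level_for_map
        )
        p1 = os.path.join(out, "concentration_map.csv")
        np.savetxt(p1, conc_img.values, delimiter=",", fmt="%.6g")
        p2 = os.path.join(out, "section_summary.csv")
        table.to_csv(p2, index=False)
        produced = [p1, p2]
        try:
            import tifffile

            p3 = os.path.join(out, "concentration_map.tiff")
            tifffile.imwrite(p3, conc_img.values.astype(np.float32))
            produced.append(p3)
        except ImportError:
            pass
        return produced

    for runner in (s_input, s_extract, s_segment, s_normalize, s_calibrate, s_quantify):
        runner()
    _write_manifest(manifest, out, failed=False)
    return manifest


def run_calibration_experiment(seed: int = 0, spec=None):
    """In-memory calibration run on a synthetic slide: generate ->
    extract -> segment -> annotate -> normalize -> summarize -> fit.

    Returns ``(fit, truth, summaries)``.  This is the programmatic
    counterpart of the file-based pipeline, convenient for recovery
    studies that repeat the experiment over many seeds.
    """
    if spec is None:
        spec = default_calibration_spec(seed)
    grid, truth = generate_slide(spec)
    targets = chem.builtin_targets()
    imgs = {
        k: extract_ion_image(grid, targets[k].mz, provenance=k)
        for k in ("BUD-GirP", "TA-GirP", "hemeB", "tiotropium")
    }
    tissue = segment_tissue(log_transform(imgs["hemeB"]))
    spots = detect_spots(log_transform(imgs["tiotropium"]))
    rois = annotate_rois(combine_maps(tissue, spots), truth.design)
    ratio = normalize_ratio(imgs["BUD-GirP"], imgs["TA-GirP"])
    summaries = summarize_roi(ratio, rois)
    spot_sums = [s for s in summaries if "amount_ng" in s.annotation]
    fit = fit_calibration(spot_sums)
    return fit, truth, summaries


def _write_manifest(manifest: dict, out: str, failed: bool) -> None:
    manifest["status"] = "failed" if failed else "ok"
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
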