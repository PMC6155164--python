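"""Readers/writers for the package's file formats and the end-to-end pipeline.

Formats: localization tables as headered CSV (x_nm, y_nm, frame, channel,
intensity, precision_nm); nucleus ROIs as GeoJSON polygons; rendered images
and frame stacks as TIFF; chromatic maps, colocalization results, ground
truth, and the run manifest as JSON; cluster and population tables as CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import spawn_rng
from .chromatic import ChromaticMap, apply_map
from .coloc import (
    colocalization_coefficient,
    overlap_mode_for,
    summarize_population,
)
from .foci import classify_population, identify_foci, fractions_table
from .render import GridSpec, NucleusROI, render, segment_channel
from .synthetic import LOC_COLUMNS, SceneConfig, generate_nucleus_scene

log = logging.getLogger(__name__)

MANDATORY_COLUMNS = ["x_nm", "y_nm", "frame", "channel"]


class FormatError(ValueError):
    """Malformed input file (missing columns, non-numeric fields, ...)."""


# ---------------------------------------------------------------- tables


def write_localizations(table: pd.DataFrame, path) -> None:
    cols = [c for c in LOC_COLUMNS if c in table.columns] + [c for c in table.columns if c not in LOC_COLUMNS]
    table[cols].to_csv(path, index=False)


def read_localizations(path, dialect: str = "native", units: str = "nm") -> pd.DataFrame:
    """Read a localization table.

    dialect "native": the package's headered CSV (x_nm, y_nm, frame, channel,
    intensity, precision_nm). dialect "generic": whitespace/TSV or CSV with at
    least x/y/frame columns (accepts x, y or x_nm, y_nm headers); ``units``
    ("nm" or "um") sets the coordinate unit, and um input is converted to nm.
    Malformed numeric fields are rejected with their line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "native":
        df = pd.read_csv(path)
    elif dialect == "generic":
        df = pd.read_csv(path, sep=None, engine="python")
        df = df.rename(columns={"x": "x_nm", "y": "y_nm"})
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns and not (c == "channel" and dialect == "generic")]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    if "channel" not in df.columns:
        df["channel"] = "0"
    for col in ("x_nm", "y_nm", "frame"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(coerced.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if bad.size:
            # +2: one for the header row, one for 1-based line numbers
            raise FormatError(f"{path}: non-numeric value in column {col!r} on line {bad[0] + 2}")
        if coerced.isna().any():
            raise FormatError(f"{path}: empty value in column {col!r} on line {int(np.nonzero(coerced.isna().to_numpy())[0][0]) + 2}")
        df[col] = coerced
    if units == "um":
        df["x_nm"] = df["x_nm"] * 1000.0
        df["y_nm"] = df["y_nm"] * 1000.0
    elif units != "nm":
        raise FormatError(f"unknown units {units!r}")
    if "intensity" not in df.columns:
        df["intensity"] = 1.0
    if "precision_nm" not in df.columns:
        df["precision_nm"] = 10.0
    return df


# ---------------------------------------------------------------- ROIs


def write_roi(roi: NucleusROI, path) -> None:
    if roi.polygon is None:
        raise ValueError("only polygon ROIs can be written as GeoJSON")
    coords = [list(map(float, xy)) for xy in roi.polygon.exterior.coords]
    payload = {"type": "Polygon", "coordinates": [coords], "properties": {"units": "nm"}}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_roi(path) -> NucleusROI:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") == "Feature":
        data = data["geometry"]
    if data.get("type") != "Polygon":
        raise FormatError(f"{path}: expected a GeoJSON Polygon, got {data.get('type')!r}")
    return NucleusROI(polygon=[tuple(p) for p in data["coordinates"][0]])


def write_image_tiff(image: np.ndarray, path) -> None:
    import tifffile

    arr = np.asarray(image)
    if arr.dtype.kind == "f":
        top = arr.max() if arr.size and arr.max() > 0 else 1.0
        arr = np.clip(arr / top * 65535.0, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)


def read_stack_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


# ---------------------------------------------------------------- pipeline


@dataclass
class NucleusInput:
    nucleus_id: str
    localizations: str | None = None  # CSV path; None when simulating
    roi: str | None = None  # GeoJSON path
    condition: str = "control"
    timepoint_h: float = 0.0


@dataclass
class PipelineConfig:
    """End-to-end run configuration. Round-trips through YAML unchanged."""

    seed: int = 0
    pixel_nm: float = 20.0
    n_sims: int = 20
    association_radius_nm: float = 250.0
    bin_width_nm: float = 10.0
    nadna_channel: str = "naDNA"
    protein_channels: list[str] = field(default_factory=lambda: ["RPA", "RAD51"])
    coefficient_mode: dict[str, str] = field(default_factory=dict)  # protein -> "number" | "area"
    stages: dict[str, bool] = field(default_factory=lambda: {"mapping": False, "foci": True})
    chromatic_maps: dict[str, str] = field(default_factory=dict)  # channel -> map JSON path
    reference_condition: str = "control"
    inputs: list[NucleusInput] = field(default_factory=list)
    simulate: dict[str, Any] | None = None  # {"n_nuclei": int, "scene": {SceneConfig kwargs}, "condition": ...}
    output_dir: str = "nanofoci_out"

    def mode_for(self, protein: str) -> str:
        return self.coefficient_mode.get(protein, overlap_mode_for(protein))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        d["inputs"] = [NucleusInput(**i) if not isinstance(i, NucleusInput) else i for i in d.get("inputs", [])]
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, nucleus_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on nucleus {nucleus_id!r}: {cause}")
        self.stage = stage
        self.nucleus_id = nucleus_id


def _analyze_nucleus(
    config: PipelineConfig,
    nucleus_id: str,
    locs: pd.DataFrame,
    roi: NucleusROI,
    maps: Mapping[str, ChromaticMap],
    seed: int,
) -> dict:
    if config.stages.get("mapping", False) and maps:
        parts = []
        for ch, sub in locs.groupby("channel", sort=False):
            parts.append(apply_map(sub, maps[ch], channel=str(ch)) if ch in maps else sub)
        locs = pd.concat(parts, ignore_index=True)
    grid = roi.default_grid(config.pixel_nm)
    sets = {}
    for ch in (config.nadna_channel, *config.protein_channels):
        img = render(locs, grid, mode="counts", channel=ch)
        sets[ch] = segment_channel(img, roi)
    out: dict[str, Any] = {"nucleus_id": nucleus_id, "coloc": {}, "foci": None}
    for k, protein in enumerate(config.protein_channels):
        res = colocalization_coefficient(
            sets[config.nadna_channel], sets[protein], roi, n_sims=config.n_sims, seed=seed + k, nucleus_id=nucleus_id
        )
        out["coloc"][protein] = res
    if config.stages.get("foci", True) and len(config.protein_channels) >= 2:
        records, n_negative = identify_foci(
            sets[config.nadna_channel],
            {p: sets[p] for p in config.protein_channels},
            association_radius_nm=config.association_radius_nm,
            nucleus_id=nucleus_id,
        )
        out["foci"] = {"records": records, "n_protein_negative": n_negative}
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run mapping -> rendering -> segmentation -> colocalization -> foci.

    Writes per-nucleus colocalization JSON, an aggregated coefficient CSV,
    focus population fractions, a population summary with Welch t tests
    against the reference condition, and a run manifest (package version,
    seed, config hash, per-nucleus flags). Deterministic for a fixed config:
    all randomness flows from ``config.seed`` through per-nucleus sub-seeds.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    maps = {ch: ChromaticMap.from_json(p) for ch, p in config.chromatic_maps.items()} if config.stages.get("mapping") else {}

    nuclei: list[tuple[NucleusInput, pd.DataFrame, NucleusROI]] = []
    if config.simulate is not None:
        sim = dict(config.simulate)
        n_nuclei = int(sim.pop("n_nuclei", 1))
        condition = sim.pop("condition", "control")
        timepoint = float(sim.pop("timepoint_h", 0.0))
        scene_kwargs = sim.pop("scene", {})
        for k in range(n_nuclei):
            sub_seed = int(spawn_rng(config.seed, 1000 + k).integers(0, 2**31 - 1))
            scene = generate_nucleus_scene(SceneConfig(seed=sub_seed, **scene_kwargs))
            nuclei.append((NucleusInput(nucleus_id=f"sim{k:03d}", condition=condition, timepoint_h=timepoint), scene.locs, scene.roi))
    for inp in config.inputs:
        locs = read_localizations(inp.localizations)
        roi = read_roi(inp.roi)
        nuclei.append((inp, locs, roi))

    per_nucleus = []
    rows = []
    by_group: dict[tuple[str, float], dict[str, list[float]]] = {}
    all_records = []
    flagged_nuclei = []
    for k, (inp, locs, roi) in enumerate(nuclei):
        try:
            result = _analyze_nucleus(config, inp.nucleus_id, locs, roi, maps, seed=config.seed * 10_000 + 100 * k)
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            raise PipelineError("analysis", inp.nucleus_id, exc) from exc
        per_nucleus.append(result)
        for protein, res in result["coloc"].items():
            coeff = res.coefficient(config.mode_for(protein))
            if res.insufficient_randomization_overlap:
                flagged_nuclei.append((inp.nucleus_id, protein))
            rows.append(
                {
                    "nucleus_id": inp.nucleus_id,
                    "condition": inp.condition,
                    "timepoint_h": inp.timepoint_h,
                    "protein": protein,
                    "mode": config.mode_for(protein),
                    "coefficient": coeff,
                    "n_real": res.n_real,
                    "area_real_nm2": res.area_real_nm2,
                    "flagged": res.insufficient_randomization_overlap,
                }
            )
            by_group.setdefault((inp.condition, inp.timepoint_h), {}).setdefault(protein, []).append(coeff)
        if result["foci"]:
            all_records.extend(result["foci"]["records"])
        (outdir / f"coloc_{inp.nucleus_id}.json").write_text(
            json.dumps({p: r.to_dict() for p, r in result["coloc"].items()}, indent=1)
        )

    coeff_df = pd.DataFrame(rows)
    coeff_df.to_csv(outdir / "coefficients.csv", index=False)

    summaries = {}
    for protein in config.protein_channels:
        groups = {g: vals[protein] for g, vals in by_group.items() if protein in vals}
        summaries[protein] = summarize_population(groups, reference_condition=config.reference_condition)
    summary_rows = [
        {
            "protein": protein,
            "condition": s.condition,
            "timepoint_h": s.timepoint_h,
            "mean": s.mean,
            "sem": s.sem,
            "n_cells": s.n_cells,
            "p_value": s.p_value,
            "significance": s.significance,
        }
        for protein, ss in summaries.items()
        for s in ss
    ]
    pd.DataFrame(summary_rows).to_csv(outdir / "population_summary.csv", index=False)

    fractions = None
    if all_records and len(config.protein_channels) >= 2:
        a, b = config.protein_channels[:2]
        fractions = classify_population(all_records, a, b)
        fractions_table(fractions).to_csv(outdir / "focus_fractions.csv", index=False)

    manifest = {
        "package": "nanofoci",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_nuclei": len(nuclei),
        "mapping_applied": bool(maps),
        "flagged_nuclei": [{"nucleus_id": n, "protein": p} for n, p in flagged_nuclei],
    }
    if not config.stages.get("mapping", False):
        manifest["mapping_skipped"] = True
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return {
        "per_nucleus": per_nucleus,
        "coefficients": coeff_df,
        "summaries": summaries,
        "fractions": fractions,
        "manifest": manifest,
    }
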