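"""End-to-end orchestration: simulate -> segment -> quantify -> fit.

Runs are driven by a :class:`RunConfig` (preset name or an input
directory with a plate map), are deterministic given the seed, isolate
per-field failures, and write a fixed output layout::

    out/percell.csv       one row per measured cell
    out/perfield.csv      one row per field (mean, SEM, counts)
    out/percondition.csv  one row per condition (dose or time point)
    out/fits.json         dose-response / kinetics fit parameters
    out/manifest.json     config, config hash, seed, package version

A ground-truth bypass mode replaces segmentation with the generator's
analytic masks, which bounds the error attributable to segmentation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import FieldImage
from .io import PlateMap, read_field_tiff, write_field_tiff, write_ground_truth
from .models import fit_exponential, fit_sigmoid
from .presets import get_preset, preset_kind, preset_names
from .quantify import (
    CellRecord,
    FieldSummary,
    QCCriteria,
    RayScanParams,
    aggregate_cells,
    qc_filter,
    radial_scan,
)
from .segment import SegmentationResult, assign_territories, segment
from .synth import (
    GroundTruth,
    analytic_masks,
    render_dose_series,
    render_field,
    render_time_series,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    preset: str | None = None
    input_dir: str | None = None
    platemap: str | None = None
    strategy: str = "auto"
    policy: str = "mean"
    reporter_role: str = "reporter"
    allow_delay: bool = True
    fit: bool = True
    seed: int = 0
    out_dir: str | None = None
    scan: RayScanParams = field(default_factory=RayScanParams)
    qc: QCCriteria = field(default_factory=QCCriteria)
    bypass_segmentation: bool = False

    def validate(self) -> None:
        if (self.preset is None) == (self.input_dir is None):
            raise ValueError("config must name exactly one of preset / input_dir")
        if self.preset is not None:
            preset_kind(self.preset)  # raises with the list of known presets
        if self.input_dir is not None and self.platemap is None:
            raise ValueError("input_dir runs require a plate map")
        if self.policy not in ("mean", "median"):
            raise ValueError(f"unknown aggregation policy {self.policy!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# single-field processing
# --------------------------------------------------------------------------

def segmentation_from_truth(gt: GroundTruth,
                            shape: tuple[int, int]) -> SegmentationResult:
    """Build a SegmentationResult from the generator's analytic masks."""
    pm = np.zeros(shape, dtype=bool)
    nuc = np.zeros(shape, dtype=np.int32)
    for i, cell in enumerate(gt.cells):
        masks = analytic_masks(cell, shape)
        pm |= masks["band_center"]
        nuc[masks["nucleus"]] = i + 1
    centroids = gt.centroids
    terr = assign_territories(centroids, pm, shape)
    return SegmentationResult(
        centroids=centroids, pm_mask=pm, territories=terr,
        nuclear_mask=nuc, strategy_used="ground-truth",
        border_cell=np.zeros(len(gt.cells), dtype=bool))


def process_field(fieldimg: FieldImage, config: RunConfig,
                  field_id: str = "", condition: dict | None = None,
                  gt: GroundTruth | None = None
                  ) -> tuple[list[CellRecord], FieldSummary]:
    """Segment, radially quantify and QC-filter one field."""
    t0 = time.perf_counter()
    if config.bypass_segmentation:
        if gt is None:
            raise ValueError("bypass mode requires ground truth")
        seg = segmentation_from_truth(gt, fieldimg.shape)
    else:
        seg = segment(fieldimg, strategy=config.strategy)
    records = radial_scan(fieldimg, seg, reporter_role=config.reporter_role,
                          params=config.scan)
    kept, dropped = qc_filter(records, config.qc)
    for rec, reason in dropped:
        log.debug("field %s cell %d dropped: %s", field_id, rec.cell_id, reason)
    summary = aggregate_cells(records, policy=config.policy,
                              field_id=field_id, condition=condition)
    log.debug("field %s: %d cells (%d pass) in %.2fs", field_id,
              len(records), summary.n_cells_pass, time.perf_counter() - t0)
    return records, summary


# --------------------------------------------------------------------------
# tabulation
# --------------------------------------------------------------------------

_COND_KEYS = ("compound", "dose_m", "time_min", "replicate")


def _percell_frame(all_records: list[tuple[str, dict, list[CellRecord]]]
                   ) -> pd.DataFrame:
    rows = []
    for field_id, condition, records in all_records:
        for r in records:
            row = {
                "cell_id": r.cell_id, "field_id": field_id,
                "row": round(r.centroid[0], 3), "col": round(r.centroid[1], 3),
                "ratio": r.pm_cyto_ratio, "n_valid": r.n_valid,
                "n_rays": r.n_rays, "area": r.area, "border": r.border,
                "qc_pass": r.qc_pass, "qc_reason": r.qc_reason,
            }
            for k in _COND_KEYS:
                if k in condition:
                    row[k] = condition[k]
            rows.append(row)
    return pd.DataFrame(rows)


def _perfield_frame(summaries: list[FieldSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"field_id": s.field_id, "n_cells_pass": s.n_cells_pass,
               "mean_ratio": s.mean_ratio, "sem_ratio": s.sem_ratio}
        if s.mean_nuc_cyto is not None:
            row["mean_nuc_cyto"] = s.mean_nuc_cyto
        for k in _COND_KEYS:
            if k in s.condition:
                row[k] = s.condition[k]
        rows.append(row)
    return pd.DataFrame(rows)


def _write_outputs(out_dir: str | Path, config: RunConfig,
                   percell: pd.DataFrame, perfield: pd.DataFrame,
                   percond: pd.DataFrame, fits: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kw = dict(index=False, float_format="%.6g")
    percell.to_csv(out / "percell.csv", **kw)
    perfield.to_csv(out / "perfield.csv", **kw)
    percond.to_csv(out / "percondition.csv", **kw)
    (out / "fits.json").write_text(json.dumps(fits, indent=1, sort_keys=True))
    manifest = {"config": config.to_dict(), "config_hash": config.hash(),
                "seed": config.seed, "pmscan_version": __version__}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))


# --------------------------------------------------------------------------
# run modes
# --------------------------------------------------------------------------

@dataclass
class EndpointResult:
    percell: pd.DataFrame
    perfield: pd.DataFrame
    percondition: pd.DataFrame
    fits: dict
    failures: list[tuple[str, str]] = field(default_factory=list)


def _iter_endpoint_fields(config: RunConfig):
    """Yield (field_id, condition, FieldImage, GroundTruth|None)."""
    if config.preset is not None:
        kind = preset_kind(config.preset)
        spec = get_preset(config.preset, seed=config.seed)
        if kind == "dose":
            for i, (dose, img, gt) in enumerate(render_dose_series(spec)):
                cond = {"compound": config.preset, "dose_m": dose,
                        "replicate": gt.condition.get("replicate", 0)}
                yield f"dose{i:02d}", cond, img, gt
        elif kind == "field":
            img, gt = render_field(spec, preset=config.preset)
            yield "field00", {"compound": config.preset}, img, gt
        else:
            raise ValueError(
                f"preset {config.preset!r} is a {kind} preset; "
                "use run_timelapse or the statistics layer directly")
    else:
        pm = PlateMap.load(config.platemap)
        base = Path(config.platemap).parent
        for e in pm.entries:
            cond = {"compound": e.compound}
            if e.dose_m is not None:
                cond["dose_m"] = e.dose_m
            if e.time_min is not None:
                cond["time_min"] = e.time_min
            img = read_field_tiff(base / e.file, roles=e.channel_roles)
            yield f"{e.well}-f{e.field}-t{e.frame}", cond, img, None


def run_endpoint(config: RunConfig) -> EndpointResult:
    """End-point assay: per-field summaries, per-condition table, dose fits.

    Dose-grouped conditions (>=5 distinct doses for one compound) are
    automatically fitted with the variable-slope sigmoid.  Unreadable or
    failing fields are recorded and skipped; the run continues.
    """
    config.validate()
    all_records, summaries, failures = [], [], []
    for field_id, cond, img, gt in _iter_endpoint_fields(config):
        try:
            records, summary = process_field(img, config, field_id, cond, gt)
        except Exception as exc:  # per-field isolation
            log.warning("field %s failed: %s", field_id, exc)
            failures.append((field_id, str(exc)))
            continue
        all_records.append((field_id, cond, records))
        summaries.append(summary)

    percell = _percell_frame(all_records)
    perfield = _perfield_frame(summaries)
    fits: dict = {}
    if not perfield.empty and "dose_m" in perfield.columns:
        percond = (perfield.groupby(["compound", "dose_m"], as_index=False)
                   .agg(mean_ratio=("mean_ratio", "mean"),
                        sem_ratio=("sem_ratio", "mean"),
                        n_fields=("field_id", "count"))
                   .sort_values(["compound", "dose_m"], ascending=[True, False])
                   .reset_index(drop=True))
        if config.fit:
            for compound, grp in percond.groupby("compound"):
                if grp["dose_m"].nunique() >= 5:
                    fit = fit_sigmoid(grp["dose_m"].to_numpy(),
                                      grp["mean_ratio"].to_numpy())
                    fits[str(compound)] = fit.to_dict()
    elif not perfield.empty:
        keys = [k for k in ("compound",) if k in perfield.columns]
        if keys:
            percond = (perfield.groupby(keys, as_index=False)
                       .agg(mean_ratio=("mean_ratio", "mean"),
                            sem_ratio=("sem_ratio", "mean"),
                            n_fields=("field_id", "count")))
        else:
            percond = perfield.copy()
    else:
        percond = perfield.copy()

    if config.out_dir:
        _write_outputs(config.out_dir, config, percell, perfield, percond, fits)
    return EndpointResult(percell=percell, perfield=perfield,
                          percondition=percond, fits=fits, failures=failures)


@dataclass
class TimelapseResult:
    percell: pd.DataFrame
    trajectory: pd.DataFrame  # per-frame field summaries
    baseline: float
    fits: dict
    failures: list[tuple[str, str]] = field(default_factory=list)


def process_timelapse_frames(frames, config: RunConfig,
                             label: str = "timelapse") -> TimelapseResult:
    """Process an ordered list of ``(time_min, FieldImage, GroundTruth|None)``.

    Frames are processed as independent fields (population-level
    kinetics, no tracking).  The baseline is the mean of pre-addition
    frames (t < 0); fewer than 3 such frames logs a warning and uses
    what is available.  Raises when frame times are not strictly
    increasing.
    """
    times = [t for t, _, _ in frames]
    if len(times) and np.any(np.diff(times) <= 0):
        raise ValueError("frames must be ordered by strictly increasing time")

    all_records, summaries, failures = [], [], []
    for i, (t, img, gt) in enumerate(frames):
        cond = {"compound": label, "time_min": t}
        fid = f"frame{i:03d}"
        try:
            records, summary = process_field(img, config, fid, cond, gt)
        except Exception as exc:
            log.warning("frame %s failed: %s", fid, exc)
            failures.append((fid, str(exc)))
            continue
        all_records.append((fid, cond, records))
        summaries.append(summary)

    traj = _perfield_frame(summaries).sort_values("time_min").reset_index(drop=True)
    pre = traj[traj["time_min"] < 0]
    if len(pre) < 3:
        log.warning("only %d pre-addition baseline frames available", len(pre))
    baseline = float(pre["mean_ratio"].mean()) if len(pre) else float("nan")

    fits = {}
    if config.fit and len(traj) >= 6:
        fit = fit_exponential(traj["time_min"].to_numpy(),
                              traj["mean_ratio"].to_numpy(),
                              allow_delay=config.allow_delay)
        fits[label] = fit.to_dict()

    percell = _percell_frame(all_records)
    if config.out_dir:
        _write_outputs(config.out_dir, config, percell, traj,
                       traj, fits)
    return TimelapseResult(percell=percell, trajectory=traj,
                           baseline=baseline, fits=fits, failures=failures)


def run_timelapse(config: RunConfig) -> TimelapseResult:
    """Time-lapse assay on a kinetics preset: render, quantify per frame, fit."""
    config.validate()
    if config.preset is None:
        raise NotImplementedError(
            "time-lapse runs are preset-driven; acquired-image time-lapse "
            "requires a plate map with frame times ordered per condition")
    if preset_kind(config.preset) != "kinetics":
        raise ValueError(f"preset {config.preset!r} is not a kinetics preset")
    spec = get_preset(config.preset, seed=config.seed)
    frames = render_time_series(spec)
    return process_timelapse_frames(frames, config, label=config.preset)


def run_simulate(preset: str, seed: int, out_dir: str | Path) -> dict:
    """Render a preset to TIFF + ground-truth sidecars; returns a manifest."""
    kind = preset_kind(preset)  # raises listing presets when unknown
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = get_preset(preset, seed=seed)
    entries = []
    if kind == "field":
        img, gt = render_field(spec, preset=preset)
        entries.append(_write_sim(out, "field00", img, gt))
    elif kind == "dose":
        for i, (dose, img, gt) in enumerate(render_dose_series(spec)):
            sub = out / f"dose{i:02d}"
            sub.mkdir(exist_ok=True)
            entries.append(_write_sim(sub, "field00", img, gt,
                                      extra={"dose_m": dose}))
    elif kind == "kinetics":
        for i, (t, img, gt) in enumerate(render_time_series(spec)):
            entries.append(_write_sim(out, f"frame{i:03d}", img, gt,
                                      extra={"time_min": t}))
    else:
        raise ValueError(
            f"preset {preset!r} defines population moments only; nothing to render")
    manifest = {"preset": preset, "seed": seed, "kind": kind,
                "entries": entries, "pmscan_version": __version__}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _write_sim(out: Path, stem: str, img, gt, extra: dict | None = None) -> dict:
    write_field_tiff(out / f"{stem}.tif", img)
    write_ground_truth(out / f"{stem}.gt.json", gt)
    entry = {"image": str(out / f"{stem}.tif"),
             "ground_truth": str(out / f"{stem}.gt.json"),
             "n_cells": len(gt.cells)}
    entry.update(extra or {})
    return entry
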