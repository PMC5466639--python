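"""File I/O: multi-page TIFF volumes with JSON sidecars, images, tables.

Field volumes are stored as paired float32 multi-page TIFFs (real and
imaginary per channel, pages over repeats x depth) plus a JSON sidecar with
the grid counts, pitches, noise energies and seed.  En-face modalities are
8-bit or 16-bit TIFFs; ground truth and report tables are CSV; run metadata
is JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .params import OpticParams
from .polarimetry import FieldVolume
from .synthetic import SyntheticEyeDataset, cohort_truth_table


def _sidecar(params: OpticParams, extra: dict | None = None) -> dict:
    meta = dataclasses.asdict(params)
    meta.update(extra or {})
    return meta


def save_field_volume(fields: FieldVolume, params: OpticParams,
                      directory, extra_meta: dict | None = None) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for ch, e in (("ch1", fields.e1), ("ch2", fields.e2)):
        tifffile.imwrite(d / f"field_{ch}_real.tif", e.real.astype(np.float32))
        tifffile.imwrite(d / f"field_{ch}_imag.tif", e.imag.astype(np.float32))
    (d / "field_meta.json").write_text(
        json.dumps(_sidecar(params, extra_meta), indent=2))


def load_field_volume(directory) -> tuple[FieldVolume, dict]:
    d = Path(directory)
    meta = json.loads((d / "field_meta.json").read_text())
    e = {}
    for ch in ("ch1", "ch2"):
        re_ = tifffile.imread(d / f"field_{ch}_real.tif")
        im_ = tifffile.imread(d / f"field_{ch}_imag.tif")
        e[ch] = re_.astype(np.float64) + 1j * im_.astype(np.float64)
    return FieldVolume(e1=e["ch1"], e2=e["ch2"]), meta


def save_eye_dataset(ds: SyntheticEyeDataset, directory) -> None:
    """Write one synthetic eye: fields, PS-SLO stack, AF images, segmentation
    and per-focus ground truth."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_field_volume(ds.fields, ds.params, d, extra_meta={
        "eye_id": ds.eye_id, "group": ds.group,
        "vitreous_max_z": ds.vitreous_max_z})
    tifffile.imwrite(d / "psslo_crossed.tif", ds.psslo.frames.astype(np.float32))
    if ds.psslo.uncrossed is not None:
        tifffile.imwrite(d / "psslo_uncrossed.tif",
                         ds.psslo.uncrossed.astype(np.float32))
    tifffile.imwrite(d / "nir_af.tif", ds.nir_af)
    tifffile.imwrite(d / "sw_af.tif", ds.sw_af)
    tifffile.imwrite(d / "segmentation_rpe.tif",
                     ds.segmentation.line.astype(np.uint16))
    truth = cohort_truth_table([ds])
    truth.to_csv(d / "ground_truth.csv", index=False)
    ped = {"ped_kind": ds.truth.ped_kind,
           "ped_volume_mm3": ds.truth.ped_volume_mm3,
           "ped_volume_analytic_mm3": ds.truth.ped_volume_analytic_mm3}
    (d / "ped_truth.json").write_text(json.dumps(ped, indent=2))


def save_cohort(datasets, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        save_eye_dataset(ds, d / ds.eye_id)
    cohort_truth_table(datasets).to_csv(d / "cohort_ground_truth.csv", index=False)


def save_png(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image)).save(Path(path))


def write_report(report: dict, out_dir, version: str = "0",
                 first_eye=None) -> None:
    """Write the pipeline report bundle: CSV tables, JSON stats/run log and
    (optionally) the first eye's en-face images."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report["eye_records"].to_csv(out / "eye_records.csv", index=False)
    report["focus_observations"].to_csv(out / "focus_observations.csv", index=False)
    report["group_counts"].to_csv(out / "group_counts.csv")
    report["group_volumes"].to_csv(out / "group_volumes.csv")
    report["truth"].to_csv(out / "cohort_truth.csv", index=False)
    (out / "stats.json").write_text(json.dumps(report["stats"], indent=2))
    run_log = {"seed": report["seed"], "config": report["config"],
               "version": version}
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    if first_eye is not None:
        ds, artifacts = first_eye
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        save_png(artifacts["min_dopu_whole"].display, img_dir / "min_dopu_whole.png")
        save_png(artifacts["min_dopu_anterior"].display,
                 img_dir / "min_dopu_anterior.png")
        save_png(artifacts["mean_intensity"].display, img_dir / "mean_intensity.png")
        save_png(artifacts["depolarized"].display, img_dir / "depolarized.png")
        save_png(ds.nir_af, img_dir / "nir_af.png")
        save_png(ds.sw_af, img_dir / "sw_af.png")
        # composite overlay of the central B-scan
        from .enface import composite_dopu_overlay
        b = ds.params.n_bscans // 2
        from .polarimetry import stokes_from_fields
        s0 = stokes_from_fields(ds.fields).s0.mean(axis=0)[:, b, :]
        comp = composite_dopu_overlay(
            s0, artifacts["dopu"].values[:, b, :],
            valid=artifacts["dopu"].valid[:, b, :])
        save_png(np.swapaxes(comp.rgb, 0, 1), img_dir / "composite_bscan.png")
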