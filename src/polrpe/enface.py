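"""Composite DOPU B-scan overlays and en-face projections.

Three en-face products are built from a DOPU/Stokes volume:

* minimum DOPU along the whole depth,
* minimum DOPU anterior to the RPE (restricted to z < segmentation line,
  half-open, which removes the physiologic depolarization of the RPE band
  and choroid so that intraretinal depolarizing foci stand out),
* mean-intensity (S0) projection, log-compressed for display.

The composite B-scan overlays low DOPU (< 0.8 by default, strict inequality)
in red on the log-compressed structural image, only on valid signal pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .polarimetry import DopuVolume, StokesVolume


@dataclass
class SegmentationLine:
    """Per-(x, b) depth index of the anterior RPE boundary."""

    line: np.ndarray
    provenance: str = "truth"  # truth | manual | file

    def __post_init__(self) -> None:
        self.line = np.asarray(self.line, dtype=int)
        if self.line.ndim != 2:
            raise ValueError("segmentation line must be 2-D (x, b)")
        if (self.line < 0).any():
            raise ValueError("segmentation indices must be >= 0")


@dataclass
class EnFaceImage:
    values: np.ndarray
    kind: str  # min_dopu_whole | min_dopu_anterior | mean_intensity
    mask: np.ndarray  # True where the pixel is valid

    @property
    def display(self) -> np.ndarray:
        """8-bit rendering (log-compressed for intensity kinds)."""
        if self.kind == "mean_intensity":
            return log_compress(self.values)
        out = np.where(self.mask, self.values, 0.0)
        return np.round(255.0 * np.clip(out, 0.0, 1.0)).astype(np.uint8)


@dataclass
class CompositeBScan:
    """3-channel uint8 B-scan: grayscale base with a red low-DOPU overlay."""

    rgb: np.ndarray
    overlay_mask: np.ndarray


def log_compress(linear: np.ndarray, floor_db: float = -40.0) -> np.ndarray:
    """Map linear intensity to 8-bit via 20*log10(I/max I) over [floor_db, 0]."""
    linear = np.asarray(linear, dtype=float)
    peak = linear.max()
    if peak <= 0:
        return np.zeros(linear.shape, dtype=np.uint8)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(np.where(linear > 0, linear, np.nan) / peak)
    db = np.where(np.isnan(db), floor_db, np.clip(db, floor_db, 0.0))
    return np.round(255.0 * (db - floor_db) / (-floor_db)).astype(np.uint8)


def min_dopu_projection(
    dopu: DopuVolume, segmentation: SegmentationLine | None = None
) -> EnFaceImage:
    """Per-(x, b) minimum DOPU over valid voxels of the column.

    With a segmentation line only depths z < line[x, b] (strictly anterior to
    the RPE) enter the minimum.  Pixels with no valid voxel in range are
    flagged invalid and rendered as 0.
    """
    nx, nb, nz = dopu.values.shape
    in_range = dopu.valid
    kind = "min_dopu_whole"
    if segmentation is not None:
        if segmentation.line.shape != (nx, nb):
            raise ValueError("segmentation grid does not match DOPU volume")
        zidx = np.arange(nz)[None, None, :]
        in_range = in_range & (zidx < segmentation.line[:, :, None])
        kind = "min_dopu_anterior"
    masked = np.where(in_range, dopu.values, np.inf)
    values = masked.min(axis=2)
    mask = in_range.any(axis=2)
    values = np.where(mask, values, 0.0)
    return EnFaceImage(values=values, kind=kind, mask=mask)


def mean_intensity_projection(stokes: StokesVolume) -> EnFaceImage:
    """Mean S0 over depth and repeats; ``.display`` gives the log-compressed
    8-bit standard-OCT-style projection."""
    values = stokes.s0.mean(axis=(0, 3))
    mask = np.ones(values.shape, dtype=bool)
    return EnFaceImage(values=values, kind="mean_intensity", mask=mask)


def composite_dopu_overlay(
    intensity_bscan: np.ndarray,
    dopu_bscan: np.ndarray,
    valid: np.ndarray | None = None,
    threshold: float = 0.8,
) -> CompositeBScan:
    """Overlay low DOPU (strictly < threshold) in red on the log-compressed
    structural B-scan; invalid (noise-masked) pixels are never flagged."""
    intensity_bscan = np.asarray(intensity_bscan, dtype=float)
    dopu_bscan = np.asarray(dopu_bscan, dtype=float)
    if intensity_bscan.shape != dopu_bscan.shape:
        raise ValueError("intensity and DOPU B-scan shapes differ")
    if valid is None:
        valid = np.ones(dopu_bscan.shape, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != dopu_bscan.shape:
            raise ValueError("validity mask shape differs")
    base = log_compress(intensity_bscan)
    flag = (dopu_bscan < threshold) & valid
    rgb = np.stack([base, base, base], axis=-1)
    rgb[flag] = (255, 0, 0)
    return CompositeBScan(rgb=rgb, overlay_mask=flag)
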